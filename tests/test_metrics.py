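"""Volume-averaged metrics and the sweep/argmax machinery."""

import math

import numpy as np
import pytest

from nrcsim import (ConstructGeometry, SeedingSpec, build_mesh,
                    design_report, volume_metrics)
from nrcsim.config import Scenario, SweepSpec
from nrcsim.metrics import argmax_sweep, golden_section_max
from nrcsim.run import run_scenario, run_sweep
from nrcsim.solver import FieldState
from nrcsim.units import CELLS_ML_TO_M3, HOUR

GEO = ConstructGeometry(Lp=0.0)


def make_state(mesh, n=None, c=None, v=None, t=0.0):
    zeros = np.zeros(mesh.n_total)
    return FieldState(
        t=t,
        n=np.zeros(mesh.n_core) if n is None else n,
        c=zeros.copy() if c is None else c,
        v=zeros.copy() if v is None else v)


class TestVolumeMetrics:
    def test_uniform_field(self):
        mesh = build_mesh(GEO, nz=24, nr_core=4)
        st = make_state(mesh, v=np.full(mesh.n_total, 3.5e-5))
        m = volume_metrics(st, mesh)
        assert m["v_bar"] == pytest.approx(3.5e-5, rel=1e-12)
        assert m["v_sd"] == pytest.approx(0.0, abs=1e-18)

    def test_linear_axial_field_has_mean_half(self):
        mesh = build_mesh(GEO, nz=48, nr_core=3)
        prof = np.repeat(mesh.z_centers / GEO.L, mesh.nr_core)
        m = volume_metrics(make_state(mesh, v=prof), mesh)
        assert m["v_bar"] == pytest.approx(0.5, rel=1e-10)

    def test_two_value_field_population_sd(self):
        """Half the volume at a, half at b: sd = |a - b| / 2 (population
        normalisation, not sample)."""
        mesh = build_mesh(GEO, nz=48, nr_core=3)
        a, b = 2.0e-5, 8.0e-5
        prof = np.where(np.repeat(mesh.z_centers, mesh.nr_core) < GEO.L / 2,
                        a, b)
        m = volume_metrics(make_state(mesh, v=prof), mesh)
        assert m["v_sd"] == pytest.approx(abs(a - b) / 2, rel=1e-10)
        assert m["v_bar"] == pytest.approx((a + b) / 2, rel=1e-10)

    def test_n_tot_consistent_with_mean(self):
        mesh = build_mesh(GEO, nz=24, nr_core=2)
        n = np.full(mesh.n_core, 1.7e14)
        m = volume_metrics(make_state(mesh, n=n), mesh)
        assert m["n_tot"] == pytest.approx(1.7e14 * GEO.core_volume,
                                           rel=1e-10)

    def test_min_mean_max_ordering(self):
        mesh = build_mesh(GEO, nz=24, nr_core=2)
        rng = np.random.default_rng(3)
        st = make_state(mesh, v=rng.uniform(0, 1, mesh.n_total))
        m = volume_metrics(st, mesh)
        assert m["v_min"] <= m["v_bar"] <= m["v_max"]


class TestGoldenSection:
    def test_locates_quadratic_maximum(self):
        x, fx = golden_section_max(lambda x: -(x - 0.37) ** 2, 0, 1, 1e-6)
        assert x == pytest.approx(0.37, abs=1e-5)
        assert fx == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def tiny_scenario():
    return Scenario(geometry=GEO, seeding=SeedingSpec.uniform(1e14),
                    t_end=6 * HOUR, output_times=(0.0, 6 * HOUR), nz=24)


class TestSweep:

    def test_single_point_grid_is_its_own_argmax(self, tiny_scenario):
        sw = SweepSpec(var="n0", values=(1.0e14,), metrics=("n_bar",),
                       times_h=(6.0,))
        res = run_sweep(tiny_scenario, sw)
        assert res.optima[("n_bar", 6 * HOUR)]["argmax"] == 1.0e14

    def test_refined_optimum_dominates_grid(self, tiny_scenario):
        sw = SweepSpec(var="n0", values=tuple(np.linspace(5e13, 3e14, 6)),
                       metrics=("n_bar",), times_h=(6.0,))
        res = run_sweep(tiny_scenario, sw)
        e = res.optima[("n_bar", 6 * HOUR)]
        curve = res.metric_curve("n_bar", 6 * HOUR)
        assert e["max"] >= curve["n_bar"].max() - 1e-12
        assert res.values.min() <= e["argmax"] <= res.values.max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(var="n0", values=())

    def test_failed_simulation_aborts_with_offending_value(self):
        def boom(value):
            raise RuntimeError("synthetic failure")
        with pytest.raises(RuntimeError, match="1e\\+14"):
            argmax_sweep(boom, [1e14], [6 * HOUR], metrics=("n_bar",))

    def test_zeta_sweep_conserves_initial_cell_number(self):
        """The three-zone profile integrates to n0_tot for every zeta, so
        n_tot at t = 0 is invariant along a zeta sweep."""
        base = Scenario(geometry=GEO,
                        seeding=SeedingSpec.three_zone(3.0e5, 1.0),
                        t_end=1 * HOUR, output_times=(0.0, 1 * HOUR), nz=24)
        sw = SweepSpec(var="zeta", values=(0.0, 1.0, 3.0),
                       metrics=("n_tot",), times_h=(1.0,))
        res = run_sweep(base, sw, refine=False)
        t0 = res.table[res.table["t"] == 0.0]
        np.testing.assert_allclose(t0["n_tot"], 3.0e5, rtol=1e-9)


class TestDesignReport:
    def test_single_sweep_single_row(self):
        sc = Scenario(geometry=GEO, seeding=SeedingSpec.uniform(1e14),
                      t_end=1 * HOUR, output_times=(0.0, 1 * HOUR), nz=24)
        sw = SweepSpec(var="n0", values=(5e13, 1e14), metrics=("n_bar",),
                       times_h=(1.0,))
        res = run_sweep(sc, sw, refine=False)
        df = design_report({"impermeable": res}, metric="n_bar")
        assert len(df) == 1
        assert df.iloc[0]["design"] == "impermeable"
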