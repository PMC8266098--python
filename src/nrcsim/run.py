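"""Scenario execution helpers shared by the CLI, the tests and the
reproduction scripts."""

from __future__ import annotations

import json
import pathlib
from typing import Optional

import numpy as np
import pandas as pd

from .config import Scenario, SweepSpec
from .metrics import SweepResult, argmax_sweep, volume_metrics_series
from .solver import SimulationResult, simulate, simulate_axial_1d
from .units import (CELLS_ML_TO_M3, HOUR, NG_ML_TO_KG_M3, PCT_O2_TO_KG_M3)

__all__ = ["run_scenario", "run_sweep", "write_outputs"]


def run_scenario(scenario: Scenario, solver: str = "auto",
                 **overrides) -> SimulationResult:
    """Simulate one scenario.

    ``solver``: "auto" picks the exact 1D axial reduction whenever the
    sheath is impermeable (initial conditions are always r-uniform here),
    "1d" forces it, "2d" forces the full axisymmetric solve.
    """
    s = scenario
    kwargs = dict(t_end=s.t_end, output_times=s.output_times, nz=s.nz)
    kwargs.update(overrides)
    use_1d = (solver == "1d"
              or (solver == "auto" and s.geometry.is_impermeable))
    if use_1d:
        return simulate_axial_1d(s.geometry, s.environment, s.seeding,
                                 s.params, **kwargs)
    return simulate(s.geometry, s.environment, s.seeding, s.params,
                    nr_core=s.nr_core, nr_sheath=s.nr_sheath, **kwargs)


def _scenario_for_value(scenario: Scenario, var: str,
                        value: float) -> Scenario:
    if var == "n0":
        return scenario.replace(seeding=scenario.seeding.replace(
            mode="uniform", n0=value))
    if var == "zeta":
        return scenario.replace(seeding=scenario.seeding.replace(
            mode="three_zone", zeta=value))
    if var == "n0_tot":
        return scenario.replace(seeding=scenario.seeding.replace(
            mode="three_zone", n0_tot=value))
    if var == "epsilon":
        return scenario.replace(geometry=scenario.geometry.replace(
            epsilon=value))
    raise ValueError(f"unknown sweep variable {var!r}")


def run_sweep(scenario: Scenario, sweep: Optional[SweepSpec] = None,
              solver: str = "auto", refine: bool = True,
              refine_resolution: Optional[float] = None,
              **overrides) -> SweepResult:
    """Run the sweep attached to (or passed alongside) a scenario.

    Output times are forced to cover the sweep's evaluation times. The
    default refinement resolution for n0 sweeps is 2.5e6 cells/ml.
    """
    sw = sweep if sweep is not None else scenario.sweep
    if sw is None:
        raise ValueError("scenario has no sweep specification")
    times = [h * HOUR for h in sw.times_h]
    t_end = max(scenario.t_end, max(times))
    out_times = tuple(sorted(
        (set(times) | set(scenario.output_times)) - {t for t in
                                                     scenario.output_times
                                                     if t > t_end}))
    base = scenario.replace(output_times=out_times, t_end=t_end)
    if refine_resolution is None and sw.var == "n0":
        refine_resolution = 2.5e6 * CELLS_ML_TO_M3

    def run_for_value(value: float) -> SimulationResult:
        return run_scenario(_scenario_for_value(base, sw.var, value),
                            solver=solver, **overrides)

    return argmax_sweep(run_for_value, sw.values, times,
                        metrics=sw.metrics, sweep_var=sw.var,
                        refine=refine, refine_resolution=refine_resolution)


def _field_frame(result: SimulationResult, state) -> pd.DataFrame:
    """Tidy per-cell field table (SI units) for one snapshot."""
    mesh = result.mesh
    rows = []
    ncore = mesh.n_core
    zc = np.repeat(mesh.z_centers, mesh.nr_core)
    rc = np.tile(mesh.r_centers_core, mesh.nz)
    for i in range(ncore):
        rows.append({"z_m": zc[i], "r_m": rc[i], "domain": "gel",
                     "n_cell_m3": state.n[i], "c_kg_m3": state.c[i],
                     "v_kg_m3": state.v[i]})
    for a, iz in enumerate(mesh.active_iz):
        for jr in range(mesh.nr_sheath):
            k = mesh.sheath_index(a, jr)
            rows.append({"z_m": mesh.z_centers[iz],
                         "r_m": mesh.r_centers_sheath[jr],
                         "domain": "sheath", "n_cell_m3": 0.0,
                         "c_kg_m3": state.c[k], "v_kg_m3": state.v[k]})
    return pd.DataFrame(rows)


def write_outputs(result: SimulationResult, out_dir, scenario=None) -> None:
    """Write metrics CSV (practical units), field CSVs (SI) and the
    resolved config to ``out_dir``."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = volume_metrics_series(result)
    rep = pd.DataFrame({
        "t_h": m["t"] / HOUR,
        "n_bar_cells_ml": m["n_bar"] / CELLS_ML_TO_M3,
        "c_bar_pct_O2": m["c_bar"] / PCT_O2_TO_KG_M3,
        "v_bar_ng_ml": m["v_bar"] / NG_ML_TO_KG_M3,
        "v_sd_ng_ml": m["v_sd"] / NG_ML_TO_KG_M3,
        "n_tot_cells": m["n_tot"],
    })
    rep.to_csv(out / "metrics.csv", index=False)
    for state in result.snapshots:
        _field_frame(result, state).to_csv(
            out / f"fields_t{state.t / HOUR:07.2f}h.csv", index=False)
    if scenario is not None:
        scenario.to_yaml(out / "scenario.resolved.yaml")
    with open(out / "run.json", "w") as fh:
        json.dump({"success": result.success, "nfev": result.nfev,
                   "solver_path": result.solver_path,
                   "times_s": [float(t) for t in result.times]}, fh,
                  indent=1)
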