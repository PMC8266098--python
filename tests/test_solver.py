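"""PDE solver verification against independent oracles.

The solver is checked against (i) exact equilibria, (ii) Fourier-series
solutions of the pure diffusion problem, (iii) the well-mixed reaction
ODE in the zero-flux limit, (iv) discrete conservation, (v) the exact
1D reduction of the impermeable construct, and (vi) grid-convergence of
the spatial scheme.
"""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nrcsim import (BoundaryEnvironment, ConstructGeometry, REFERENCE_PARAMS,
                    SeedingSpec, assemble_diffusion, build_mesh, simulate,
                    simulate_axial_1d, wellmixed_solve)
from nrcsim.units import CELLS_ML_TO_M3, HOUR, PCT_O2_TO_KG_M3

P = REFERENCE_PARAMS
GEO = ConstructGeometry(Lp=0.0)


def fourier_slab(z, t, L, D, u0, u_b, modes=60):
    """Dirichlet-slab diffusion: uniform IC u0, boundary value u_b."""
    u = np.full_like(z, u_b, dtype=float)
    for k in range(1, 2 * modes, 2):  # odd modes only
        u += (u0 - u_b) * 4.0 / (k * math.pi) * np.sin(
            k * math.pi * z / L) * math.exp(-D * (k * math.pi / L) ** 2 * t)
    return u


class TestOperator:
    def test_interior_rows_annihilate_constants(self):
        mesh = build_mesh(GEO, nz=24, nr_core=4)
        op = assemble_diffusion(mesh, GEO, P, "oxygen")
        u = np.ones(mesh.n_total)
        r = op.rate(u, 1.0)  # boundary value equal to the constant field
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_closed_operator_annihilates_constants_without_boundary(self):
        mesh = build_mesh(GEO, nz=24, nr_core=4)
        op = assemble_diffusion(mesh, GEO, P, "oxygen", closed_ends=True)
        u = np.full(mesh.n_total, 3.7)
        np.testing.assert_allclose(op.A @ u, 0.0, atol=1e-12)
        assert op.boundary_g.sum() == 0.0

    def test_mass_rate_equals_boundary_flux(self):
        """Telescoping conservation: sum_i cap_i (A u + b)_i = boundary flux,
        for arbitrary fields (reactions off)."""
        geo = ConstructGeometry(Lp=7.5e-3, epsilon=0.8)
        mesh = build_mesh(geo, nz=24, nr_core=4, nr_sheath=3)
        op = assemble_diffusion(mesh, geo, P, "vegf")
        rng = np.random.default_rng(7)
        for _ in range(3):
            u = rng.uniform(0, 1e-4, mesh.n_total)
            val = 3e-5
            dmass = float(op.capacity @ op.rate(u, val))
            assert dmass == pytest.approx(op.boundary_flux(u, val),
                                          rel=1e-10, abs=1e-22)

    def test_open_sheath_conductance_matches_free_diffusion(self):
        """With eps = 1 (tau = 1) the sheath carries free diffusivities, so
        interface conductance equals the two-layer harmonic value."""
        geo = ConstructGeometry(Lp=7.5e-3, epsilon=1.0)
        mesh = build_mesh(geo, nz=24, nr_core=2, nr_sheath=2)
        op = assemble_diffusion(mesh, geo, P, "oxygen")
        i = mesh.core_index(5, 1)
        j = mesh.sheath_index(5, 0)
        g_num = op.A[i, j] * op.capacity[i]
        A_if = 2 * math.pi * geo.R1 * mesh.dz
        g_exact = A_if / ((mesh.dr_core / 2) / P.D_c_gel
                          + (mesh.dr_sheath / 2) / P.D_c_sheath)
        assert g_num == pytest.approx(g_exact, rel=1e-12)


class TestPureDiffusion:
    def test_oxygen_matches_fourier_series(self):
        """No cells: oxygen obeys 1D Dirichlet-slab diffusion."""
        env = BoundaryEnvironment()
        res = simulate_axial_1d(GEO, env, SeedingSpec.uniform(0.0),
                                t_end=24 * HOUR,
                                output_times=[6 * HOUR, 24 * HOUR], nz=160)
        for st in res.snapshots:
            exact = fourier_slab(res.mesh.z_centers, st.t, GEO.L, P.D_c_gel,
                                 env.c0, env.c_tissue)
            err = np.max(np.abs(st.c - exact)) / env.c0
            assert err < 1e-3

    def test_vegf_without_degradation_matches_fourier_series(self):
        env = BoundaryEnvironment(v0=1e-4, v_tissue=0.0)
        p = P.replace(K=0.0)
        res = simulate_axial_1d(GEO, env, SeedingSpec.uniform(0.0), params=p,
                                t_end=48 * HOUR, output_times=[48 * HOUR],
                                nz=160)
        st = res.snapshots[-1]
        exact = fourier_slab(res.mesh.z_centers, st.t, GEO.L, P.D_v_gel,
                             env.v0, env.v_tissue)
        assert np.max(np.abs(st.v - exact)) / env.v0 < 1e-3

    def test_second_order_spatial_convergence(self):
        """Smooth manufactured solution sin(pi z / L) e^{-D (pi/L)^2 t}:
        the observed order of the FV scheme is ~2."""
        D = P.D_c_gel
        L = GEO.L
        t_end = 0.2 * L ** 2 / (4 * D)
        errs = []
        for nz in (24, 48, 96):
            mesh = build_mesh(GEO, nz=nz, nr_core=1)
            op = assemble_diffusion(mesh, GEO, P, "oxygen")
            z = mesh.z_centers
            u0 = np.sin(math.pi * z / L)
            sol = solve_ivp(lambda t, u: op.rate(u, 0.0), (0, t_end), u0,
                            method="BDF", rtol=1e-10, atol=1e-12,
                            t_eval=[t_end])
            exact = np.sin(math.pi * z / L) * math.exp(
                -D * (math.pi / L) ** 2 * t_end)
            errs.append(np.max(np.abs(sol.y[:, -1] - exact)))
        order1 = math.log2(errs[0] / errs[1])
        order2 = math.log2(errs[1] / errs[2])
        assert order1 > 1.8 and order2 > 1.8


class TestCoupledSystem:
    def test_equilibrium_is_preserved(self):
        """No cells and IC equal to tissue values: nothing moves."""
        env = BoundaryEnvironment(c0=5 * PCT_O2_TO_KG_M3,
                                  c_tissue=5 * PCT_O2_TO_KG_M3,
                                  v0=0.0, v_tissue=0.0)
        res = simulate_axial_1d(GEO, env, SeedingSpec.uniform(0.0),
                                t_end=12 * HOUR, output_times=[12 * HOUR],
                                nz=24)
        st = res.snapshots[-1]
        np.testing.assert_allclose(st.c, env.c0, rtol=1e-9)
        np.testing.assert_allclose(st.v, 0.0, atol=1e-15)
        np.testing.assert_allclose(st.n, 0.0, atol=1e-15)

    def test_zero_flux_limit_matches_wellmixed_oracle(self):
        """With every boundary closed the PDE collapses to the reaction
        ODEs; fields must match the independent well-mixed solution."""
        n0 = 1.78e14
        env = BoundaryEnvironment()
        times = np.array([1, 6, 12, 24]) * HOUR
        res = simulate(GEO, env, SeedingSpec.uniform(n0), t_end=24 * HOUR,
                       output_times=times, nz=8, nr_core=1,
                       closed_ends=True, rtol=1e-8)
        ode = wellmixed_solve(n0, env.c0, env.v0, t_end=24 * HOUR,
                              output_times=times, rtol=1e-10)
        for k, st in enumerate(res.snapshots):
            assert np.max(np.abs(st.n - ode.n[k])) / n0 < 1e-4
            assert np.max(np.abs(st.c - ode.c[k])) / env.c0 < 1e-4
            assert np.max(np.abs(st.v - ode.v[k])) / max(ode.v[k], 1e-30) \
                < 1e-4

    def test_conservation_with_reactions_off(self):
        """Change in total discrete mass equals the time-integrated
        boundary flux (tracked as an auxiliary ODE) to 1e-8 relative."""
        mesh = build_mesh(GEO, nz=48, nr_core=1)
        op = assemble_diffusion(mesh, GEO, P, "oxygen")
        env = BoundaryEnvironment()
        u0 = np.full(mesh.n_total, env.c0)

        def rhs(t, y):
            u = y[:-1]
            return np.concatenate([op.rate(u, env.c_tissue),
                                   [op.boundary_flux(u, env.c_tissue)]])

        sol = solve_ivp(rhs, (0, 24 * HOUR), np.concatenate([u0, [0.0]]),
                        method="BDF", rtol=1e-10, atol=1e-16,
                        t_eval=[24 * HOUR])
        u_end = sol.y[:-1, -1]
        q_end = sol.y[-1, -1]
        dmass = op.total_mass(u_end) - op.total_mass(u0)
        assert dmass == pytest.approx(q_end, rel=1e-8)

    def test_1d_2d_equivalence_for_impermeable_construct(self):
        """r-uniform ICs + impermeable sheath: the 2D solution is z-only
        and must agree with the 1D fast path to < 1e-3 relative."""
        n0 = 1.78e14
        env = BoundaryEnvironment()
        common = dict(t_end=24 * HOUR, output_times=[24 * HOUR], nz=48)
        r1 = simulate_axial_1d(GEO, env, SeedingSpec.uniform(n0), **common)
        r2 = simulate(GEO, env, SeedingSpec.uniform(n0), nr_core=6, **common)
        s1, s2 = r1.snapshots[-1], r2.snapshots[-1]
        n2 = s2.n.reshape(48, 6)
        c2 = s2.c.reshape(48, 6)
        v2 = s2.v.reshape(48, 6)
        # radial uniformity of the 2D solution
        assert np.max(np.ptp(c2, axis=1)) / env.c0 < 1e-6
        assert np.max(np.abs(n2.mean(axis=1) - s1.n)) / n0 < 1e-3
        assert np.max(np.abs(c2.mean(axis=1) - s1.c)) / env.c0 < 1e-3
        assert np.max(np.abs(v2.mean(axis=1) - s1.v)) / s1.v.max() < 1e-3

    def test_axial_symmetry_of_symmetric_problem(self):
        """Symmetric ICs/BCs give a solution symmetric about z = L/2."""
        res = simulate_axial_1d(GEO, BoundaryEnvironment(),
                                SeedingSpec.uniform(1.78e14),
                                t_end=12 * HOUR, output_times=[12 * HOUR],
                                nz=48)
        st = res.snapshots[-1]
        for f, scale in ((st.n, 1.78e14), (st.c, 8.6e-3),
                         (st.v, st.v.max())):
            assert np.max(np.abs(f - f[::-1])) / scale < 1e-9

    def test_1d_path_rejects_porous_sheath(self):
        geo = ConstructGeometry(Lp=7.5e-3, epsilon=0.8)
        with pytest.raises(ValueError):
            simulate_axial_1d(geo, BoundaryEnvironment(),
                              SeedingSpec.uniform(1e14))


class TestScenarioBehaviour:
    def test_positivity_on_baseline_scenarios(self, baseline_1d_run,
                                              porous_2d_run):
        for res in (baseline_1d_run, porous_2d_run):
            for st in res.snapshots:
                assert st.n.min() >= -1e-12 * 1.78e14
                assert st.c.min() >= -1e-12 * 8.62e-3
                assert st.v.min() >= -1e-12 * max(st.v.max(), 1e-12)

    def test_impermeable_cell_density_minimum_migrates_inward(
            self, baseline_1d_run):
        """Cell density is lowest near the stumps early (< 6 h, loss of
        oxygen to the tissue) but lowest at the centre later (oxygen
        starvation at depth)."""
        res = baseline_1d_run
        early = res.state_at(1 * HOUR)
        late = res.state_at(12 * HOUR)
        nz = res.mesh.nz
        centre = slice(nz // 3, 2 * nz // 3)
        assert early.n[:3].min() < early.n[centre].min()
        assert late.n[centre].min() < late.n[:3].min()

    def test_impermeable_vegf_rises_then_falls_peaking_near_12h(
            self, baseline_1d_run):
        m = baseline_1d_run.metrics()
        v = m.set_index("t")["v_bar"]
        assert v[12 * HOUR] > v[6 * HOUR]
        assert v[24 * HOUR] < v[12 * HOUR]

    def test_porous_oxygen_relaxes_to_tissue_within_half_hour(
            self, porous_2d_run, environment):
        """eps = 0.8, T = 0.25 mm: radial equilibration is fast; the core
        oxygen field is within 5% of c_tissue by t = 0.5 h."""
        st = porous_2d_run.state_at(0.5 * HOUR)
        core_c = st.c[: porous_2d_run.mesh.n_core]
        assert np.max(np.abs(core_c - environment.c_tissue)) \
            / environment.c_tissue < 0.05
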