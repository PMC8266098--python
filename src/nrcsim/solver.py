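"""Finite-volume discretisation and stiff time integration of the coupled
cell-oxygen-VEGF system.

Spatial scheme
--------------
Cell-centred axisymmetric finite volumes. Face conductances are
``g = D_eff * A / d`` with A the axisymmetric face area and d the
centre-to-centre distance; at the gel-sheath interface the two one-sided
half-cell conductances are combined harmonically, which enforces discrete
flux continuity, and (with partition coefficients of 1) concentration
continuity at the interface. The sheath carries the effective diffusivity
``D * epsilon / tau(epsilon)`` and an ``epsilon``-scaled storage
capacity. Dirichlet tissue values act through half-cell boundary faces at
z = 0, z = L (gel, and sheath where porous) and at r = R2 (porous sheath
only); the axis r = 0, the interface over impermeable sheath sections and
the internal porous-zone end faces are zero-flux. Because unknowns live
at cell centres, the t = 0 conflict between initial and boundary values
never materialises on a node: boundary values act on t > 0 through the
boundary-face fluxes while the initial snapshot reports the initial
condition.

Time scheme
-----------
Method of lines with scipy's adaptive implicit BDF integrator on the full
coupled system (no operator splitting); the tanh hypoxia switch and the
Michaelis-Menten uptake make the system stiff near c ~ c_h. Reaction
terms evaluate max(c, 0) so that tiny negative integrator excursions
cannot destabilise the kinetics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .geometry import ConstructGeometry, Mesh, SeedingSpec, build_mesh, \
    seeding_profile
from .parameters import REFERENCE_PARAMS, ParameterSet
from .units import HOUR, PCT_O2_TO_KG_M3

__all__ = ["BoundaryEnvironment", "FieldState", "SimulationResult",
           "DiffusionOperator", "assemble_diffusion", "simulate",
           "simulate_axial_1d", "DEFAULT_OUTPUT_TIMES"]

#: default output cadence (s): 0, 0.5, 1, 6, 12, 24, 120 h
DEFAULT_OUTPUT_TIMES = tuple(h * HOUR for h in (0.0, 0.5, 1.0, 6.0, 12.0,
                                                24.0, 120.0))


@dataclass(frozen=True)
class BoundaryEnvironment:
    """Initial and surrounding-tissue concentrations (SI units).

    Defaults: construct stored at 21 %O2 with no VEGF; tissue at 5 %O2
    with no VEGF.
    """

    c0: float = 21.0 * PCT_O2_TO_KG_M3
    c_tissue: float = 5.0 * PCT_O2_TO_KG_M3
    v0: float = 0.0
    v_tissue: float = 0.0

    def __post_init__(self) -> None:
        if min(self.c0, self.c_tissue, self.v0, self.v_tissue) < 0:
            raise ValueError("concentrations must be non-negative")

    def replace(self, **changes) -> "BoundaryEnvironment":
        return dataclasses.replace(self, **changes)


@dataclass
class DiffusionOperator:
    """Assembled finite-volume diffusion operator for one solute.

    ``rate(u, value)`` returns the storage-normalised diffusive rate
    A @ u + w * value (units: concentration / s), where ``value`` is the
    common Dirichlet tissue concentration. ``boundary_flux(u, value)``
    returns the instantaneous net mass inflow through all Dirichlet faces
    (kg/s), and equals d/dt of the total discrete mass when reactions are
    off (telescoping conservation of the FV assembly).
    """

    A: sp.csr_matrix          # (N, N), includes Dirichlet diagonal terms
    dirichlet_weight: np.ndarray  # (N,), b = weight * value
    boundary_g: np.ndarray    # (N,), summed raw conductances per cell (m^3/s)
    capacity: np.ndarray      # (N,), phi * V per cell (m^3)

    def rate(self, u: np.ndarray, value: float) -> np.ndarray:
        return self.A @ u + self.dirichlet_weight * value

    def boundary_flux(self, u: np.ndarray, value: float) -> float:
        return float(self.boundary_g.sum() * value - self.boundary_g @ u)

    def total_mass(self, u: np.ndarray) -> float:
        return float(self.capacity @ u)


def assemble_diffusion(mesh: Mesh, geometry: ConstructGeometry,
                       params: ParameterSet, species: str = "oxygen",
                       closed_ends: bool = False) -> DiffusionOperator:
    """Assemble the axisymmetric FV diffusion operator for one solute.

    ``species`` selects the gel/sheath diffusivity pair. With
    ``closed_ends`` every Dirichlet face is omitted, giving the zero-flux
    configuration used to cross-check the solver against the well-mixed
    reaction oracle.
    """
    if species == "oxygen":
        D_g, D_s = params.D_c_gel, params.D_c_sheath
    elif species == "vegf":
        D_g, D_s = params.D_v_gel, params.D_v_sheath
    else:
        raise ValueError(f"unknown species {species!r}")

    nz, nrc, nrs = mesh.nz, mesh.nr_core, mesh.nr_sheath
    dz, dr_c = mesh.dz, mesh.dr_core
    N = mesh.n_total

    capacity = np.empty(N)
    capacity[: mesh.n_core] = mesh.core_volumes.reshape(-1)
    has_sheath = mesh.n_sheath > 0
    if has_sheath:
        eps = geometry.epsilon
        tau = geometry.tau()
        D_s_eff = D_s * eps / tau
        dr_s = mesh.dr_sheath
        active = mesh.active_iz
        for a, _iz in enumerate(active):
            for jr in range(nrs):
                capacity[mesh.sheath_index(a, jr)] = (
                    eps * mesh.sheath_volumes[jr])

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    dir_weight = np.zeros(N)
    boundary_g = np.zeros(N)

    def add_internal(i, j, g):
        i = np.atleast_1d(np.asarray(i, dtype=np.int64))
        j = np.atleast_1d(np.asarray(j, dtype=np.int64))
        g = np.broadcast_to(np.asarray(g, dtype=float), i.shape)
        rows.extend([i, i, j, j])
        cols.extend([i, j, j, i])
        vals.extend([-g / capacity[i], g / capacity[i],
                     -g / capacity[j], g / capacity[j]])

    def add_dirichlet(i, g):
        i = np.atleast_1d(np.asarray(i, dtype=np.int64))
        g = np.broadcast_to(np.asarray(g, dtype=float), i.shape)
        rows.append(i)
        cols.append(i)
        vals.append(-g / capacity[i])
        np.add.at(dir_weight, i, g / capacity[i])
        np.add.at(boundary_g, i, g)

    iz_all = np.arange(nz)

    # --- core radial faces ------------------------------------------------
    for jr in range(nrc - 1):
        r_f = mesh.r_faces_core[jr + 1]
        g = D_g * 2.0 * math.pi * r_f * dz / dr_c
        add_internal(mesh.core_index(iz_all, jr),
                     mesh.core_index(iz_all, jr + 1), g)

    # --- core axial faces -------------------------------------------------
    ring_core = math.pi * (mesh.r_faces_core[1:] ** 2
                           - mesh.r_faces_core[:-1] ** 2)
    for jr in range(nrc):
        g = D_g * ring_core[jr] / dz
        iz = np.arange(nz - 1)
        add_internal(mesh.core_index(iz, jr), mesh.core_index(iz + 1, jr), g)
        if not closed_ends:
            g_b = D_g * ring_core[jr] / (dz / 2.0)
            add_dirichlet(mesh.core_index(0, jr), g_b)
            add_dirichlet(mesh.core_index(nz - 1, jr), g_b)

    if has_sheath:
        # --- gel-sheath interface (porous columns only) -------------------
        A_if = 2.0 * math.pi * geometry.R1 * dz
        g_if = A_if / ((dr_c / 2.0) / D_g + (dr_s / 2.0) / D_s_eff)
        for a, iz in enumerate(active):
            add_internal(mesh.core_index(iz, nrc - 1),
                         mesh.sheath_index(a, 0), g_if)

        # --- sheath radial faces ------------------------------------------
        for jr in range(nrs - 1):
            r_f = mesh.r_faces_sheath[jr + 1]
            g = D_s_eff * 2.0 * math.pi * r_f * dz / dr_s
            for a in range(len(active)):
                add_internal(mesh.sheath_index(a, jr),
                             mesh.sheath_index(a, jr + 1), g)

        # --- sheath outer Dirichlet (r = R2) ------------------------------
        if not closed_ends:
            g_out = D_s_eff * 2.0 * math.pi * geometry.R2 * dz / (dr_s / 2.0)
            for a in range(len(active)):
                add_dirichlet(mesh.sheath_index(a, nrs - 1), g_out)

        # --- sheath axial faces -------------------------------------------
        ring_sheath = math.pi * (mesh.r_faces_sheath[1:] ** 2
                                 - mesh.r_faces_sheath[:-1] ** 2)
        for a in range(len(active) - 1):
            if active[a + 1] == active[a] + 1:  # contiguous columns
                for jr in range(nrs):
                    g = D_s_eff * ring_sheath[jr] / dz
                    add_internal(mesh.sheath_index(a, jr),
                                 mesh.sheath_index(a + 1, jr), g)
        if not closed_ends:
            # Dirichlet at the construct ends where the sheath reaches them;
            # internal porous-zone end faces (z = Lp, L - Lp) stay zero-flux.
            for a, iz in enumerate(active):
                if iz == 0 or iz == nz - 1:
                    for jr in range(nrs):
                        g_b = D_s_eff * ring_sheath[jr] / (dz / 2.0)
                        add_dirichlet(mesh.sheath_index(a, jr), g_b)

    A = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N)).tocsr()
    return DiffusionOperator(A=A, dirichlet_weight=dir_weight,
                             boundary_g=boundary_g, capacity=capacity)


@dataclass
class FieldState:
    """Discretised fields at one time point (flat core-then-sheath order)."""

    t: float
    n: np.ndarray  # (n_core,)
    c: np.ndarray  # (n_total,)
    v: np.ndarray  # (n_total,)


@dataclass
class SimulationResult:
    """Snapshots plus the fully resolved configuration of a run."""

    mesh: Mesh
    geometry: ConstructGeometry
    environment: BoundaryEnvironment
    seeding: SeedingSpec
    params: ParameterSet
    times: np.ndarray
    snapshots: List[FieldState]
    success: bool
    message: str = ""
    nfev: int = 0
    solver_path: str = "2d"

    def state_at(self, t: float) -> FieldState:
        i = int(np.argmin(np.abs(self.times - t)))
        if not math.isclose(self.times[i], t, rel_tol=1e-9, abs_tol=1e-6):
            raise KeyError(f"no snapshot at t = {t} s")
        return self.snapshots[i]

    def metrics(self):
        from .metrics import volume_metrics_series
        return volume_metrics_series(self)


def _reaction_arrays(mesh: Mesh, seeding: SeedingSpec,
                     geometry: ConstructGeometry, params: ParameterSet):
    """Per-core-cell seeded density and the coefficients evaluated at it.

    delta, alpha and Vm are evaluated at the locally *seeded* density
    n0(z) (zone-local under three-zone seeding), held fixed in time.
    """
    n0_z = seeding_profile(seeding, geometry, mesh.z_centers)
    n0_cells = np.repeat(n0_z, mesh.nr_core)
    delta = params.death_rate(n0_cells)
    alpha = params.vegf_baseline(n0_cells)
    vm = params.regulation(n0_cells)
    return n0_cells, delta, np.asarray(alpha), np.asarray(vm)


def _jac_sparsity(mesh: Mesh, op_c: DiffusionOperator,
                  op_v: DiffusionOperator) -> sp.csr_matrix:
    ncore, ntot = mesh.n_core, mesh.n_total
    N = ncore + 2 * ntot
    eye_core = sp.identity(ncore, format="coo")
    blocks = [
        (eye_core.row, eye_core.col),                       # n-n
        (eye_core.row, ncore + eye_core.col),               # n-c
        (ncore + np.arange(ntot), ncore + np.arange(ntot)),  # c-c diag
        (ncore + eye_core.row, eye_core.col),               # c-n
        (ncore + ntot + np.arange(ntot),
         ncore + ntot + np.arange(ntot)),                   # v-v diag
        (ncore + ntot + eye_core.row, ncore + eye_core.col),  # v-c
        (ncore + ntot + eye_core.row, eye_core.col),        # v-n
    ]
    Ac = op_c.A.tocoo()
    Av = op_v.A.tocoo()
    blocks.append((ncore + Ac.row, ncore + Ac.col))
    blocks.append((ncore + ntot + Av.row, ncore + ntot + Av.col))
    rows = np.concatenate([np.asarray(r, dtype=np.int64) for r, _ in blocks])
    cols = np.concatenate([np.asarray(c, dtype=np.int64) for _, c in blocks])
    return sp.coo_matrix((np.ones_like(rows, dtype=float), (rows, cols)),
                         shape=(N, N)).tocsr()


def simulate(
    geometry: ConstructGeometry,
    environment: BoundaryEnvironment,
    seeding: SeedingSpec,
    params: ParameterSet = REFERENCE_PARAMS,
    t_end: float = 24 * HOUR,
    output_times: Optional[Sequence[float]] = None,
    nz: int = 99,
    nr_core: int = 12,
    nr_sheath: int = 8,
    rtol: float = 1e-6,
    atol_conc: float = 1e-12,
    atol_cells: float = 1.0,
    closed_ends: bool = False,
    mesh: Optional[Mesh] = None,
    negativity_tol: float = 1e-6,
) -> SimulationResult:
    """Run the coupled cell-oxygen-VEGF simulation on the (r, z) mesh.

    Returns snapshots at ``output_times`` (defaulting to the standard
    cadence clipped to ``t_end``). ``closed_ends`` removes every Dirichlet
    boundary, which together with ``nr_core=1, nz>=8`` gives the zero-flux
    configuration whose solution must coincide with the well-mixed
    reaction system.

    Raises ``RuntimeError`` if the integrator fails or if any field
    undershoots zero by more than ``negativity_tol`` of its scale.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if mesh is None:
        mesh = build_mesh(geometry, nz=nz, nr_core=nr_core,
                          nr_sheath=nr_sheath)
    if output_times is None:
        output_times = [t for t in DEFAULT_OUTPUT_TIMES if t <= t_end]
        if output_times[-1] < t_end:
            output_times.append(t_end)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times[0] < 0 or output_times[-1] > t_end * (1 + 1e-12):
        raise ValueError("output times must lie in [0, t_end]")

    op_c = assemble_diffusion(mesh, geometry, params, "oxygen", closed_ends)
    op_v = assemble_diffusion(mesh, geometry, params, "vegf", closed_ends)
    _, delta, alpha, vm = _reaction_arrays(mesh, seeding, geometry, params)

    ncore, ntot = mesh.n_core, mesh.n_total
    n_init = np.repeat(seeding_profile(seeding, geometry, mesh.z_centers),
                       mesh.nr_core)
    y0 = np.concatenate([
        n_init,
        np.full(ntot, environment.c0),
        np.full(ntot, environment.v0),
    ])

    beta, n_max = params.beta, params.n_max
    M, c_half = params.M, params.c_half
    K, B, c_h = params.K, params.B, params.c_h
    c_bc, v_bc = environment.c_tissue, environment.v_tissue
    vm_hi = (vm + 1.0) / 2.0
    vm_lo = (vm - 1.0) / 2.0

    def rhs(t, y):
        n = y[:ncore]
        c = y[ncore:ncore + ntot]
        v = y[ncore + ntot:]
        cc = np.maximum(c[:ncore], 0.0)
        nn = np.maximum(n, 0.0)
        dn = beta * cc * n * (1.0 - n / n_max) - delta * n
        dc = op_c.rate(c, c_bc)
        dc[:ncore] -= nn * M * cc / (c_half + cc)
        dv = op_v.rate(v, v_bc) - K * v
        dv[:ncore] += alpha * nn * (vm_hi - vm_lo * np.tanh(B * (cc - c_h)))
        return np.concatenate([dn, dc, dv])

    sparsity = _jac_sparsity(mesh, op_c, op_v)
    atol = np.concatenate([
        np.full(ncore, atol_cells),
        np.full(2 * ntot, atol_conc),
    ])
    t_eval = output_times if output_times[0] == 0.0 else \
        np.concatenate([[0.0], output_times])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
                    rtol=rtol, atol=atol, jac_sparsity=sparsity)
    if not sol.success:
        raise RuntimeError(
            f"integrator failed at t = {sol.t[-1] if sol.t.size else 0:.1f} s:"
            f" {sol.message}")

    snapshots = []
    scale_c = max(environment.c0, environment.c_tissue, params.c_half)
    for k, t in enumerate(sol.t):
        if t not in output_times and not np.any(
                np.isclose(t, output_times, rtol=1e-12, atol=1e-9)):
            continue
        yk = sol.y[:, k]
        st = FieldState(t=float(t), n=yk[:ncore].copy(),
                        c=yk[ncore:ncore + ntot].copy(),
                        v=yk[ncore + ntot:].copy())
        if st.n.min() < -negativity_tol * max(n_init.max(), 1.0) or \
                st.c.min() < -negativity_tol * scale_c:
            raise RuntimeError(
                f"negative-concentration excursion beyond tolerance at "
                f"t = {t:.1f} s")
        snapshots.append(st)
    return SimulationResult(
        mesh=mesh, geometry=geometry, environment=environment,
        seeding=seeding, params=params,
        times=np.array([s.t for s in snapshots]), snapshots=snapshots,
        success=True, nfev=sol.nfev,
        solver_path="1d" if mesh.nr_core == 1 else "2d")


def simulate_axial_1d(
    geometry: ConstructGeometry,
    environment: BoundaryEnvironment,
    seeding: SeedingSpec,
    params: ParameterSet = REFERENCE_PARAMS,
    t_end: float = 24 * HOUR,
    output_times: Optional[Sequence[float]] = None,
    nz: int = 99,
    **kwargs,
) -> SimulationResult:
    """Fast 1D axial path for impermeable sheaths.

    With an impermeable sheath and r-uniform initial conditions the full
    axisymmetric problem admits z-only solutions (zero radial flux
    everywhere), so a single radial cell reproduces the 2D solution
    exactly up to integrator tolerance.
    """
    if not geometry.is_impermeable:
        raise ValueError("1D axial path requires an impermeable sheath "
                         "(Lp = 0 or porosity 0)")
    return simulate(geometry, environment, seeding, params, t_end,
                    output_times, nz=nz, nr_core=1, nr_sheath=0, **kwargs)
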