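"""Pointwise reaction terms and a zero-dimensional well-mixed reference
solver.

The well-mixed system is the reaction-only (zero-flux) limit of the full
transport model and serves as an independent oracle for the PDE solver:
with all spatial fluxes removed, every point of the construct evolves by

    dn/dt = beta c n (1 - n/n_max) - delta(n0) n
    dc/dt = - n M c / (c_half + c)
    dv/dt = alpha(n0) n f(c) - K v

with f the tanh hypoxia switch. All rate coefficients that depend on the
seeding density are evaluated at the fixed reference ``n0_ref`` (the
locally seeded density), not at the evolving density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import REFERENCE_PARAMS, ParameterSet

__all__ = ["LocalState", "cell_rate", "oxygen_uptake", "vegf_production",
           "wellmixed_solve", "WellMixedResult"]


@dataclass(frozen=True)
class LocalState:
    """Pointwise state (n, c, v) plus the fixed seeding reference density."""

    n: float
    c: float
    v: float
    n0_ref: float

    def __post_init__(self) -> None:
        if min(self.n, self.c, self.v, self.n0_ref) < 0:
            raise ValueError("state components must be non-negative")


def cell_rate(state: LocalState, params: ParameterSet = REFERENCE_PARAMS):
    """dn/dt: oxygen-limited logistic growth minus linear death."""
    growth = params.beta * state.c * state.n * (1.0 - state.n / params.n_max)
    return growth - params.death_rate(state.n0_ref) * state.n


def oxygen_uptake(state: LocalState, params: ParameterSet = REFERENCE_PARAMS):
    """Michaelis-Menten oxygen consumption rate, kg m^-3 s^-1 (>= 0)."""
    return state.n * params.M * state.c / (params.c_half + state.c)


def vegf_production(state: LocalState, params: ParameterSet = REFERENCE_PARAMS):
    """Hypoxia-regulated VEGF secretion rate G_v, kg m^-3 s^-1.

    Interpolates smoothly between alpha*n (normoxia, c >> c_h) and
    alpha*n*Vm (hypoxia, c << c_h) through a tanh switch of steepness B.
    """
    vm = params.regulation(state.n0_ref)
    alpha = params.vegf_baseline(state.n0_ref)
    switch = (vm + 1.0) / 2.0 - (vm - 1.0) / 2.0 * np.tanh(
        params.B * (state.c - params.c_h))
    return alpha * state.n * switch


@dataclass
class WellMixedResult:
    t: np.ndarray
    n: np.ndarray
    c: np.ndarray
    v: np.ndarray
    success: bool
    message: str = ""
    t_final: float = field(default=0.0)


def wellmixed_solve(
    n0: float,
    c0: float,
    v0: float,
    params: ParameterSet = REFERENCE_PARAMS,
    t_end: float = 24 * 3600.0,
    output_times: Optional[np.ndarray] = None,
    n0_ref: Optional[float] = None,
    fixed_oxygen: Optional[float] = None,
    rtol: float = 1e-6,
    atol_conc: float = 1e-12,
    atol_cells: float = 1.0,
) -> WellMixedResult:
    """Integrate the reaction-only (well-mixed) system with a stiff solver.

    Parameters
    ----------
    fixed_oxygen : if given, oxygen is clamped at this value and its
        consumption is switched off (used for stationary-state analysis
        where an external reservoir holds c constant).
    n0_ref : seeding density used to evaluate delta, alpha, Vm; defaults
        to ``n0``.
    """
    if min(n0, c0, v0) < 0:
        raise ValueError("initial values must be non-negative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    ref = n0 if n0_ref is None else n0_ref
    delta = float(params.death_rate(ref))
    alpha = float(params.vegf_baseline(ref))
    vm = float(params.regulation(ref))

    clamp = fixed_oxygen is not None

    def rhs(t, y):
        n, c, v = y
        cc = fixed_oxygen if clamp else max(c, 0.0)
        dn = params.beta * cc * n * (1.0 - n / params.n_max) - delta * n
        dc = 0.0 if clamp else -max(n, 0.0) * params.M * cc / (params.c_half + cc)
        switch = (vm + 1.0) / 2.0 - (vm - 1.0) / 2.0 * np.tanh(
            params.B * (cc - params.c_h))
        dv = alpha * max(n, 0.0) * switch - params.K * v
        return [dn, dc, dv]

    if output_times is None:
        output_times = np.linspace(0.0, t_end, 97)
    output_times = np.asarray(output_times, dtype=float)

    sol = solve_ivp(
        rhs, (0.0, t_end), [n0, c0 if not clamp else fixed_oxygen, v0],
        method="BDF", t_eval=output_times, rtol=rtol,
        atol=[atol_cells, atol_conc, atol_conc],
    )
    return WellMixedResult(
        t=sol.t, n=sol.y[0], c=sol.y[1], v=sol.y[2],
        success=sol.success, message=sol.message,
        t_final=float(sol.t[-1]) if sol.t.size else 0.0,
    )
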