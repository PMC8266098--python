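"""Closed-form diagnostics: characteristic timescales, oxygen penetration
length, stationary states and survival thresholds.

These quantities explain the simulated behaviour without running the PDE:
longitudinal diffusion times set how fast the tissue can resupply the
construct ends, the consumption/secretion times set how fast the cells
deplete oxygen and accumulate VEGF, the radial times (porous sheath) set
how fast the construct equilibrates with the surrounding tissue, and the
survival threshold c_tau = delta(n0)/beta decides whether a seeded
population can persist at a given sustained oxygen level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .geometry import ConstructGeometry
from .parameters import (BETA_PRACTICAL_ML_MOL_S, DELTA1_PRACTICAL_ML_CELL_S,
                         REFERENCE_PARAMS, ParameterSet, tortuosity)
from .units import (CELLS_ML_TO_M3, HOUR, NG_ML_TO_KG_M3, PCT_O2_TO_KG_M3,
                    PCT_O2_TO_MOL_ML)

__all__ = ["TimescaleReport", "StabilityReport", "timescales",
           "penetration_length", "stationary_analysis",
           "survival_threshold_density"]


@dataclass(frozen=True)
class TimescaleReport:
    """Characteristic times (s) and the oxygen penetration length (m).

    t_cL, t_vL : longitudinal diffusion times L^2/(4 D) of oxygen / VEGF
    t_cM : oxygen consumption time c0 / (M n0)
    t_vP : VEGF secretion time v_p / (alpha(n0) n0)
    t_vK : VEGF degradation time 1/K
    t_cR, t_vR : radial diffusion times across core plus porous sheath,
        R1^2/D_gel + tau^2 T^2/D_sheath
    """

    t_cL: float
    t_cM: float
    t_vL: float
    t_vP: float
    t_vK: float
    t_cR: float
    t_vR: float
    l_c: float
    n0: float
    v_p: float
    epsilon: float
    structure: str

    def to_frame(self) -> pd.DataFrame:
        names = ("t_cL", "t_cM", "t_vL", "t_vP", "t_vK", "t_cR", "t_vR")
        rows = [{"quantity": k, "seconds": getattr(self, k),
                 "hours": getattr(self, k) / HOUR} for k in names]
        rows.append({"quantity": "l_c", "seconds": float("nan"),
                     "hours": float("nan"), "metres": self.l_c,
                     "mm": self.l_c * 1e3})
        return pd.DataFrame(rows)


def timescales(params: ParameterSet = REFERENCE_PARAMS,
               geometry: Optional[ConstructGeometry] = None,
               n0: float = 1.78e14,
               v_p: float = 100.0 * NG_ML_TO_KG_M3,
               c0: float = 21.0 * PCT_O2_TO_KG_M3,
               c_tissue: float = 5.0 * PCT_O2_TO_KG_M3,
               epsilon: Optional[float] = None,
               structure: Optional[str] = None) -> TimescaleReport:
    """All characteristic times for a given scenario.

    ``v_p`` defaults to 100 ng/ml, roughly half the maximal VEGF
    concentration reached within 24 h. With n0 = 0 the consumption and
    secretion times are reported as infinite. The radial times use the
    tau^2-weighted sheath term exactly as defined.
    """
    if geometry is None:
        geometry = ConstructGeometry()
    eps = geometry.epsilon if epsilon is None else epsilon
    struct = geometry.structure if structure is None else structure
    tau = tortuosity(struct, eps) if eps > 0 else float("inf")
    L, R1, T = geometry.L, geometry.R1, geometry.T

    t_cL = L ** 2 / (4.0 * params.D_c_gel)
    t_vL = L ** 2 / (4.0 * params.D_v_gel)
    if n0 > 0:
        t_cM = c0 / (params.M * n0)
        t_vP = v_p / (float(params.vegf_baseline(n0)) * n0)
    else:
        t_cM = t_vP = float("inf")
    t_vK = 1.0 / params.K
    if math.isinf(tau):
        t_cR = t_vR = float("inf")
    else:
        t_cR = R1 ** 2 / params.D_c_gel + tau ** 2 * T ** 2 / params.D_c_sheath
        t_vR = R1 ** 2 / params.D_v_gel + tau ** 2 * T ** 2 / params.D_v_sheath
    l_c = penetration_length(params, c_tissue, n0) if n0 > 0 else float("inf")
    return TimescaleReport(t_cL=t_cL, t_cM=t_cM, t_vL=t_vL, t_vP=t_vP,
                           t_vK=t_vK, t_cR=t_cR, t_vR=t_vR, l_c=l_c,
                           n0=n0, v_p=v_p, epsilon=eps, structure=struct)


def penetration_length(params: ParameterSet, c_tissue: float,
                       n_ref: float) -> float:
    """Characteristic oxygen penetration length from the stumps (m).

    l_c = sqrt(c_tissue D_c_gel / (M n_ref)): the depth over which
    tissue-supplied oxygen survives consumption by cells at density
    n_ref before being exhausted.
    """
    if n_ref <= 0:
        raise ValueError("reference cell density must be positive")
    if c_tissue < 0:
        raise ValueError("tissue oxygen concentration must be non-negative")
    return math.sqrt(c_tissue * params.D_c_gel / (params.M * n_ref))


def survival_threshold_density(
        c_tissue_pct: float = 5.0,
        delta0: float = REFERENCE_PARAMS.delta0) -> float:
    """Seeding density (cells/ml) above which no long-term survival.

    Solves delta0 + delta1 n0 = beta c_tissue in *practical* units
    (beta = 220 ml mol^-1 s^-1, 1 %O2 = 1.32e-8 mol ml^-1,
    delta1 = 9.13e-14 ml cell^-1 s^-1). Above this density the survival
    threshold c_tau exceeds the sustained tissue oxygen level, so the
    population decays to extinction once the initial oxygen reserve is
    spent.
    """
    beta_c = BETA_PRACTICAL_ML_MOL_S * c_tissue_pct * PCT_O2_TO_MOL_ML
    n0 = (beta_c - delta0) / DELTA1_PRACTICAL_ML_CELL_S
    # below the zero-density threshold delta0/beta no seeding density
    # survives at all
    return max(n0, 0.0)


@dataclass(frozen=True)
class StabilityReport:
    """Stationary states of the local cell dynamics at sustained oxygen.

    c_tau = delta(n0)/beta is the survival threshold; for a sustained
    oxygen level c_ref the population converges to 0 if c_ref <= c_tau
    (the trivial state is stable) and to n_stat2 = n_max (1 - c_tau/c_ref)
    otherwise.
    """

    n0: float
    c_ref: float
    c_tau: float
    c_tau_pct: float
    n_stat2: float
    stable_state: str          # "extinction" | "persistence"
    n0_threshold_cells_ml: float
    n0_threshold_si: float


def stationary_analysis(params: ParameterSet = REFERENCE_PARAMS,
                        n0: float = 1.78e14,
                        c_ref: float = 5.0 * PCT_O2_TO_KG_M3
                        ) -> StabilityReport:
    """Survival threshold, stationary density and stability at fixed c."""
    if n0 < 0:
        raise ValueError("seeding density must be non-negative")
    delta = float(params.death_rate(n0))
    c_tau = delta / params.beta
    if c_ref > c_tau:
        n_stat2 = params.n_max * (1.0 - c_tau / c_ref)
        stable = "persistence"
    else:
        n_stat2 = 0.0
        stable = "extinction"
    thr_ml = survival_threshold_density(c_ref / PCT_O2_TO_KG_M3,
                                        delta0=params.delta0)
    return StabilityReport(
        n0=n0, c_ref=c_ref, c_tau=c_tau,
        c_tau_pct=c_tau / PCT_O2_TO_KG_M3,
        n_stat2=n_stat2, stable_state=stable,
        n0_threshold_cells_ml=thr_ml,
        n0_threshold_si=thr_ml * CELLS_ML_TO_M3)
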