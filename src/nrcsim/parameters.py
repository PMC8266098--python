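"""Model parameters in SI units, seeding-density-dependent coefficients and
tortuosity models.

The kinetic picture: therapeutic cells in a collagen gel grow logistically
with a rate proportional to the local oxygen concentration, die at a rate
``delta = delta0 + delta1 * n0`` that increases with the *seeded* density
``n0`` (initial crowding shortens later survival), consume oxygen with
Michaelis-Menten kinetics, and secrete VEGF at a baseline rate
``alpha(n0)`` that is upregulated by a factor approaching ``Vm(n0)`` when
oxygen falls below the hypoxia threshold ``c_h``. The annular sheath is an
acellular porous medium whose effective diffusivity is
``D * epsilon / tau(epsilon)``.

Note on ``delta1``: the source tables print two mutually inconsistent
values (9.13e-23 m^3/cell/s in SI against 9.13e-14 ml/cell/s in practical
units, i.e. 9.13e-20 m^3/cell/s). This module adopts 9.13e-20 m^3/cell/s,
the only value consistent with the survival-threshold concentration
c_tau = 16.43 %O2 at n0 = 4e8 cells/ml and the long-term survival limit
n0 ~ 3.5e7 cells/ml; both printed values are kept in the provenance table.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .units import CELLS_ML_TO_M3, PCT_O2_TO_KG_M3

__all__ = [
    "ParameterSet",
    "REFERENCE_PARAMS",
    "cell_death_rate",
    "vegf_baseline_rate",
    "regulation_factor",
    "tortuosity",
    "provenance_table",
    "BETA_PRACTICAL_ML_MOL_S",
    "DELTA1_PRACTICAL_ML_CELL_S",
]

#: practical-unit growth rate, ml mol^-1 s^-1 (used only for the
#: survival-threshold seeding density, which is defined in practical units)
BETA_PRACTICAL_ML_MOL_S = 220.0
#: practical-unit density-dependent death coefficient, ml cell^-1 s^-1
DELTA1_PRACTICAL_ML_CELL_S = 9.13e-14
#: SI twin of the practical delta1 (adopted; see module docstring)
DELTA1_SI = DELTA1_PRACTICAL_ML_CELL_S / 1e-6 * 1e-12  # = 9.13e-20 m^3/cell/s
#: SI value as printed in the source table (inconsistent, not used)
DELTA1_SI_AS_PRINTED = 9.13e-23


@dataclass(frozen=True)
class ParameterSet:
    """Immutable registry of kinetic and transport constants (SI units).

    Attributes
    ----------
    beta : cell growth rate, m^3 kg^-1 s^-1
    n_max : maximum (carrying-capacity) cell density, cell m^-3
    delta0, delta1 : death rate intercept (s^-1) and seeding-density slope
        (m^3 cell^-1 s^-1)
    D_c_gel, D_v_gel : oxygen / VEGF diffusivity in the collagen gel, m^2 s^-1
    M : maximal oxygen metabolic rate per cell, kg cell^-1 s^-1
    c_half : Michaelis constant of oxygen uptake, kg m^-3
    D_c_sheath, D_v_sheath : free diffusivities in the water-filled sheath
        pores, m^2 s^-1
    K : VEGF first-order degradation rate, s^-1
    alpha0, alpha1, alpha2 : baseline VEGF production polynomial in n0
    Vm0, Vm1 : hypoxic upregulation factor, linear in n0
    B : steepness of the tanh hypoxia switch, m^3 kg^-1
    c_h : hypoxia threshold, kg m^-3
    lambda_c, lambda_v : gel/sheath partition coefficients (both 1, so the
        interface condition reduces to concentration continuity)
    """

    beta: float = 7.10e-3
    n_max: float = 4.00e14
    delta0: float = 1.13e-5
    delta1: float = DELTA1_SI
    D_c_gel: float = 4.50e-10
    M: float = 6.20e-21
    c_half: float = 2.07e-4
    D_c_sheath: float = 2.63e-9
    D_v_gel: float = 1.13e-10
    K: float = 2.99e-5
    D_v_sheath: float = 1.37e-10
    alpha0: float = 2.17e-23
    alpha1: float = 3.10e-38
    alpha2: float = 2.60e-52
    Vm0: float = 5.22
    Vm1: float = -9.04e-15
    B: float = 4.35e5
    c_h: float = 1.95e-3
    lambda_c: float = 1.0
    lambda_v: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_max", "D_c_gel", "c_half", "D_c_sheath", "D_v_gel",
                     "D_v_sheath", "B", "c_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        # rates may be zeroed to isolate individual processes
        for name in ("beta", "M", "K", "delta0", "delta1"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if not self.c_half < self.c_h:
            raise ValueError("c_half must lie below the hypoxia threshold c_h")

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    # -- seeding-density-dependent coefficients ---------------------------
    def death_rate(self, n0):
        """delta(n0) = delta0 + delta1 * n0, in s^-1 (n0 in cell m^-3)."""
        n0 = np.asarray(n0, dtype=float)
        if np.any(n0 < 0):
            raise ValueError("seeding density must be non-negative")
        return self.delta0 + self.delta1 * n0

    def vegf_baseline(self, n0):
        """alpha(n0) = alpha0 + alpha1*n0 + alpha2*n0^2, kg cell^-1 s^-1."""
        n0 = np.asarray(n0, dtype=float)
        if np.any(n0 < 0):
            raise ValueError("seeding density must be non-negative")
        return self.alpha0 + self.alpha1 * n0 + self.alpha2 * n0 ** 2

    def regulation(self, n0):
        """Vm(n0) = Vm0 + Vm1 * n0 (dimensionless, decreasing in n0)."""
        n0 = np.asarray(n0, dtype=float)
        if np.any(n0 < 0):
            raise ValueError("seeding density must be non-negative")
        vm = self.Vm0 + self.Vm1 * n0
        if np.any(vm < 1.0):
            warnings.warn(
                "Vm(n0) < 1: hypoxic 'upregulation' becomes downregulation "
                "outside the fitted seeding-density range",
                stacklevel=2,
            )
        return vm


REFERENCE_PARAMS = ParameterSet()

#: named presets; overrides go through ParameterSet.replace / config files
PRESETS = {"reference": REFERENCE_PARAMS}


# module-level functional forms mirroring the library surface -------------

def cell_death_rate(n0, params: ParameterSet = REFERENCE_PARAMS):
    """Death rate delta(n0) in s^-1 for a seeding density n0 in cell m^-3."""
    return params.death_rate(n0)


def vegf_baseline_rate(n0, params: ParameterSet = REFERENCE_PARAMS):
    """Baseline VEGF production alpha(n0) in kg cell^-1 s^-1."""
    return params.vegf_baseline(n0)


def regulation_factor(n0, params: ParameterSet = REFERENCE_PARAMS):
    """Hypoxic upregulation factor Vm(n0) (dimensionless)."""
    return params.regulation(n0)


# -- tortuosity models ----------------------------------------------------

STRUCTURES = ("spheres", "cylinders", "tubes")


def tortuosity(structure: str, epsilon: float) -> float:
    """Tortuosity tau(epsilon) of an archetypal porous structure.

    ``spheres`` : overlapping spheres, tau = 1 - ln(eps)/2
    ``cylinders`` : overlapping cylinders, tau = 3 eps / (4 eps - 1),
        valid only for eps > 0.25 (singular at eps = 0.25)
    ``tubes`` : disordered tubes, tau = eps / (1 - (1-eps)^(1/3))

    All models satisfy tau(1) = 1 (fully open medium) and tau >= 1 on
    their validity domain.
    """
    eps = float(epsilon)
    if not 0.0 < eps <= 1.0:
        raise ValueError(f"porosity must lie in (0, 1], got {eps!r}")
    if structure == "spheres":
        return 1.0 - 0.5 * math.log(eps)
    if structure == "cylinders":
        if eps <= 0.25:
            raise ValueError(
                "cylinder tortuosity model is singular at eps = 0.25; "
                "valid only for eps > 0.25"
            )
        return 3.0 * eps / (4.0 * eps - 1.0)
    if structure == "tubes":
        if eps == 1.0:
            return 1.0
        return eps / (1.0 - (1.0 - eps) ** (1.0 / 3.0))
    raise ValueError(f"unknown porous structure {structure!r}; "
                     f"expected one of {STRUCTURES}")


# -- provenance -----------------------------------------------------------

def provenance_table():
    """Active SI parameter values with practical-unit twins and notes.

    Returns a list of dicts suitable for CSV export (``params dump``).
    """
    p = REFERENCE_PARAMS
    rows = [
        ("beta", p.beta, "m^3 kg^-1 s^-1", "220 ml mol^-1 s^-1",
         "cell growth rate"),
        ("n_max", p.n_max, "cell m^-3", "4.00e8 cell ml^-1",
         "maximum cell density"),
        ("delta0", p.delta0, "s^-1", "1.13e-5 s^-1", "baseline death rate"),
        ("delta1", p.delta1, "m^3 cell^-1 s^-1", "9.13e-14 ml cell^-1 s^-1",
         "adopted from the practical-unit value; the printed SI value "
         f"{DELTA1_SI_AS_PRINTED:g} is inconsistent with it and with the "
         "survival thresholds"),
        ("D_c_gel", p.D_c_gel, "m^2 s^-1", "4.50e-6 cm^2 s^-1",
         "oxygen diffusivity in collagen gel"),
        ("M", p.M, "kg cell^-1 s^-1", "2.00e-19 mol cell^-1 s^-1",
         "maximal oxygen metabolic rate"),
        ("c_half", p.c_half, "kg m^-3", "0.51 %O2",
         "half-maximal oxygen concentration (modelling value adopted)"),
        ("D_c_sheath", p.D_c_sheath, "m^2 s^-1", "2.63e-5 cm^2 s^-1",
         "oxygen diffusivity in water-filled sheath pores"),
        ("D_v_gel", p.D_v_gel, "m^2 s^-1", "1.13e-6 cm^2 s^-1",
         "VEGF diffusivity in collagen gel"),
        ("K", p.K, "s^-1", "2.99e-5 s^-1", "VEGF degradation rate"),
        ("D_v_sheath", p.D_v_sheath, "m^2 s^-1", "1.37e-6 cm^2 s^-1",
         "VEGF diffusivity in water-filled sheath pores"),
        ("alpha0", p.alpha0, "kg cell^-1 s^-1", "2.17e-11 ng cell^-1 s^-1",
         "VEGF baseline production, intercept"),
        ("alpha1", p.alpha1, "kg m^3 cell^-2 s^-1",
         "3.10e-20 ng ml cell^-2 s^-1", "VEGF baseline production, linear"),
        ("alpha2", p.alpha2, "kg m^6 cell^-3 s^-1",
         "2.60e-28 ng ml^2 cell^-3 s^-1",
         "VEGF baseline production, quadratic"),
        ("Vm0", p.Vm0, "-", "5.22", "hypoxic upregulation, intercept"),
        ("Vm1", p.Vm1, "m^3 cell^-1", "-9.04e-9 ml cell^-1",
         "hypoxic upregulation, slope"),
        ("B", p.B, "m^3 kg^-1", "(modelling value used verbatim)",
         "tanh transition steepness"),
        ("c_h", p.c_h, "kg m^-3", "4.77 %O2", "hypoxia threshold"),
        ("lambda_c", p.lambda_c, "-", "1", "O2 partition coefficient"),
        ("lambda_v", p.lambda_v, "-", "1", "VEGF partition coefficient"),
        ("pct_O2_to_kg_m3", PCT_O2_TO_KG_M3, "kg m^-3 per %O2", "-",
         "unit pairing (effective O2 molar mass ~31 g/mol)"),
        ("cells_ml_to_m3", CELLS_ML_TO_M3, "m^-3 per ml^-1", "-",
         "unit pairing"),
    ]
    return [
        {"name": n, "value_si": v, "si_units": u, "practical": pr, "note": note}
        for n, v, u, pr, note in rows
    ]
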