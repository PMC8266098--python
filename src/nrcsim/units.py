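"""Unit conversions between practical and modelling (SI) unit systems.

All internal computation is carried out in SI ("modelling") units:
concentrations in kg m^-3, cell densities in cell m^-3, lengths in m,
times in s. Practical units (%O2, ng/ml, cells/ml, hours) appear only at
configuration and reporting boundaries.

The %O2 <-> kg m^-3 pairing follows the tabulated correspondence
(1 %O2 = 4.10e-4 kg m^-3, implying an effective O2 molar mass of about
31 g/mol); it is used verbatim rather than re-derived from 32 g/mol so
that every converted quantity stays consistent with the tabulated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

#: kg m^-3 of dissolved oxygen per %O2 of gas-phase equilibrium
PCT_O2_TO_KG_M3 = 4.10e-4
#: mol ml^-1 of dissolved oxygen per %O2 (practical-unit twin)
PCT_O2_TO_MOL_ML = 1.32e-8
#: kg m^-3 per ng ml^-1 (VEGF)
NG_ML_TO_KG_M3 = 1.00e-6
#: cell m^-3 per cell ml^-1
CELLS_ML_TO_M3 = 1.0e6

HOUR = 3600.0  # s


def _check_nonneg(value: float, what: str) -> None:
    if value < 0:
        raise ValueError(f"{what} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class UnitSystem:
    """Registry of the linear conversion factors between unit systems."""

    oxygen_percent_to_kg_per_m3: float = PCT_O2_TO_KG_M3
    vegf_ng_per_ml_to_kg_per_m3: float = NG_ML_TO_KG_M3
    cells_per_ml_to_per_m3: float = CELLS_ML_TO_M3

    def oxygen_pct_to_si(self, pct: float) -> float:
        _check_nonneg(pct, "oxygen concentration (%O2)")
        return pct * self.oxygen_percent_to_kg_per_m3

    def oxygen_si_to_pct(self, kg_m3: float) -> float:
        _check_nonneg(kg_m3, "oxygen concentration (kg/m^3)")
        return kg_m3 / self.oxygen_percent_to_kg_per_m3

    def vegf_ngml_to_si(self, ngml: float) -> float:
        _check_nonneg(ngml, "VEGF concentration (ng/ml)")
        return ngml * self.vegf_ng_per_ml_to_kg_per_m3

    def vegf_si_to_ngml(self, kg_m3: float) -> float:
        _check_nonneg(kg_m3, "VEGF concentration (kg/m^3)")
        return kg_m3 / self.vegf_ng_per_ml_to_kg_per_m3

    def cells_ml_to_si(self, per_ml: float) -> float:
        _check_nonneg(per_ml, "cell density (cells/ml)")
        return per_ml * self.cells_per_ml_to_per_m3

    def cells_si_to_ml(self, per_m3: float) -> float:
        _check_nonneg(per_m3, "cell density (cells/m^3)")
        return per_m3 / self.cells_per_ml_to_per_m3


UNITS = UnitSystem()


def convert_oxygen(pct: float) -> float:
    """%O2 -> kg m^-3 (linear, via the tabulated pairing)."""
    return UNITS.oxygen_pct_to_si(pct)


def convert_oxygen_inverse(kg_m3: float) -> float:
    """kg m^-3 -> %O2."""
    return UNITS.oxygen_si_to_pct(kg_m3)
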