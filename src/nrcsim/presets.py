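"""Built-in scenario presets for the standard design experiments.

Each preset is a fully resolved :class:`~nrcsim.config.Scenario` covering
one design question: impermeable baseline heatmaps, seeding-density
sweeps, culture and tissue condition sweeps, porous and partially porous
sheaths, sheath-material grids and non-uniform seeding strategies.
"""

from __future__ import annotations

import numpy as np

from .config import Scenario, SweepSpec
from .geometry import ConstructGeometry, SeedingSpec
from .units import CELLS_ML_TO_M3, HOUR

__all__ = ["PRESETS", "PRESET_NOTES", "get_preset", "list_presets",
           "N0_SWEEP_DEFAULT"]

#: default uniform-seeding sweep grid: 40 points on [1e7, 4e8] cells/ml
N0_SWEEP_DEFAULT = tuple(np.linspace(1.0e13, 4.0e14, 40))

_IMPERMEABLE = ConstructGeometry(Lp=0.0)
_POROUS = ConstructGeometry(Lp=7.5e-3, epsilon=0.8, structure="spheres",
                            T=2.5e-4)
_BASELINE_N0 = 1.78e8 * CELLS_ML_TO_M3


def _presets():
    p = {}
    p["impermeable-baseline"] = Scenario(
        name="impermeable-baseline",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        note="heatmaps of n, c, v over 24 h, impermeable sheath, "
             "n0 = 1.78e8 cells/ml")
    p["impermeable-n0-sweep"] = Scenario(
        name="impermeable-n0-sweep",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        t_end=120 * HOUR,
        output_times=tuple(h * HOUR for h in (0, 12, 24, 120)),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT,
                        times_h=(12.0, 24.0, 120.0)),
        note="seeding-density sweep, impermeable sheath; 120 h points are "
             "extrapolations beyond the fitted 24 h window")
    p["culture-c0-sweep"] = Scenario(
        name="culture-c0-sweep",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT, times_h=(24.0,)),
        note="repeat the n0 sweep for c0 in [1, 21] %O2 (set "
             "environment.c0 per run)")
    p["culture-v0-sweep"] = Scenario(
        name="culture-v0-sweep",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT, times_h=(24.0,)),
        note="repeat the n0 sweep for v0 in [0, 1] ng/ml")
    p["tissue-conditions-sweep"] = Scenario(
        name="tissue-conditions-sweep",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT, times_h=(24.0,)),
        note="repeat the n0 sweep for c_tissue in [1, 10] %O2 and "
             "v_tissue in [0, 1] ng/ml")
    p["porous-baseline"] = Scenario(
        name="porous-baseline",
        geometry=_POROUS,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        note="heatmaps over 24 h, fully porous sheath, eps = 0.8, "
             "spheres, T = 0.25 mm")
    p["porosity-sweep"] = Scenario(
        name="porosity-sweep",
        geometry=_POROUS,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT,
                        times_h=(0.5, 1.0, 12.0, 24.0)),
        note="metrics vs n0 for eps in {0, 0.1, 0.4, 0.8}, spheres, "
             "T = 0.25 mm (eps = 0 is the impermeable case)")
    p["material-grid"] = Scenario(
        name="material-grid",
        geometry=_POROUS,
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="epsilon",
                        values=tuple(np.arange(0.1, 1.001, 0.1)),
                        metrics=("n_bar", "v_sd"), times_h=(24.0,)),
        note="argmax/max over n0 as functions of porosity, structure "
             "(spheres/cylinders/tubes) and thickness T in [0.25, 1.5] mm")
    p["partial-porosity"] = Scenario(
        name="partial-porosity",
        geometry=_POROUS.replace(Lp=1.0e-3),
        seeding=SeedingSpec.uniform(_BASELINE_N0),
        sweep=SweepSpec(var="n0", values=N0_SWEEP_DEFAULT,
                        times_h=(0.5, 24.0)),
        note="partially porous sheath, Lp in {0, 1, 3} mm, eps = 0.8, "
             "T = 0.25 mm")
    p["nonuniform-seeding"] = Scenario(
        name="nonuniform-seeding",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.three_zone(n0_tot=2.0e5, zeta=3.0),
        note="three-zone seeding heatmaps, zeta in {1, 3}, n0_tot in "
             "{1e5, 5e5} cells, impermeable and porous sheaths")
    p["zeta-sweep"] = Scenario(
        name="zeta-sweep",
        geometry=_IMPERMEABLE,
        seeding=SeedingSpec.three_zone(n0_tot=3.0e5, zeta=1.0),
        sweep=SweepSpec(var="zeta", values=tuple(np.linspace(0.0, 3.0, 13)),
                        metrics=("n_tot", "v_bar", "v_sd"),
                        times_h=(12.0, 24.0)),
        note="repartition-factor sweep for n0_tot in {5e4 ... 5e5} cells, "
             "impermeable and porous sheaths")
    return p


PRESETS = _presets()

PRESET_NOTES = {name: s.note for name, s in PRESETS.items()}


def get_preset(name: str) -> Scenario:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(sorted(PRESETS))}") from None


def list_presets():
    """(name, description) pairs for every built-in preset."""
    return [(name, PRESET_NOTES[name]) for name in sorted(PRESETS)]
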