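"""Scenario configuration: a fully resolved, serialisable description of
one simulation or sweep.

Configs round-trip through YAML (config -> Scenario -> config is the
identity on resolved values). Concentrations may be given in practical
units in YAML (``c0_pct``, ``v0_ngml``, ``n0_cells_ml`` ...) and are
resolved to SI on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .geometry import ConstructGeometry, SeedingSpec
from .parameters import REFERENCE_PARAMS, ParameterSet
from .solver import BoundaryEnvironment, DEFAULT_OUTPUT_TIMES
from .units import CELLS_ML_TO_M3, HOUR, NG_ML_TO_KG_M3, PCT_O2_TO_KG_M3

__all__ = ["Scenario", "SweepSpec", "scenario_from_dict", "scenario_to_dict"]


@dataclass(frozen=True)
class SweepSpec:
    """Optional sweep attached to a scenario.

    ``var`` is one of n0 (uniform seeding density), zeta, n0_tot or
    epsilon; ``values`` are in SI units (cell m^-3 for densities).
    """

    var: str = "n0"
    values: tuple = ()
    metrics: tuple = ("n_bar", "v_bar", "v_sd")
    times_h: tuple = (12.0, 24.0)

    def __post_init__(self) -> None:
        if self.var not in ("n0", "zeta", "n0_tot", "epsilon"):
            raise ValueError(f"unknown sweep variable {self.var!r}")
        if len(self.values) == 0:
            raise ValueError("sweep grid must not be empty")


@dataclass(frozen=True)
class Scenario:
    """Named, fully resolved simulation setup."""

    name: str = "custom"
    geometry: ConstructGeometry = field(default_factory=ConstructGeometry)
    environment: BoundaryEnvironment = field(
        default_factory=BoundaryEnvironment)
    seeding: SeedingSpec = field(
        default_factory=lambda: SeedingSpec.uniform(1.78e14))
    params: ParameterSet = REFERENCE_PARAMS
    t_end: float = 24 * HOUR
    output_times: tuple = tuple(t for t in DEFAULT_OUTPUT_TIMES
                                if t <= 24 * HOUR)
    nz: int = 99
    nr_core: int = 12
    nr_sheath: int = 8
    sweep: Optional[SweepSpec] = None
    note: str = ""

    def replace(self, **changes) -> "Scenario":
        return dataclasses.replace(self, **changes)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return scenario_to_dict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return scenario_from_dict(d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"invalid scenario config in {path}")
        return cls.from_dict(d)


def _plain(obj) -> dict:
    return {k: (float(v) if isinstance(v, (int, float)) and
                not isinstance(v, bool) else v)
            for k, v in dataclasses.asdict(obj).items()}


def scenario_to_dict(s: Scenario) -> dict:
    d = {
        "name": s.name,
        "geometry": _plain(s.geometry),
        "environment": _plain(s.environment),
        "seeding": _plain(s.seeding),
        "t_end": float(s.t_end),
        "output_times": [float(t) for t in s.output_times],
        "mesh": {"nz": s.nz, "nr_core": s.nr_core, "nr_sheath": s.nr_sheath},
        "note": s.note,
    }
    overrides = {k: float(getattr(s.params, k))
                 for k in (f.name for f in dataclasses.fields(ParameterSet))
                 if getattr(s.params, k) != getattr(REFERENCE_PARAMS, k)}
    if overrides:
        d["params"] = overrides
    if s.sweep is not None:
        d["sweep"] = {"var": s.sweep.var,
                      "values": [float(v) for v in s.sweep.values],
                      "metrics": list(s.sweep.metrics),
                      "times_h": [float(t) for t in s.sweep.times_h]}
    return d


_ENV_PRACTICAL = {
    "c0_pct": ("c0", PCT_O2_TO_KG_M3),
    "c_tissue_pct": ("c_tissue", PCT_O2_TO_KG_M3),
    "v0_ngml": ("v0", NG_ML_TO_KG_M3),
    "v_tissue_ngml": ("v_tissue", NG_ML_TO_KG_M3),
}


def scenario_from_dict(d: dict) -> Scenario:
    geo = ConstructGeometry(**d.get("geometry", {}))
    env_d = dict(d.get("environment", {}))
    for key, (target, factor) in _ENV_PRACTICAL.items():
        if key in env_d:
            env_d[target] = float(env_d.pop(key)) * factor
    env = BoundaryEnvironment(**env_d)
    seed_d = dict(d.get("seeding", {}))
    if "n0_cells_ml" in seed_d:
        seed_d["n0"] = float(seed_d.pop("n0_cells_ml")) * CELLS_ML_TO_M3
    seed = SeedingSpec(**seed_d)
    params = REFERENCE_PARAMS.replace(**d.get("params", {}))
    mesh = d.get("mesh", {})
    sweep = None
    if "sweep" in d and d["sweep"]:
        sw = d["sweep"]
        sweep = SweepSpec(var=sw.get("var", "n0"),
                          values=tuple(float(v) for v in sw["values"]),
                          metrics=tuple(sw.get("metrics",
                                               ("n_bar", "v_bar", "v_sd"))),
                          times_h=tuple(sw.get("times_h", (12.0, 24.0))))
    t_end = float(d.get("t_end", 24 * HOUR))
    out = d.get("output_times")
    if out is None:
        out = [t for t in DEFAULT_OUTPUT_TIMES if t <= t_end]
        if out[-1] < t_end:
            out.append(t_end)
    return Scenario(
        name=d.get("name", "custom"), geometry=geo, environment=env,
        seeding=seed, params=params, t_end=t_end,
        output_times=tuple(float(t) for t in out),
        nz=int(mesh.get("nz", 99)), nr_core=int(mesh.get("nr_core", 12)),
        nr_sheath=int(mesh.get("nr_sheath", 8)), sweep=sweep,
        note=d.get("note", ""))
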