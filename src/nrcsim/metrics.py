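"""Volume-averaged design metrics over the collagen core and the
sweep/argmax machinery used to rank seeding and sheath designs.

The design metrics are the volume averages of the cell density (n_bar),
oxygen (c_bar) and VEGF (v_bar) over the core, the population standard
deviation of VEGF (v_sd, an indirect measure of VEGF gradients at the
construct scale), and the total viable cell number n_tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .solver import FieldState, SimulationResult

__all__ = ["volume_metrics", "volume_metrics_series", "argmax_sweep",
           "SweepResult", "golden_section_max", "design_report"]

METRICS = ("n_bar", "c_bar", "v_bar", "v_sd", "n_tot")


def volume_metrics(state: FieldState, mesh) -> Dict[str, float]:
    """Volume-weighted core metrics for one snapshot.

    v_sd is the population standard deviation (the variance integral is
    normalised by the full core volume, not by V - 1 cell).
    """
    w = mesh.core_volumes.reshape(-1)
    V = w.sum()
    n = state.n
    c = state.c[: mesh.n_core]
    v = state.v[: mesh.n_core]
    n_bar = float(w @ n / V)
    c_bar = float(w @ c / V)
    v_bar = float(w @ v / V)
    v_sd = float(math.sqrt(max(w @ (v - v_bar) ** 2 / V, 0.0)))
    return {
        "t": state.t,
        "n_bar": n_bar, "c_bar": c_bar, "v_bar": v_bar, "v_sd": v_sd,
        "n_tot": n_bar * V,
        "n_min": float(n.min()), "n_max": float(n.max()),
        "c_min": float(c.min()), "c_max": float(c.max()),
        "v_min": float(v.min()), "v_max": float(v.max()),
    }


def volume_metrics_series(result: SimulationResult) -> pd.DataFrame:
    """Metric time series (one row per stored snapshot)."""
    return pd.DataFrame([volume_metrics(s, result.mesh)
                         for s in result.snapshots])


def golden_section_max(f: Callable[[float], float], a: float, b: float,
                       xatol: float) -> Tuple[float, float]:
    """Golden-section search for the maximum of a unimodal f on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > xatol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
    x = 0.5 * (a + b)
    return x, max(f1, f2)


@dataclass
class SweepResult:
    """Grid sweep of a scenario parameter plus refined per-metric optima."""

    sweep_var: str
    values: np.ndarray
    table: pd.DataFrame              # tidy: value, t, n_bar, ..., n_tot
    optima: Dict[Tuple[str, float], Dict[str, float]] = field(
        default_factory=dict)       # (metric, time) -> argmax/max/bracket

    def metric_curve(self, metric: str, time: float) -> pd.DataFrame:
        sel = self.table[np.isclose(self.table["t"], time)]
        return sel.sort_values("value")[["value", metric]]

    def optimum(self, metric: str, time: float) -> Dict[str, float]:
        key = min(self.optima,
                  key=lambda k: (k[0] != metric, abs(k[1] - time)))
        if key[0] != metric or not math.isclose(key[1], time,
                                                rel_tol=1e-9, abs_tol=1e-3):
            raise KeyError(f"no refined optimum for ({metric}, {time})")
        return self.optima[key]


def argmax_sweep(
    run_for_value: Callable[[float], SimulationResult],
    values: Sequence[float],
    times: Sequence[float],
    metrics: Sequence[str] = ("n_bar", "v_bar", "v_sd"),
    sweep_var: str = "n0",
    refine_resolution: Optional[float] = None,
    refine: bool = True,
) -> SweepResult:
    """Sweep a scenario parameter, locate and refine per-metric argmaxima.

    ``run_for_value`` maps one swept value (e.g. a uniform seeding density
    in cell m^-3) to a completed simulation whose snapshots include every
    requested evaluation time. The grid argmax of each (metric, time)
    pair is refined by golden-section search between its bracketing grid
    neighbours, down to ``refine_resolution`` in the swept variable
    (default: grid spacing / 4). Simulations are cached by value, and any
    simulation failure aborts the sweep with the offending value in the
    error message.
    """
    values = np.asarray(sorted(float(v) for v in values))
    if values.size == 0:
        raise ValueError("empty sweep grid")
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    cache: Dict[float, pd.DataFrame] = {}

    def metrics_for(value: float) -> pd.DataFrame:
        if value not in cache:
            try:
                res = run_for_value(value)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep aborted: simulation failed for "
                    f"{sweep_var} = {value:g}: {exc}") from exc
            cache[value] = volume_metrics_series(res)
        return cache[value]

    rows: List[pd.DataFrame] = []
    for v in values:
        df = metrics_for(v).copy()
        df.insert(0, "value", v)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    def metric_at(value: float, metric: str, time: float) -> float:
        df = metrics_for(value)
        i = int(np.argmin(np.abs(df["t"].to_numpy() - time)))
        if not math.isclose(df["t"].iloc[i], time, rel_tol=1e-9, abs_tol=1.0):
            raise KeyError(f"no snapshot at t = {time} s")
        return float(df[metric].iloc[i])

    optima: Dict[Tuple[str, float], Dict[str, float]] = {}
    if values.size > 1:
        spacing = float(np.min(np.diff(values)))
    else:
        spacing = 0.0
    xatol = refine_resolution if refine_resolution is not None \
        else spacing / 4.0

    for metric in metrics:
        for time in times:
            ys = np.array([metric_at(v, metric, time) for v in values])
            k = int(np.argmax(ys))
            lo = values[max(k - 1, 0)]
            hi = values[min(k + 1, values.size - 1)]
            entry = {"argmax_grid": float(values[k]),
                     "max_grid": float(ys[k]),
                     "bracket_lo": float(lo), "bracket_hi": float(hi)}
            if refine and hi > lo and xatol > 0:
                x, fx = golden_section_max(
                    lambda v: metric_at(v, metric, time), lo, hi, xatol)
                if fx >= ys[k]:
                    entry.update(argmax=float(x), max=float(fx))
                else:  # refinement never degrades the grid optimum
                    entry.update(argmax=float(values[k]), max=float(ys[k]))
            else:
                entry.update(argmax=float(values[k]), max=float(ys[k]))
            optima[(metric, float(time))] = entry

    return SweepResult(sweep_var=sweep_var, values=values, table=table,
                       optima=optima)


def design_report(sweeps: Dict[str, SweepResult], metric: str = "n_bar",
                  time: Optional[float] = None) -> pd.DataFrame:
    """Tabulate refined optima of several sweeps, ranked by one metric.

    ``sweeps`` maps a design label (e.g. "eps=0.8, spheres, T=0.25mm") to
    its SweepResult. Rows are sorted by the maximal value of ``metric``
    (descending) at the requested time (default: the latest time present).
    """
    rows = []
    for label, sw in sweeps.items():
        times = sorted({t for (_m, t) in sw.optima})
        t_sel = time if time is not None else times[-1]
        for (m, t), entry in sw.optima.items():
            if not math.isclose(t, t_sel, rel_tol=1e-9, abs_tol=1.0):
                continue
            rows.append({"design": label, "metric": m, "t": t,
                         "argmax": entry["argmax"], "max": entry["max"]})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    order = df[df["metric"] == metric].sort_values(
        "max", ascending=False)["design"]
    df["design"] = pd.Categorical(df["design"], categories=list(order),
                                  ordered=True)
    return df.sort_values(["design", "metric"]).reset_index(drop=True)
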