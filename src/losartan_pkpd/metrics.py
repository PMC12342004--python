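"""Pharmacokinetic summary metrics: Cmax, tmax, terminal half-life, AUC.

Metrics are computed on a dense :class:`~losartan_pkpd.model.SimulationResult`
or on plain ``(time, concentration)`` arrays from an observed dataset.  AUC
for simulations is the terminal value of the integrated AUC state (the
concentration integrated alongside the amounts, not a quadrature
afterthought); for observed arrays it falls back to the trapezoid rule.

The terminal half-life follows the semilogarithmic regression convention:
ordinary least squares of ln C on t over a terminal window, with
t_half = ln 2 / |slope|.  For exactly two points this reduces to
``(t2 - t1) * ln 2 / ln(C1 / C2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .model import SimulationResult

__all__ = [
    "PKSummary",
    "SCHEDULE_H",
    "cmax_tmax",
    "auc",
    "auc_ratio",
    "terminal_half_life",
    "summarize",
    "UndefinedHalfLifeError",
]

#: Blood-sampling schedule (h) of the clinical profiles the model emulates.
SCHEDULE_H = (0.0, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)


class UndefinedHalfLifeError(RuntimeError):
    """Terminal slope non-negative or too few positive points in the window."""


@dataclass
class PKSummary:
    """Per-analyte PK parameters plus the losartan/E-3174 AUC ratio.

    ``cmax`` in nM, ``tmax`` and ``t_half`` in h, ``auc`` in nmol*h/L.
    ``t_half_window`` records the (t_first, t_last, n_points) actually used
    by the terminal regression.  ``degenerate`` flags an all-zero profile.
    """

    cmax: dict
    tmax: dict
    t_half: dict
    auc: dict
    auc_ratio: float
    t_half_window: dict = field(default_factory=dict)
    degenerate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _series(source, analyte: str):
    if isinstance(source, SimulationResult):
        conc = {"losartan": source.Cp, "e3174": source.Cm}[_norm_analyte(analyte)]
        return np.asarray(source.t, float), np.asarray(conc, float)
    t, c = source
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    if t.size == 0:
        raise ValueError("empty concentration series")
    return t, c


def _norm_analyte(analyte: str) -> str:
    key = analyte.lower().replace("-", "").replace("_", "")
    if key in ("losartan", "parent", "cp"):
        return "losartan"
    if key in ("e3174", "metabolite", "carboxylosartan", "cm"):
        return "e3174"
    raise ValueError(f"unknown analyte {analyte!r}")


def cmax_tmax(source, analyte: str = "losartan"):
    """Maximum concentration and its earliest time on the output grid.

    Returns ``(cmax, tmax, degenerate)`` where ``degenerate`` is True for an
    all-zero profile (tmax then reported as the first grid time).
    """
    t, c = _series(source, analyte)
    if np.all(c <= 0):
        return 0.0, float(t[0]), True
    i = int(np.argmax(c))  # argmax returns the earliest maximizer
    return float(c[i]), float(t[i]), False


def auc(source, analyte: str = "losartan") -> float:
    """Area under the curve over the simulated/observed span (nmol*h/L).

    For a :class:`SimulationResult` this is the terminal value of the
    integrated AUC state; for raw arrays, composite trapezoid.
    """
    if isinstance(source, SimulationResult):
        return source.auc_p if _norm_analyte(analyte) == "losartan" else source.auc_m
    t, c = _series(source, analyte)
    return float(np.trapezoid(c, t))


def auc_ratio(auc_losartan: float, auc_metabolite: float) -> float:
    """Piecewise losartan/E-3174 AUC ratio: defined as 0 when the metabolite
    AUC is 0 (the delayed metabolite has not appeared yet)."""
    if auc_losartan < 0 or auc_metabolite < 0:
        raise ValueError("AUC inputs must be non-negative")
    if auc_metabolite == 0:
        return 0.0
    return auc_losartan / auc_metabolite


def terminal_half_life(source, analyte: str = "losartan",
                       schedule=SCHEDULE_H, window: tuple | int | None = None,
                       r2_min: float = 0.98, return_window: bool = False):
    """Terminal elimination half-life by semilog linear regression (h).

    The window defaults to the last 3 schedule times with positive
    concentration (all after tmax), extended backwards point by point while
    the semilog fit keeps R^2 >= ``r2_min``.  ``window`` may instead be an
    explicit ``(t_lo, t_hi)`` interval or a point count from the end.
    """
    t, c = _series(source, analyte)
    _, tmax, degenerate = cmax_tmax(source, analyte)
    if degenerate:
        raise UndefinedHalfLifeError("all-zero profile has no half-life")

    sched = np.asarray(schedule, float)
    sched = sched[(sched >= t[0]) & (sched <= t[-1])]
    cs = np.interp(sched, t, c)
    usable = (cs > 0) & (sched > tmax)
    ts_all, cs_all = sched[usable], cs[usable]

    if isinstance(window, tuple):
        sel = (ts_all >= window[0]) & (ts_all <= window[1])
        ts, cs_w = ts_all[sel], cs_all[sel]
    elif isinstance(window, int):
        ts, cs_w = ts_all[-window:], cs_all[-window:]
    else:
        k = 3
        while k < len(ts_all):  # extend backwards while log-linear
            if _r2(ts_all[-(k + 1):], np.log(cs_all[-(k + 1):])) >= r2_min:
                k += 1
            else:
                break
        ts, cs_w = ts_all[-k:], cs_all[-k:]

    if len(ts) < 2:
        raise UndefinedHalfLifeError("fewer than 2 positive terminal points")
    slope, _ = np.polyfit(ts, np.log(cs_w), 1)
    if slope >= 0:
        raise UndefinedHalfLifeError(f"non-negative terminal slope {slope:.3g}")
    t_half = math.log(2.0) / abs(slope)
    if return_window:
        return t_half, (float(ts[0]), float(ts[-1]), len(ts))
    return t_half


def _r2(x, y):
    if len(x) < 2:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return 1.0 - np.sum(resid ** 2) / ss_tot


def summarize(result: SimulationResult, schedule=SCHEDULE_H) -> PKSummary:
    """Full PK summary of a simulation: both analytes plus AUC ratio."""
    out = PKSummary(cmax={}, tmax={}, t_half={}, auc={}, auc_ratio=0.0)
    for analyte in ("losartan", "e3174"):
        cmax, tmax, degenerate = cmax_tmax(result, analyte)
        out.cmax[analyte] = cmax
        out.tmax[analyte] = tmax
        out.degenerate[analyte] = degenerate
        out.auc[analyte] = auc(result, analyte)
        if degenerate:
            out.t_half[analyte] = float("nan")
            out.t_half_window[analyte] = None
        else:
            th, win = terminal_half_life(result, analyte, schedule=schedule,
                                         return_window=True)
            out.t_half[analyte] = th
            out.t_half_window[analyte] = win
    out.auc_ratio = auc_ratio(out.auc["losartan"], out.auc["e3174"])
    return out
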