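"""The 14 CGM-derived indices of glucose dynamics, plus time in range.

Twelve established glycemic-variability indices (CONGA, LI, J-index, HBGI,
GRADE, MODD, MAGE, ADRR, M-value, MAG, and the plain mean and Std of the
trace) together with two autocorrelation metrics, AC_Mean and AC_Var, the
mean and variance of the glucose autocorrelation function over a fixed lag
window: lags 1-30 at 5-min sampling, lags 1-10 at 15-min sampling (both
windows span 150 minutes of physiology).

Readings are held in mg/dL; indices whose literature definition is on the
mmol/L scale (CONGA, LI, J-index, MODD, MAGE, MAG) convert internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import MGDL_PER_MMOL, GlucoseTrace, TraceError, resample_uniform

#: index names of the per-subject panel, in canonical order
PANEL_NAMES = [
    "CGM_Mean", "CGM_Std", "CONGA", "LI", "JINDEX", "HBGI", "GRADE",
    "MODD", "MAGE", "ADRR", "MVALUE", "MAG", "AC_Mean", "AC_Var", "TIR",
]


class IndexError_(TraceError):
    """An index could not be computed on this trace (precondition failure)."""


@dataclass
class ACF:
    """Sample autocorrelation at lags 1..K, each value in [-1, 1]."""

    lags: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if len(self.lags) < 1 or len(self.lags) != len(self.r):
            raise ValueError("ACF needs at least one lag and matching r")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("autocorrelation outside [-1, 1]")


def lags_for_interval(sampling_interval: float) -> int:
    """Lag window for AC metrics: 30 lags at 5-min data, 10 at 15-min.

    Both choices cover a 150-minute window; other sampling intervals get
    round(150 / interval) with the same rationale.
    """
    return max(1, int(round(150.0 / sampling_interval)))


def acf(trace: GlucoseTrace, K: int) -> ACF:
    """Autocorrelation r_1..r_K of a uniform trace (biased denominator).

    r_k = sum_t (G_t - Gbar)(G_{t+k} - Gbar) / sum_t (G_t - Gbar)^2.
    """
    g = np.asarray(trace.values, dtype=float)
    n = len(g)
    if n <= K + 1:
        raise IndexError_(f"trace of length {n} too short for {K} lags")
    x = g - g.mean()
    denom = float(x @ x)
    if denom <= 0:
        raise IndexError_("autocorrelation undefined on a constant trace")
    full = np.correlate(x, x, mode="full")[n - 1:]
    r = full[1:K + 1] / denom
    return ACF(np.arange(1, K + 1), r)


def ac_metrics(a: ACF) -> tuple[float, float]:
    """(AC_Mean, AC_Var): mean and unbiased variance of r_1..r_K."""
    if len(a.r) < 2:
        return float(a.r.mean()), float("nan")
    return float(a.r.mean()), float(a.r.var(ddof=1))


def summary_stats(trace: GlucoseTrace) -> tuple[float, float, float]:
    """(CGM_Mean mg/dL, unbiased CGM_Std mg/dL, TIR % in [70, 180] inclusive)."""
    g = trace.values
    if len(g) < 2:
        raise IndexError_("summary statistics need >= 2 readings")
    tir = 100.0 * np.mean((g >= 70) & (g <= 180))
    return float(g.mean()), float(g.std(ddof=1)), float(tir)


def conga(trace: GlucoseTrace, n_hours: float = 1.0) -> float:
    """CONGA: Std of differences between readings ``n_hours`` apart, mmol/L."""
    if not trace.is_uniform():
        raise IndexError_("CONGA needs a uniform trace")
    lag = int(round(n_hours * 60.0 / trace.sampling_interval))
    if lag < 1 or len(trace) <= lag + 1:
        raise IndexError_(f"trace span too short for CONGA({n_hours} h)")
    g = trace.values / MGDL_PER_MMOL
    d = g[lag:] - g[:-lag]
    return float(d.std(ddof=1))


def li(trace: GlucoseTrace) -> float:
    """Lability Index: mean squared hourly glucose change, (mmol/L)^2/h.

    Computed on a 60-min resampled grid; LI = (1/(N-1)) sum (dG_mmol)^2 / dt_h.
    """
    hourly = resample_uniform(trace, step=60.0, max_gap=120.0)
    if len(hourly) < 2:
        raise IndexError_("LI needs >= 2 hourly points")
    g = hourly.values / MGDL_PER_MMOL
    dt_h = np.diff(hourly.times) / 60.0
    return float(np.mean(np.diff(g) ** 2 / dt_h))


def jindex(trace: GlucoseTrace) -> float:
    """J-index: 0.324 (mean + Std)^2 with glucose in mmol/L."""
    mean, std, _ = summary_stats(trace)
    return 0.324 * ((mean + std) / MGDL_PER_MMOL) ** 2


def _risk(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized blood-glucose risk transform (g in mg/dL) -> (rl, rh)."""
    if np.any(g <= 1):
        raise IndexError_("risk transform needs glucose > 1 mg/dL")
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    r = 10.0 * f ** 2
    return np.where(f < 0, r, 0.0), np.where(f > 0, r, 0.0)


def bgri(trace: GlucoseTrace) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(HBGI, LBGI, per-reading rl, rh) from the log-power risk transform."""
    rl, rh = _risk(trace.values)
    return float(rh.mean()), float(rl.mean()), rl, rh


def grade(trace: GlucoseTrace) -> float:
    """GRADE: mean of 425 (log10(log10 g_mmol) + 0.16)^2, capped at 50."""
    g = trace.values / MGDL_PER_MMOL
    if np.any(g <= 1):
        raise IndexError_("GRADE needs glucose > 1 mmol/L")
    score = 425.0 * (np.log10(np.log10(g)) + 0.16) ** 2
    return float(np.minimum(score, 50.0).mean())


def modd(trace: GlucoseTrace) -> float:
    """MODD: mean absolute difference of readings 24 h apart, mmol/L."""
    t, g = trace.times, trace.values / MGDL_PER_MMOL
    tol = trace.sampling_interval / 2.0
    j = np.searchsorted(t, t + 1440.0)
    diffs = []
    for i, jj in enumerate(j):
        for cand in (jj - 1, jj):
            if 0 <= cand < len(t) and abs(t[cand] - t[i] - 1440.0) <= tol:
                diffs.append(abs(g[cand] - g[i]))
                break
    if not diffs:
        raise IndexError_("MODD needs readings spanning >= 2 days")
    return float(np.mean(diffs))


def _alternating_extrema(g: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior local extrema by three-point comparison with plateau merging.

    Returns (indices, signs); signs alternate, +1 for peaks, -1 for nadirs.
    Strict three-point extrema alternate by construction; the merge pass is a
    safeguard for plateau edge cases.
    """
    n = len(g)
    idx: list[int] = []
    sgn: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and g[j + 1] == g[j]:  # plateau merge
            j += 1
        if j + 1 < n:
            left, right = g[i - 1], g[j + 1]
            if g[i] > left and g[i] > right:
                idx.append(i); sgn.append(+1)
            elif g[i] < left and g[i] < right:
                idx.append(i); sgn.append(-1)
        i = j + 1
    # enforce alternation: merge same-sign neighbours, keeping the extreme one
    out_i: list[int] = []
    out_s: list[int] = []
    for k in range(len(idx)):
        if out_s and sgn[k] == out_s[-1]:
            better = (g[idx[k]] > g[out_i[-1]]) if sgn[k] > 0 else (g[idx[k]] < g[out_i[-1]])
            if better:
                out_i[-1] = idx[k]
        else:
            out_i.append(idx[k]); out_s.append(sgn[k])
    return out_i, out_s


def mage(trace: GlucoseTrace) -> tuple[float, bool]:
    """MAGE (mmol/L) and a flag for "no qualifying excursion".

    Service-style: find alternating local extrema, iteratively delete the
    adjacent extremum pair with the smallest amplitude while that amplitude is
    below one Std of the whole trace (preserving alternation), then average
    the absolute amplitudes of the remaining consecutive excursions,
    direction-agnostic.  A trace with no excursion >= 1 Std reports (0, True).
    """
    g = np.asarray(trace.values, dtype=float)
    if len(g) < 3:
        return 0.0, True
    sd = g.std(ddof=1)
    if sd == 0:
        return 0.0, True
    idx, _ = _alternating_extrema(g)
    vals = [g[i] for i in idx]
    # iteratively remove the smallest below-threshold adjacent pair
    while len(vals) >= 2:
        amps = [abs(vals[k + 1] - vals[k]) for k in range(len(vals) - 1)]
        k = int(np.argmin(amps))
        if amps[k] >= sd:
            break
        if len(vals) == 2:
            vals.pop(k + 1)
            continue
        if k == 0:
            del vals[0]
        elif k == len(vals) - 2:
            del vals[-1]
        else:
            del vals[k:k + 2]  # interior pair; neighbours re-join, alternation kept
    amps = [abs(vals[k + 1] - vals[k]) for k in range(len(vals) - 1)]
    amps = [a for a in amps if a >= sd]
    if not amps:
        return 0.0, True
    return float(np.mean(amps) / MGDL_PER_MMOL), False


def _day_blocks(trace: GlucoseTrace):
    """Split reading indices into consecutive 1440-min blocks from t[0]."""
    rel = trace.times - trace.times[0]
    day = np.floor(rel / 1440.0).astype(int)
    return [np.flatnonzero(day == d) for d in range(day.max() + 1)]


def adrr(trace: GlucoseTrace, min_hours: float = 20.0) -> float:
    """ADRR: mean over complete days of (max low risk + max high risk).

    A day block counts as complete when its readings cover >= ``min_hours``.
    """
    rl, rh = _risk(trace.values)
    totals = []
    for block in _day_blocks(trace):
        if len(block) < 2:
            continue
        coverage_h = (trace.times[block[-1]] - trace.times[block[0]]
                      + trace.sampling_interval) / 60.0
        if coverage_h < min_hours:
            continue
        totals.append(rl[block].max() + rh[block].max())
    if not totals:
        raise IndexError_("ADRR needs at least one complete day")
    return float(np.mean(totals))


def mvalue(trace: GlucoseTrace, ideal: float = 120.0) -> float:
    """Schlichtkrull M-value around 120 mg/dL with the W/20 range correction."""
    g = trace.values
    if len(g) < 2:
        raise IndexError_("M-value needs >= 2 readings")
    m = np.mean(np.abs(10.0 * np.log10(g / ideal)) ** 3)
    w = g.max() - g.min()
    return float(m + w / 20.0)


def mag(trace: GlucoseTrace) -> float:
    """MAG: summed absolute glucose change (mmol/L) per elapsed hour."""
    if len(trace) < 2:
        raise IndexError_("MAG needs >= 2 readings")
    hours = (trace.times[-1] - trace.times[0]) / 60.0
    if hours <= 0:
        raise IndexError_("MAG needs nonzero elapsed time")
    total = np.sum(np.abs(np.diff(trace.values))) / MGDL_PER_MMOL
    return float(total / hours)


def index_panel(trace: GlucoseTrace, conga_hours: float = 1.0) -> tuple[dict, dict]:
    """All 15 panel values for one trace; failures recorded, not raised.

    The AC lag window follows the sampling interval (30 lags at 5 min, 10 at
    15 min).  Returns ``(panel, reasons)`` where ``panel`` maps every name in
    :data:`PANEL_NAMES` to a float or NaN, and ``reasons`` explains each NaN.
    """
    panel: dict[str, float] = {k: float("nan") for k in PANEL_NAMES}
    reasons: dict[str, str] = {}

    def attempt(name, fn):
        try:
            panel[name] = fn()
        except (TraceError, ValueError) as exc:
            reasons[name] = str(exc)

    def set_summary():
        m, s, t = summary_stats(trace)
        panel["CGM_Mean"], panel["CGM_Std"], panel["TIR"] = m, s, t
        return m

    attempt("CGM_Mean", set_summary)
    attempt("CONGA", lambda: conga(trace, conga_hours))
    attempt("LI", lambda: li(trace))
    attempt("JINDEX", lambda: jindex(trace))
    attempt("HBGI", lambda: bgri(trace)[0])
    attempt("GRADE", lambda: grade(trace))
    attempt("MODD", lambda: modd(trace))
    attempt("MAGE", lambda: mage(trace)[0])
    attempt("ADRR", lambda: adrr(trace))
    attempt("MVALUE", lambda: mvalue(trace))
    attempt("MAG", lambda: mag(trace))

    def set_ac():
        K = lags_for_interval(trace.sampling_interval)
        m, v = ac_metrics(acf(trace, K))
        panel["AC_Mean"], panel["AC_Var"] = m, v
        return m

    attempt("AC_Mean", set_ac)
    for name in PANEL_NAMES:
        if math.isnan(panel[name]) and name not in reasons:
            reasons[name] = reasons.get("CGM_Mean", reasons.get("AC_Mean", "not computed"))
    return panel, reasons
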