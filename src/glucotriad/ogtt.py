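"""OGTT-derived insulin secretion/sensitivity indices and 3-point curve metrics.

Works on the canonical 75 g OGTT sampling grid (0, 30, 60, 90, 120 min) with
plasma glucose in mg/dL and immunoreactive insulin (IRI) in uU/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

OGTT_MINUTES = (0, 30, 60, 90, 120)


class OgttError(ValueError):
    pass


@dataclass
class OgttRecord:
    """Glucose (mg/dL) and insulin (uU/mL) at the canonical OGTT minutes.

    Missing time points are simply absent from the dicts; each index states
    which points it needs.
    """

    glucose: dict[int, float] = field(default_factory=dict)
    insulin: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.glucose, self.insulin):
            for t in d:
                if t not in OGTT_MINUTES:
                    raise OgttError(f"non-canonical OGTT minute {t}")

    def _need(self, which: str, minutes) -> np.ndarray:
        d = getattr(self, which)
        missing = [t for t in minutes if t not in d]
        if missing:
            raise OgttError(f"missing {which} at minutes {missing}")
        return np.array([d[t] for t in minutes], dtype=float)


def insulinogenic_index(rec: OgttRecord) -> float:
    """I.I. = (IRI30 - IRI0) / (PG30 - PG0), the 30-min increment ratio."""
    g = rec._need("glucose", (0, 30))
    i = rec._need("insulin", (0, 30))
    dg = g[1] - g[0]
    if dg == 0:
        raise OgttError("undefined increment ratio: PG30 equals PG0")
    if dg < 0:
        warnings.warn("paradoxical OGTT response: glucose fell by 30 min",
                      stacklevel=2)
    return float((i[1] - i[0]) / dg)


def composite_index(rec: OgttRecord) -> float:
    """Matsuda composite insulin-sensitivity index.

    10000 / sqrt(FPG x FIRI x meanG x meanI), means over the five OGTT samples.
    """
    g = rec._need("glucose", OGTT_MINUTES)
    i = rec._need("insulin", OGTT_MINUTES)
    prod = g[0] * i[0] * g.mean() * i.mean()
    if prod <= 0:
        raise OgttError("composite index needs positive glucose and insulin")
    return float(10000.0 / np.sqrt(prod))


def oral_di(rec: OgttRecord) -> float:
    """Oral disposition index: composite index x (AUC_ins / AUC_glc).

    AUCs by trapezoid over minutes {0, 30, 60, 120}; the 90-min samples are
    excluded by definition.
    """
    nodes = (0, 30, 60, 120)
    g = rec._need("glucose", nodes)
    i = rec._need("insulin", nodes)
    t = np.array(nodes, dtype=float)
    auc_g = np.trapezoid(g, t)
    auc_i = np.trapezoid(i, t)
    return float(composite_index(rec) * auc_i / auc_g)


def ogtt_pattern_metrics(g0: float, g30: float, g120: float,
                         grid_step: float = 1.0,
                         lags: int = 20) -> tuple[float, float, float]:
    """(mean, Std, AC_Var) of the piecewise-linear 3-point OGTT curve.

    The glucose values at 0, 30 and 120 min are linearly interpolated onto a
    ``grid_step``-minute grid on [0, 120]; AC_Var uses autocorrelation lags
    1..``lags`` (the default 20 spans the 2-h window).  A flat curve reports
    Std = 0 and AC_Var = NaN (autocorrelation undefined at zero variance).
    """
    from .indices import ac_metrics, acf
    from .trace import GlucoseTrace

    for g in (g0, g30, g120):
        if g <= 0:
            raise OgttError("OGTT glucose values must be positive")
    t = np.arange(0.0, 120.0 + grid_step / 2, grid_step)
    curve = np.interp(t, [0.0, 30.0, 120.0], [g0, g30, g120])
    mean, std = float(curve.mean()), float(curve.std(ddof=1))
    if std == 0:
        return mean, 0.0, float("nan")
    tr = GlucoseTrace("ogtt", t, curve, sampling_interval=grid_step)
    _, ac_var = ac_metrics(acf(tr, lags))
    return mean, std, float(ac_var)
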