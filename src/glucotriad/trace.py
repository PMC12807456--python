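"""CGM trace container, CSV I/O, unit conversion and uniform-grid resampling.

The canonical internal unit is mg/dL.  Formulas that are defined on the
mmol/L scale convert internally with the molar-mass factor 18.016.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

#: grams/mole convention for glucose: 1 mmol/L = 18.016 mg/dL
MGDL_PER_MMOL = 18.016

_UNITS = {"mg/dL", "mmol/L"}


class TraceError(ValueError):
    """Raised when a glucose trace violates its invariants or a precondition."""


def to_unit(values, from_unit: str, to_unit: str):
    """Convert glucose between mg/dL and mmol/L (multiplicative, 18.016)."""
    for u in (from_unit, to_unit):
        if u not in _UNITS:
            raise TraceError(f"unknown glucose unit {u!r}; expected one of {sorted(_UNITS)}")
    arr = np.asarray(values, dtype=float)
    if from_unit == to_unit:
        return arr
    if from_unit == "mmol/L":
        return arr * MGDL_PER_MMOL
    return arr / MGDL_PER_MMOL


@dataclass
class GlucoseTrace:
    """One subject's glucose time series on the minutes-since-start axis.

    Parameters
    ----------
    subject_id : str
    times : array of minutes since the first reading, strictly increasing.
    values : glucose in mg/dL, all positive.
    sampling_interval : nominal minutes between readings (5 or 15 typical).
    start_time : optional calendar timestamp of the first reading.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    sampling_interval: float = 5.0
    start_time: pd.Timestamp | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise TraceError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise TraceError(f"subject {self.subject_id}: times not strictly increasing")
        if np.any(self.values <= 0):
            raise TraceError(f"subject {self.subject_id}: non-positive glucose value")
        if self.sampling_interval <= 0:
            raise TraceError("sampling_interval must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_min(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        if len(self) < 2:
            return False
        d = np.diff(self.times)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))


@dataclass
class CohortTable:
    """Subjects x features table with a %NC-style continuous outcome.

    ``features`` holds numeric columns only; missing entries are NaN and are
    never silently imputed.  ``outcome`` is %NC on the 0-100 percent scale.
    """

    subject_ids: list[str]
    features: pd.DataFrame
    outcome: pd.Series | None = None

    def __post_init__(self):
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in cohort")
        self.features = self.features.apply(pd.to_numeric)
        if self.outcome is not None:
            oc = np.asarray(self.outcome, dtype=float)
            ok = oc[np.isfinite(oc)]
            if len(ok) and (ok.min() < 0 or ok.max() > 100):
                raise ValueError("%NC outcome outside [0, 100]")

    def to_frame(self, outcome_name: str = "NC") -> pd.DataFrame:
        df = self.features.copy()
        df.index = pd.Index(self.subject_ids, name="subject_id")
        if self.outcome is not None:
            df[outcome_name] = np.asarray(self.outcome, dtype=float)
        return df


def read_cgm_csv(path, unit: str = "mg/dL") -> tuple[list[GlucoseTrace], dict]:
    """Read a long-format CGM CSV into one :class:`GlucoseTrace` per subject.

    Expected columns: ``subject_id``, plus either ``timestamp`` (ISO 8601) or
    ``t_min`` (minutes), plus ``glucose``.  ``unit`` names the glucose unit of
    the file; mmol/L input is converted to mg/dL.

    Returns ``(traces, qc_report)``; subjects with non-monotone time axes are
    rejected, non-positive readings are dropped, and both are listed in the QC
    report rather than raised.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "subject_id" not in cols or "glucose" not in cols:
        raise TraceError("CGM CSV needs subject_id and glucose columns")
    qc: dict = {"rejected_subjects": [], "rejected_readings": []}
    traces: list[GlucoseTrace] = []
    for sid, grp in df.groupby(cols["subject_id"], sort=False):
        sid = str(sid)
        start_time = None
        if "timestamp" in cols:
            ts = pd.to_datetime(grp[cols["timestamp"]])
            t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 60.0
            start_time = ts.iloc[0]
        elif "t_min" in cols:
            t = grp[cols["t_min"]].to_numpy(dtype=float)
        else:
            raise TraceError("CGM CSV needs a timestamp or t_min column")
        g = to_unit(grp[cols["glucose"]].to_numpy(dtype=float), unit, "mg/dL")
        bad = ~(g > 0) | ~np.isfinite(g)
        if bad.any():
            for tt, gg in zip(t[bad], g[bad]):
                qc["rejected_readings"].append(
                    {"subject_id": sid, "t_min": float(tt), "glucose": float(gg),
                     "reason": "non-positive glucose"})
            t, g = t[~bad], g[~bad]
        if len(t) and np.any(np.diff(t) <= 0):
            qc["rejected_subjects"].append(
                {"subject_id": sid, "reason": "non-monotone timestamps"})
            continue
        t = t - t[0] if len(t) else t
        step = float(np.median(np.diff(t))) if len(t) > 1 else 5.0
        traces.append(GlucoseTrace(sid, t, g, sampling_interval=step,
                                   start_time=start_time))
    return traces, qc


def write_cgm_csv(traces: Iterable[GlucoseTrace], path) -> None:
    """Write traces to a long-format CSV (t_min, glucose in mg/dL)."""
    rows = []
    for tr in traces:
        for t, g in zip(tr.times, tr.values):
            rows.append({"subject_id": tr.subject_id, "t_min": t, "glucose": g})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_qc_report(qc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2)


def resample_uniform(trace: GlucoseTrace, step: float | None = None,
                     max_gap: float = 30.0) -> GlucoseTrace:
    """Resample a trace onto an even grid by linear interpolation.

    Gaps between consecutive readings longer than ``max_gap`` minutes are not
    interpolated across; the longest fully covered contiguous block of grid
    points is returned.  ``step`` defaults to the trace's nominal interval.
    """
    if len(trace) < 2:
        raise TraceError("resampling needs at least two readings")
    step = float(step if step is not None else trace.sampling_interval)
    if step <= 0:
        raise TraceError("step must be positive")
    t, g = trace.times, trace.values
    grid = np.arange(t[0], t[-1] + 0.5 * step, step)
    grid = grid[grid <= t[-1] + 1e-9]
    vals = np.interp(grid, t, g)
    # mark grid points that fall inside an over-long observation gap
    gap_start = t[:-1][np.diff(t) > max_gap + 1e-9]
    gap_end = t[1:][np.diff(t) > max_gap + 1e-9]
    covered = np.ones(len(grid), dtype=bool)
    for a, b in zip(gap_start, gap_end):
        covered &= ~((grid > a + 1e-9) & (grid < b - 1e-9))
    # longest contiguous run of covered grid points
    best_len, best_start, run_start = 0, 0, None
    for i, c in enumerate(np.append(covered, False)):
        if c and run_start is None:
            run_start = i
        elif not c and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len < 2:
        raise TraceError(f"subject {trace.subject_id}: trace unusable "
                         "(no contiguous block of >= 2 grid points)")
    sl = slice(best_start, best_start + best_len)
    out_t = grid[sl]
    return GlucoseTrace(trace.subject_id, out_t - out_t[0], vals[sl],
                        sampling_interval=step, start_time=trace.start_time)
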