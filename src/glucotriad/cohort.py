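"""Synthetic cohorts with controllable mean/variance/autocorrelation structure.

The generator emulates the structure of a plaque-imaging CGM cohort: 8 NGT,
16 IGT and 29 T2DM subjects, each with at least three consecutive days of
CGM, an OGTT, and a continuous plaque-vulnerability outcome (%NC).  The
outcome is linear in the z-scored mean, Std and AC_Var of each subject's
glucose trace with Gaussian noise, which is the minimal generative structure
under which the downstream regression, selection and factor stages become
recovery problems with a known truth.

Two trace models are available: a fast AR(1)-plus-meals process with
analytically known autocorrelation (the default for recovery tests) and the
mechanistic delay-integral simulator from :mod:`glucotriad.sim`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .indices import ac_metrics, acf, index_panel, lags_for_interval
from .ogtt import OgttRecord, composite_index, insulinogenic_index, oral_di
from .trace import CohortTable, GlucoseTrace

#: per-class parameter distributions for the AR1-meals trace model.
#: mu: baseline glucose mg/dL; sigma: AR(1) innovation scale mg/dL;
#: phi: AR coefficient per 5-min step; meal_amp: meal bump height mg/dL.
CLASS_PARAMS = {
    "NGT": {"mu": (100.0, 8.0), "sigma": (3.0, 6.0), "phi": (0.88, 0.94),
            "meal_amp": (20.0, 45.0)},
    "IGT": {"mu": (125.0, 10.0), "sigma": (5.0, 9.0), "phi": (0.92, 0.96),
            "meal_amp": (40.0, 70.0)},
    "T2DM": {"mu": (160.0, 20.0), "sigma": (7.0, 14.0), "phi": (0.94, 0.98),
             "meal_amp": (55.0, 95.0)},
}

#: diagnostic ranges used to draw class-consistent markers (ADA-style
#: cutoffs: T2DM at HbA1c >= 6.5 %, FPG >= 126 mg/dL or PG120 >= 200 mg/dL;
#: IGT at 6.0-6.4 %, 110-125 mg/dL, 140-199 mg/dL; NGT below all three)
CLASS_RANGES = {
    "NGT": {"FBG": (85.0, 109.0), "HbA1c": (5.0, 5.9), "PG120": (90.0, 139.0)},
    "IGT": {"FBG": (110.0, 125.0), "HbA1c": (6.0, 6.4), "PG120": (140.0, 199.0)},
    "T2DM": {"FBG": (126.0, 200.0), "HbA1c": (6.5, 10.0), "PG120": (200.0, 320.0)},
}

#: insulinogenic-index range per class (uU/mL per mg/dL); secretion falls
#: from NGT to T2DM
CLASS_II = {"NGT": (0.8, 1.6), "IGT": (0.4, 0.9), "T2DM": (0.1, 0.4)}


@dataclass
class SubjectParams:
    mu: float
    sigma: float
    phi: float
    meal_amp: float
    label: str = "NGT"


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort (defaults mirror 8/16/29)."""

    n_ngt: int = 8
    n_igt: int = 16
    n_t2dm: int = 29
    days: int = 3
    sampling_interval: float = 5.0
    trace_model: str = "ar1-meals"  # or "simulator"
    beta0: float = 18.0
    beta_mean: float = 4.0
    beta_std: float = 3.0
    beta_ac: float = 3.0
    sigma_nc: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ngt + self.n_igt + self.n_t2dm < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if min(self.n_ngt, self.n_igt, self.n_t2dm) < 0:
            raise ValueError("class counts must be >= 0")
        if self.sigma_nc <= 0:
            raise ValueError("sigma_nc must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_trace(params: SubjectParams, seed, days: int = 3,
                   sampling_interval: float = 5.0,
                   subject_id: str = "S", n_meals: int = 3) -> GlucoseTrace:
    """AR(1)-plus-meals CGM trace, deterministic given the seed.

    G_t = mu + X_t + meal bumps, with X_t = phi X_{t-1} + eta_t,
    eta ~ N(0, sigma^2), X_0 from the stationary distribution.  Meals are
    Gaussian bumps at ~07:30, 12:30 and 19:00 with +-40 min timing jitter and
    30 % amplitude jitter.  Values are floored at 40 mg/dL.
    """
    rng = _rng(seed)
    n = int(days * 1440 / sampling_interval)
    t = np.arange(n) * sampling_interval
    if params.sigma > 0:
        eta = rng.normal(0.0, params.sigma, size=n)
        x0 = rng.normal(0.0, params.sigma / np.sqrt(1 - params.phi ** 2))
        x = signal.lfilter([1.0], [1.0, -params.phi], eta,
                           zi=np.array([params.phi * x0]))[0]
    else:
        rng.normal(size=n + 1)  # keep the stream aligned across sigma choices
        x = np.zeros(n)
    g = params.mu + x
    if params.meal_amp > 0:
        width = 45.0  # min, Gaussian sd of a meal bump
        for day in range(days):
            for base_min in (450.0, 750.0, 1140.0)[:n_meals]:
                center = day * 1440 + base_min + rng.uniform(-40, 40)
                amp = params.meal_amp * rng.uniform(0.7, 1.3)
                g = g + amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return GlucoseTrace(subject_id, t, np.maximum(g, 40.0),
                        sampling_interval=sampling_interval)


def trace_components(trace: GlucoseTrace) -> dict:
    """Empirical (mean, std, ac_mean, ac_var) with the sampling-matched lags."""
    K = lags_for_interval(trace.sampling_interval)
    ac_mean, ac_var = ac_metrics(acf(trace, K))
    return {"mean": float(trace.values.mean()),
            "std": float(trace.values.std(ddof=1)),
            "ac_mean": ac_mean, "ac_var": ac_var}


def _marker(rng, lo, hi, z_mu) -> float:
    """Class-range marker positioned by the subject's baseline glucose."""
    u = float(np.clip(0.5 + 0.30 * z_mu + 0.25 * rng.normal(), 0.02, 0.98))
    return lo + u * (hi - lo)


def _ogtt_record(rng, label: str, fbg: float, pg120: float) -> OgttRecord:
    """Class-plausible five-point OGTT glucose and insulin curves."""
    peak_rise = {"NGT": (40, 70), "IGT": (55, 90), "T2DM": (60, 110)}[label]
    pg30 = fbg + rng.uniform(*peak_rise)
    pg60 = pg30 + rng.uniform(-10, 30) if label != "NGT" else pg30 - rng.uniform(0, 30)
    pg90 = 0.5 * (pg60 + pg120) + rng.uniform(-10, 10)
    iri0 = float(rng.uniform(*{"NGT": (4, 10), "IGT": (7, 16), "T2DM": (8, 20)}[label]))
    ii = rng.uniform(*CLASS_II[label])
    iri30 = iri0 + ii * (pg30 - fbg)
    iri60 = iri30 * rng.uniform(0.9, 1.4)
    iri90 = iri60 * rng.uniform(0.7, 1.1)
    iri120 = iri90 * rng.uniform(0.5, 0.9)
    glc = dict(zip((0, 30, 60, 90, 120),
                   np.maximum([fbg, pg30, pg60, pg90, pg120], 40.0)))
    ins = dict(zip((0, 30, 60, 90, 120),
                   np.maximum([iri0, iri30, iri60, iri90, iri120], 1.0)))
    return OgttRecord(glc, ins)


def draw_subject_params(rng, label: str) -> SubjectParams:
    cp = CLASS_PARAMS[label]
    return SubjectParams(
        mu=float(rng.normal(*cp["mu"])),
        sigma=float(rng.uniform(*cp["sigma"])),
        phi=float(rng.uniform(*cp["phi"])),
        meal_amp=float(rng.uniform(*cp["meal_amp"])),
        label=label,
    )


def generate_cohort(spec: CohortSpec | None = None, *, compute_panel: bool = True,
                    ) -> tuple[list[GlucoseTrace], CohortTable, dict]:
    """Generate traces, a feature table and a %NC outcome with known truth.

    Returns ``(traces, cohort, truth)``.  ``truth`` carries the generating
    betas and each subject's empirical trace components so recovery tests can
    compare against them.  With ``compute_panel=False`` only the three
    component columns plus markers/OGTT indices are produced (much faster;
    used by simulation studies that do not need the full 15-index panel).
    """
    spec = spec or CohortSpec()
    rng = _rng(spec.seed)
    labels = (["NGT"] * spec.n_ngt + ["IGT"] * spec.n_igt
              + ["T2DM"] * spec.n_t2dm)
    traces, rows, comp_rows = [], [], []
    for i, label in enumerate(labels):
        sid = f"S{i:03d}"
        sp = draw_subject_params(rng, label)
        if spec.trace_model == "simulator":
            tr = _simulator_trace(rng, sp, spec, sid)
        else:
            tr = generate_trace(sp, rng, days=spec.days,
                                sampling_interval=spec.sampling_interval,
                                subject_id=sid)
        comp = trace_components(tr)
        zmu = (sp.mu - CLASS_PARAMS[label]["mu"][0]) / CLASS_PARAMS[label]["mu"][1]
        rg = CLASS_RANGES[label]
        fbg = _marker(rng, *rg["FBG"], zmu)
        hba1c = _marker(rng, *rg["HbA1c"], zmu)
        pg120 = _marker(rng, *rg["PG120"], zmu)
        rec = _ogtt_record(rng, label, fbg, pg120)
        row = {"label": label, "BMI": float(rng.normal(25, 3.5)),
               "FBG": fbg, "HbA1c": hba1c, "PG120": pg120,
               "II": insulinogenic_index(rec),
               "Composite": composite_index(rec),
               "OralDI": oral_di(rec)}
        if compute_panel:
            panel, _ = index_panel(tr)
            row.update(panel)
        else:
            row.update({"CGM_Mean": comp["mean"], "CGM_Std": comp["std"],
                        "AC_Mean": comp["ac_mean"], "AC_Var": comp["ac_var"]})
        traces.append(tr)
        rows.append(row)
        comp_rows.append(comp)
    comps = pd.DataFrame(comp_rows)
    z = (comps[["mean", "std", "ac_var"]]
         - comps[["mean", "std", "ac_var"]].mean()) / comps[["mean", "std", "ac_var"]].std(ddof=1)
    nc = (spec.beta0 + spec.beta_mean * z["mean"] + spec.beta_std * z["std"]
          + spec.beta_ac * z["ac_var"]
          + rng.normal(0.0, spec.sigma_nc, size=len(labels)))
    nc = np.clip(nc.to_numpy(), 0.0, 100.0)
    feats = pd.DataFrame(rows)
    label_col = feats.pop("label")
    table = CohortTable([tr.subject_id for tr in traces], feats,
                        outcome=pd.Series(nc))
    truth = {"betas": {"intercept": spec.beta0, "mean": spec.beta_mean,
                       "std": spec.beta_std, "ac_var": spec.beta_ac},
             "sigma_nc": spec.sigma_nc,
             "components": comps,
             "labels": list(label_col)}
    return traces, table, truth


def _simulator_trace(rng, sp: SubjectParams, spec: CohortSpec, sid: str) -> GlucoseTrace:
    """Mechanistic trace: day-long simulator runs stitched over the horizon."""
    from .sim import SimParams, bolus, simulate

    scale = sp.mu / 100.0
    p = SimParams(k_pro=1.0 * scale, k_tim=float(rng.uniform(20, 60)),
                  input=bolus(rate=sp.meal_amp / 8.0, start=450.0, duration=30.0),
                  horizon=spec.days * 1440.0, step=1.0)
    res = simulate(p)
    step = spec.sampling_interval
    tg = np.arange(0.0, p.horizon, step)
    g = np.interp(tg, res.t, res.G)
    g = g + rng.normal(0.0, sp.sigma * 0.5, size=len(g))
    return GlucoseTrace(sid, tg, np.maximum(g, 40.0), sampling_interval=step)


def generate_index_table(n: int = 300, k_true: int = 3, seed: int = 0,
                         loading: tuple[float, float] = (0.7, 0.9),
                         block_sizes: tuple[int, ...] | None = None,
                         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Correlated index-like variables with a known block factor structure.

    Variables are Lambda @ F + unique noise with unit total variance; the
    default 3-factor layout mirrors the mean / variance / autocorrelation
    grouping of CGM indices.  Returns ``(table, Lambda, F)``.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    rng = _rng(seed)
    if block_sizes is None:
        block_sizes = {1: (6,), 2: (5, 4), 3: (5, 4, 3)}.get(
            k_true, tuple([4] * k_true))
    if len(block_sizes) != k_true:
        raise ValueError("need one block size per factor")
    p = sum(block_sizes)
    lam = np.zeros((p, k_true))
    row = 0
    for k, size in enumerate(block_sizes):
        lam[row:row + size, k] = rng.uniform(*loading, size=size)
        row += size
    F = rng.standard_normal((n, k_true))
    unique_sd = np.sqrt(np.clip(1.0 - (lam ** 2).sum(axis=1), 1e-6, None))
    X = F @ lam.T + rng.standard_normal((n, p)) * unique_sd
    block_prefix = ["mean", "var", "ac"] if k_true == 3 else [
        f"f{k + 1}" for k in range(k_true)]
    names = []
    row = 0
    for k, size in enumerate(block_sizes):
        names += [f"{block_prefix[min(k, len(block_prefix) - 1)]}_{j + 1}"
                  for j in range(size)]
        row += size
    return pd.DataFrame(X, columns=names), lam, F
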