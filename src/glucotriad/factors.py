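"""Exploratory factor analysis of glucose-dynamics indices.

Factor-count selection (BIC over maximum-likelihood fits, Velicer's minimum
average partial), ML extraction with Kaiser-normalized varimax rotation,
sampling adequacy (KMO, Bartlett's sphericity), reliability (Cronbach's
alpha with Feldt CIs, corrected item-total correlations), regression-method
factor scores and their Spearman association with the outcome, and
Ward/Euclidean variable clustering with silhouette model selection.

Extraction is maximum likelihood (required for a likelihood-based BIC) and
factor scores use the regression (Thurstone) estimator; both are package
choices where the field offers several conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors


@dataclass
class FactorSolution:
    loadings: pd.DataFrame          # variables x k, varimax-rotated
    variance_explained: np.ndarray  # proportion per factor (of total variance)
    scores: pd.DataFrame            # subjects x k, regression method
    rotation: str = "varimax"
    interpretation: dict = field(default_factory=dict)  # factor -> [variables]
    heywood: bool = False


@dataclass
class ReliabilityReport:
    alpha: float
    ci: tuple[float, float]
    item_total: pd.Series  # corrected (item excluded from the total)


def ledermann_bound(p: int) -> int:
    """Largest k with (p - k)^2 >= p + k (identifiability of the ML model)."""
    k = 0
    while k + 1 < p and (p - (k + 1)) ** 2 >= p + (k + 1):
        k += 1
    return k


def _ml_fit(R: np.ndarray, table: pd.DataFrame, k: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Factor(table, n_factor=k, method="ml").fit()
    return res


def _factor_loglik(R: np.ndarray, L: np.ndarray, psi: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood of the factor model Sigma = LL' + diag(psi)."""
    p = R.shape[0]
    sigma = L @ L.T + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    quad = np.trace(np.linalg.solve(sigma, R))
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + quad)


def select_n_factors(table: pd.DataFrame, k_max: int | None = None,
                     ) -> tuple[int, int]:
    """(k_bic, k_map): factor counts by BIC over ML fits and by Velicer's MAP.

    BIC = -2 max-loglik + n_params ln(n) with n_params = p k + p - k(k-1)/2;
    candidate k runs 1..min(Ledermann bound, 8).  MAP minimizes the average
    squared partial correlation after removing successive principal
    components; a minimum at zero removed components is reported as k_map=0
    ("no common factor").
    """
    n, p = table.shape
    if p < 3:
        raise ValueError("factor selection needs >= 3 variables")
    if n <= p:
        raise ValueError("factor selection needs n > p")
    R = np.corrcoef(table.to_numpy(), rowvar=False)
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-10:
        raise ValueError(f"correlation matrix not positive definite "
                         f"(smallest eigenvalue {w.min():.3e})")
    k_hi = min(ledermann_bound(p), 8) if k_max is None else k_max
    best_bic, k_bic = np.inf, 1
    for k in range(1, k_hi + 1):
        try:
            res = _ml_fit(R, table, k)
            L = np.asarray(res.loadings)
            psi = np.clip(np.asarray(res.uniqueness), 1e-8, None)
        except Exception:
            continue
        ll = _factor_loglik(R, L, psi, n)
        n_par = p * k + p - k * (k - 1) // 2
        bic = -2 * ll + n_par * np.log(n)
        if bic < best_bic:
            best_bic, k_bic = bic, k
    return k_bic, velicer_map(R)


def velicer_map(R: np.ndarray, k_max: int | None = None) -> int:
    """Velicer's minimum average partial (squared partials, original form)."""
    p = R.shape[0]
    k_max = p - 2 if k_max is None else k_max
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    off = ~np.eye(p, dtype=bool)
    avg = [np.mean(R[off] ** 2)]  # m = 0 baseline
    for m in range(1, k_max + 1):
        A = V[:, :m] * np.sqrt(w[:m])
        resid = R - A @ A.T
        d = np.sqrt(np.clip(np.diag(resid), 1e-12, None))
        partial = resid / np.outer(d, d)
        avg.append(np.mean(partial[off] ** 2))
    return int(np.argmin(avg))


def _kaiser_varimax(L: np.ndarray) -> np.ndarray:
    """Varimax with Kaiser row normalization."""
    h = np.sqrt(np.clip((L ** 2).sum(axis=1), 1e-12, None))
    Lr, _ = rotate_factors(L / h[:, None], "varimax")
    Lr = Lr * h[:, None]
    # orient each factor so its largest-magnitude loading is positive
    for k in range(Lr.shape[1]):
        j = np.argmax(np.abs(Lr[:, k]))
        if Lr[j, k] < 0:
            Lr[:, k] = -Lr[:, k]
    # order factors by explained variance
    order = np.argsort(-(Lr ** 2).sum(axis=0))
    return Lr[:, order]


def fit_efa(table: pd.DataFrame, k: int, rotation: str = "varimax",
            loading_threshold: float = 0.30) -> FactorSolution:
    """ML factor extraction with varimax rotation and regression scores.

    Interpretation sets collect, per factor, the variables with absolute
    rotated loading >= ``loading_threshold``.  Heywood cases (communality
    reaching 1) are flagged with a warning, not fatal.
    """
    n, p = table.shape
    if k > ledermann_bound(p):
        raise ValueError(f"k={k} exceeds the Ledermann bound for p={p}")
    R = np.corrcoef(table.to_numpy(), rowvar=False)
    res = _ml_fit(R, table, k)
    L = np.asarray(res.loadings)
    if rotation == "varimax" and k > 1:
        L = _kaiser_varimax(L)
    heywood = bool(((L ** 2).sum(axis=1) > 1 + 1e-6).any()
                   or (np.asarray(res.uniqueness) < 1e-6).any())
    if heywood:
        warnings.warn("Heywood case: a communality reached 1", stacklevel=2)
    cols = [f"F{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(L, index=table.columns, columns=cols)
    Z = (table - table.mean()) / table.std(ddof=1)
    # regression (Thurstone) scores: F = Z R^{-1} L
    scores = pd.DataFrame(Z.to_numpy() @ np.linalg.solve(R, L),
                          index=table.index, columns=cols)
    var_expl = (L ** 2).sum(axis=0) / p
    interp = {c: [v for v in table.columns
                  if abs(loadings.loc[v, c]) >= loading_threshold]
              for c in cols}
    return FactorSolution(loadings, var_expl, scores, rotation, interp, heywood)


def adequacy(table: pd.DataFrame) -> tuple[float, float, float]:
    """(KMO overall MSA, Bartlett chi-square, Bartlett p).

    KMO compares squared correlations to squared anti-image partial
    correlations; Bartlett tests R = I with
    chi2 = -(n - 1 - (2p + 5)/6) ln det R on p(p-1)/2 df.
    """
    n, p = table.shape
    if p < 3 or n <= p:
        raise ValueError("adequacy needs p >= 3 and n > p")
    R = np.corrcoef(table.to_numpy(), rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("singular correlation matrix")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    kmo = np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(partial[off] ** 2))
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(kmo), float(chi2), pval


def reliability(items: pd.DataFrame, signs: pd.Series | None = None,
                ) -> ReliabilityReport:
    """Cronbach's alpha (Feldt 95% CI) and corrected item-total correlations.

    ``signs`` (e.g. the factor loadings) flips negatively keyed items before
    scoring.  Corrected item-total correlates each item with the sum of the
    remaining items.
    """
    X = pd.DataFrame(items).astype(float)
    if X.shape[1] < 2:
        raise ValueError("reliability needs >= 2 items")
    if (X.std(ddof=1) <= 0).any():
        bad = X.columns[X.std(ddof=1) <= 0].tolist()
        raise ValueError(f"zero-variance item(s): {bad}")
    if signs is not None:
        flip = np.sign(np.asarray(signs, dtype=float))
        flip[flip == 0] = 1.0
        X = X * flip
    n, k = X.shape
    item_var = X.var(ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    alpha = (k / (k - 1)) * (1.0 - item_var.sum() / total_var)
    # Feldt (1965): (1 - alpha) follows a scaled F(n-1, (n-1)(k-1))
    fl = stats.f.ppf(0.975, n - 1, (n - 1) * (k - 1))
    fu = stats.f.ppf(0.025, n - 1, (n - 1) * (k - 1))
    ci = (1 - (1 - alpha) * fl, 1 - (1 - alpha) * fu)
    itc = {}
    for c in X.columns:
        rest = X.drop(columns=c).sum(axis=1)
        itc[c] = float(stats.pearsonr(X[c], rest)[0])
    return ReliabilityReport(float(alpha), (float(ci[0]), float(ci[1])),
                             pd.Series(itc))


def factor_score_assoc(scores: pd.DataFrame, y, n_boot: int = 10000,
                       seed: int = 0) -> pd.DataFrame:
    """Per-factor Spearman correlation with %NC, percentile bootstrap 95% CI."""
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for c in scores.columns:
        s = scores[c].to_numpy()
        if np.std(s) == 0:
            rows.append({"factor": c, "r": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "skipped": "constant score column"})
            continue
        r = stats.spearmanr(s, y)[0]
        boots = np.array([stats.spearmanr(s[ix], y[ix])[0] for ix in idx])
        rows.append({"factor": c, "r": float(r),
                     "ci_lo": float(np.nanpercentile(boots, 2.5)),
                     "ci_hi": float(np.nanpercentile(boots, 97.5)),
                     "skipped": ""})
    return pd.DataFrame(rows).set_index("factor")


def hclust_variables(table: pd.DataFrame, invert: list[str] | None = None,
                     k_range: tuple[int, int] = (2, 6),
                     ) -> tuple[np.ndarray, int, pd.Series]:
    """Ward/Euclidean clustering of variables with silhouette-selected k.

    The table should be z-scored; columns named in ``invert`` are negated
    first (indices whose healthy direction is high).  Variables are treated
    as points with subjects as coordinates.  Returns (linkage matrix, chosen
    k, memberships).
    """
    X = pd.DataFrame(table).astype(float).copy()
    for c in invert or []:
        X[c] = -X[c]
    pts = X.to_numpy().T  # variables x subjects
    if pts.shape[0] < max(3, k_range[0] + 1):
        raise ValueError("clustering needs more variables than the minimum k")
    Z = linkage(pts, method="ward", metric="euclidean")
    best_k, best_s = None, -np.inf
    for k in range(k_range[0], min(k_range[1], pts.shape[0] - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(pts, labels, metric="euclidean")
        if s > best_s:
            best_k, best_s = k, s
    labels = fcluster(Z, best_k, criterion="maxclust")
    return Z, int(best_k), pd.Series(labels, index=X.columns)
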