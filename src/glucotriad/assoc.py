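"""Regression and feature-selection stages linking glucose features to %NC.

z-scoring, OLS with AIC/VIF, iterative VIF pruning, the bootstrap Spearman
correlation network with Benjamini-Hochberg correction, LASSO with
leave-one-out cross-validation, PLS with VIP scores, and the Fisher-z
power/sample-size calculation for a correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import lasso_path
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

AIC_FLOOR = -1e12  # reported in place of -inf on an exactly perfect fit


@dataclass
class RegressionReport:
    coef: pd.Series
    conf_int: pd.DataFrame      # 95% CI per coefficient
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aic: float
    vif: pd.Series
    perfect_fit: bool = False


@dataclass
class LassoReport:
    lambdas: np.ndarray
    cv_mse: np.ndarray
    optimal_lambda: float
    coef_path: pd.DataFrame     # variables x lambdas
    coef: pd.Series             # refit at the optimum, full data
    nonzero: list[str] = field(default_factory=list)


@dataclass
class PlsReport:
    n_components: int
    vip: pd.Series
    cv_mse: np.ndarray          # LOO MSE per candidate component count


@dataclass
class NetworkEdge:
    a: str
    b: str
    r: float
    ci: tuple[float, float]
    p: float
    q: float
    significant: bool


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column to mean 0 and sample Std 1 (ddof=1)."""
    sd = table.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    return (table - table.mean()) / sd


def fit_ols(X: pd.DataFrame, y) -> RegressionReport:
    """OLS of y on standardized X with t-based 95% CIs, Gaussian-ML AIC, VIF.

    The AIC convention is Gaussian maximum likelihood with all constants and
    parameter count p + 1 (coefficients plus intercept; sigma not counted),
    fixed for internal model comparison.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, design).fit()
    perfect = fit.ssr <= 1e-12 * max(1.0, float(np.sum(y ** 2)))
    aic = AIC_FLOOR if perfect else float(fit.aic)
    Xv = X.to_numpy()
    design_np = np.column_stack([np.ones(n), Xv])
    vif = pd.Series([variance_inflation_factor(design_np, j + 1) for j in range(p)],
                    index=X.columns)
    return RegressionReport(
        coef=fit.params, conf_int=fit.conf_int(alpha=0.05), pvalues=fit.pvalues,
        r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj), aic=aic,
        vif=vif, perfect_fit=bool(perfect))


def vif_prune(X: pd.DataFrame, threshold: float = 10.0,
              ) -> tuple[list[str], list[tuple[str, float]]]:
    """Drop the single highest-VIF column until all VIFs are below threshold.

    Ties break to the first column in input order.  Returns the retained
    column names and the removal trail [(name, vif_at_removal), ...].
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF pruning needs >= 2 variables")
    cols = list(X.columns)
    trail: list[tuple[str, float]] = []
    while len(cols) >= 2:
        design = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in cols])
        with np.errstate(divide="ignore"):
            vifs = np.array([variance_inflation_factor(design, j + 1)
                             for j in range(len(cols))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        worst = int(np.argmax(vifs))  # argmax takes the first maximum
        if vifs[worst] < threshold:
            break
        trail.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return cols, trail


def spearman_network(table: pd.DataFrame, n_boot: int = 10000,
                     q_threshold: float = 0.05, seed: int = 0,
                     ) -> list[NetworkEdge]:
    """All pairwise Spearman correlations with bootstrap CIs and BH Q-values.

    Subjects are resampled with replacement for percentile 95% CIs;
    Benjamini-Hochberg correction is applied jointly across all pairs.
    Pairs involving a constant column are skipped.
    """
    if len(table) < 3:
        raise ValueError("network needs >= 3 subjects")
    rng = np.random.default_rng(seed)
    cols = list(table.columns)
    data = table.to_numpy(dtype=float)
    keep = [j for j, c in enumerate(cols) if np.std(data[:, j]) > 0]
    pairs = [(i, j) for k, i in enumerate(keep) for j in keep[k + 1:]]
    rho = np.empty(len(pairs))
    pval = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        rho[k], pval[k] = stats.spearmanr(data[:, i], data[:, j])
    n = len(table)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    # rank once per bootstrap sample for all columns, then correlate pairs
    cis = np.empty((len(pairs), 2))
    boot_r = np.empty((n_boot, len(pairs)))
    with np.errstate(invalid="ignore", divide="ignore"):
        # a resample can draw a constant column; its NaN correlations are
        # dropped by the nanpercentile below
        for b in range(n_boot):
            sample = data[boot_idx[b]]
            ranks = stats.rankdata(sample, axis=0)
            rc = np.corrcoef(ranks, rowvar=False)
            for k, (i, j) in enumerate(pairs):
                boot_r[b, k] = rc[i, j]
    cis[:, 0] = np.nanpercentile(boot_r, 2.5, axis=0)
    cis[:, 1] = np.nanpercentile(boot_r, 97.5, axis=0)
    qvals = multipletests(pval, method="fdr_bh")[1]
    edges = []
    for k, (i, j) in enumerate(pairs):
        edges.append(NetworkEdge(cols[i], cols[j], float(rho[k]),
                                 (float(cis[k, 0]), float(cis[k, 1])),
                                 float(pval[k]), float(qvals[k]),
                                 bool(qvals[k] < q_threshold)))
    return edges


def default_lambda_grid() -> np.ndarray:
    """200 log-spaced regularization strengths in [1e-3, 1e2]."""
    return np.logspace(-3, 2, 200)


def lasso_loocv(X: pd.DataFrame, y, lambda_grid=None, seed: int = 0) -> LassoReport:
    """LASSO with the (1/2n) objective and leave-one-out CV over a lambda grid.

    Objective: (1/(2n)) ||y - b0 - X b||^2 + lambda ||b||_1 with the intercept
    unpenalized, so lambda is on the same scale as scikit-learn's ``alpha``.
    The optimum is the exact argmin of the LOO mean-squared error on the grid;
    coefficients are refit on the full data at the optimum.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("LOO-CV needs n >= 3")
    grid = np.sort(np.asarray(
        default_lambda_grid() if lambda_grid is None else lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    Xv = X.to_numpy()
    n = len(y)

    def _path(Xs, ys):
        # centering X and y makes the unpenalized intercept implicit
        xm, ym = Xs.mean(axis=0), ys.mean()
        _, coefs, _ = lasso_path(Xs - xm, ys - ym, alphas=grid[::-1],
                                 max_iter=50000, tol=1e-8)
        return coefs[:, ::-1], xm, ym  # p x n_lambda, ascending grid order

    errs = np.zeros((n, grid.size))
    for fold, (tr, te) in enumerate(LeaveOneOut().split(Xv)):
        coefs, xm, ym = _path(Xv[tr], y[tr])
        pred = (Xv[te] - xm) @ coefs + ym
        errs[fold] = (pred.ravel() - y[te][0]) ** 2
    cv_mse = errs.mean(axis=0)
    best = int(np.argmin(cv_mse))
    path, _, _ = _path(Xv, y)
    coef = pd.Series(path[:, best], index=X.columns)
    return LassoReport(
        lambdas=grid, cv_mse=cv_mse, optimal_lambda=float(grid[best]),
        coef_path=pd.DataFrame(path, index=X.columns, columns=grid),
        coef=coef, nonzero=[c for c in X.columns if coef[c] != 0.0])


def vip_scores(pls: PLSRegression, feature_names) -> pd.Series:
    """VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a).

    SS_a is the y-variance explained by component a (q_a^2 t_a' t_a); the
    scores satisfy sum_j VIP_j^2 = p.
    """
    W = pls.x_weights_           # p x A
    T = pls.x_scores_            # n x A
    Q = pls.y_loadings_          # 1 x A
    p, A = W.shape
    ss = (Q.ravel() ** 2) * np.sum(T ** 2, axis=0)
    wnorm2 = np.sum(W ** 2, axis=0)
    vip = np.sqrt(p * ((W ** 2 / wnorm2) @ ss) / ss.sum())
    return pd.Series(vip, index=list(feature_names))


def pls_vip(X: pd.DataFrame, y, max_components: int = 5) -> PlsReport:
    """PLS regression with LOO-CV component selection and VIP scores."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("PLS needs n >= 3")
    if np.std(y) == 0:
        raise ValueError("zero-variance outcome")
    n, p = X.shape
    kmax = max(1, min(max_components, p, n - 1))
    Xv = X.to_numpy()
    cv_mse = np.empty(kmax)
    for a in range(1, kmax + 1):
        errs = []
        for tr, te in LeaveOneOut().split(Xv):
            m = PLSRegression(n_components=a, scale=False).fit(Xv[tr], y[tr])
            errs.append(float((m.predict(Xv[te]).ravel()[0] - y[te][0]) ** 2))
        cv_mse[a - 1] = float(np.mean(errs))
    best = int(np.argmin(cv_mse)) + 1
    m = PLSRegression(n_components=best, scale=False).fit(Xv, y)
    return PlsReport(n_components=best, vip=vip_scores(m, X.columns), cv_mse=cv_mse)


def power_sample_size(r: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Minimum n to detect correlation r != 0 (two-sided Fisher-z test).

    n = ceil(((z_{1-alpha/2} + z_power) / atanh(r))^2) + 3.
    """
    if not (0 < abs(r) < 1):
        raise ValueError("expected correlation must satisfy 0 < |r| < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    return int(math.ceil(((za + zb) / math.atanh(abs(r))) ** 2) + 3)
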