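"""Descriptive statistics: paired frame tests, usage PCA, OLS with nested
ANOVA comparison, PMVD relative importance with bootstrap, Spearman rank
correlation and stepwise AIC selection.

PMVD (proportional marginal variance decomposition) apportions a
regression's R-squared across correlated regressors using Feldman's
data-dependent ordering weights: each ordering of the p regressors
contributes its sequential R-squared increments, weighted proportionally to
the product over the ordering's prefixes of the inverse remaining
unexplained variance. Orderings are enumerated exactly (p <= 6), which is
how the decomposition behaves in the small designs used here (at most the
three positional G+C fractions).
"""
from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclasses.dataclass
class PCAResult:
    loadings: np.ndarray            # variables x components
    variance_fractions: np.ndarray  # per component
    scores: np.ndarray              # observations x components


@dataclasses.dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    r_squared: float
    adjusted_r_squared: float
    residuals: np.ndarray
    anova_p: float | None = None    # F-test vs the nested comparison model
    aic: float | None = None
    model: object | None = None


@dataclasses.dataclass
class PMVDResult:
    shares: np.ndarray
    r_squared: float
    bootstrap_ci: np.ndarray | None = None  # (p, 2) percentile intervals


def paired_frame_test(per_gene):
    """Paired t-test of per-gene (n2, n3) OSC counts.

    Returns (t, p, direction) with direction '+2', '+3' or 'none'.
    """
    arr = np.asarray(per_gene, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 genes of (n2, n3) counts")
    diff = arr[:, 0] - arr[:, 1]
    if diff.std(ddof=1) == 0:
        if diff.mean() == 0:
            return 0.0, 1.0, "none"
        return math.copysign(math.inf, diff.mean()), 0.0, "+2" if diff.mean() > 0 else "+3"
    t, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
    direction = "none"
    if p < 0.05:
        direction = "+2" if t > 0 else "+3"
    return float(t), float(p), direction


def pca_usage(matrix) -> PCAResult:
    """PCA of an OSC-usage matrix (genomes x usage variables).

    Centers but does not scale (all variables are frequencies); signs fixed
    so each component's largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("undefined (NaN) usage rows must be excluded first")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return PCAResult(loadings=Vt.T, variance_fractions=np.zeros_like(var),
                         scores=np.zeros_like(U))
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    return PCAResult(loadings=Vt.T, variance_fractions=var / total,
                     scores=U * s)


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def fit_regression(y, X, compare_to=None) -> RegressionResult:
    """OLS of y on X (intercept added); optional nested-model ANOVA F-test.

    ``compare_to`` names a subset of X's columns forming the nested model;
    the reported ``anova_p`` is the F-test p-value for the improvement of
    the full model over that subset.
    """
    Xdf = _as_design(X)
    y = np.asarray(y, dtype=float)
    if len(y) < Xdf.shape[1] + 2:
        raise ValueError("too few observations for the design")
    design = sm.add_constant(Xdf)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        _, R = np.linalg.qr(design.values)
        bad = [design.columns[i] for i in range(design.shape[1])
               if abs(R[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    anova_p = None
    if compare_to is not None:
        sub = sm.add_constant(Xdf[list(compare_to)]) if len(compare_to) else \
            pd.DataFrame({"const": np.ones(len(y))})
        fit0 = sm.OLS(y, sub).fit()
        anova = sm.stats.anova_lm(fit0, fit)
        anova_p = float(anova["Pr(>F)"].iloc[1])
    return RegressionResult(
        params=fit.params, bse=fit.bse, r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj), residuals=np.asarray(fit.resid),
        anova_p=anova_p, aic=float(fit.aic), model=fit)


def _subset_r2(y, X, cols: frozenset) -> float:
    if not cols:
        return 0.0
    Xs = X[:, sorted(cols)]
    design = np.column_stack([np.ones(len(y)), Xs])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid ** 2).sum() / tss if tss > 0 else 0.0


def _pmvd_shares(y, X) -> tuple[np.ndarray, float]:
    n, p = X.shape
    r2_cache: dict[frozenset, float] = {}

    def r2(cols: frozenset) -> float:
        if cols not in r2_cache:
            r2_cache[cols] = _subset_r2(y, X, cols)
        return r2_cache[cols]

    full = r2(frozenset(range(p)))
    if p == 1:
        return np.array([full]), full
    eps = 1e-12
    weights = []
    increments = []
    for perm in itertools.permutations(range(p)):
        w = 1.0
        inc = np.zeros(p)
        prev = 0.0
        cols = frozenset()
        for i, k in enumerate(perm):
            cols = cols | {k}
            cur = r2(cols)
            inc[k] = cur - prev
            prev = cur
            if i < p - 1:
                w *= 1.0 / max(full - cur, eps)
        weights.append(w)
        increments.append(inc)
    weights = np.array(weights)
    weights /= weights.sum()
    shares = (weights[:, None] * np.array(increments)).sum(axis=0)
    return shares, full


def pmvd_importance(y, X, n_boot: int = 1000, seed: int = 0) -> PMVDResult:
    """PMVD relative-importance shares with case-resampling bootstrap CIs.

    Shares are non-negative and sum to the model R-squared; exact
    enumeration over the p! orderings (p <= 6 enforced).
    """
    X = np.asarray(_as_design(X), dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] > 6:
        raise ValueError("exact PMVD enumeration supports at most 6 regressors")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("regressor with zero variance")
    shares, full = _pmvd_shares(y, X)
    ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, X.shape[1]))
        n = len(y)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b], _ = _pmvd_shares(y[idx], X[idx])
        ci = np.percentile(boots, [2.5, 97.5], axis=0).T
    return PMVDResult(shares=shares, r_squared=full, bootstrap_ci=ci)


def lmg_importance(y, X) -> np.ndarray:
    """LMG decomposition (equal ordering weights); cross-check for PMVD."""
    X = np.asarray(_as_design(X), dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    inc_sum = np.zeros(p)
    perms = list(itertools.permutations(range(p)))
    for perm in perms:
        prev = 0.0
        cols = frozenset()
        for k in perm:
            cols = cols | {k}
            cur = _subset_r2(y, X, cols)
            inc_sum[k] += cur - prev
            prev = cur
    return inc_sum / len(perms)


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with midrank ties; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def stepwise_aic(y, X, direction: str = "both"):
    """Greedy add/drop AIC minimisation starting from the full model.

    Returns (selected column names, RegressionResult of the selected model).
    Ties break toward the earlier column.
    """
    if direction != "both":
        raise ValueError("only direction='both' is supported")
    Xdf = _as_design(X)
    if Xdf.shape[1] == 0:
        raise ValueError("empty design")
    y = np.asarray(y, dtype=float)
    cols = list(Xdf.columns)
    current = list(cols)

    def aic_of(subset) -> float:
        design = sm.add_constant(Xdf[subset]) if subset else \
            pd.DataFrame({"const": np.ones(len(y))}, index=Xdf.index)
        return float(sm.OLS(y, design).fit().aic)

    best = aic_of(current)
    improved = True
    while improved:
        improved = False
        candidates = []
        for c in current:
            subset = [x for x in current if x != c]
            candidates.append((aic_of(subset), subset))
        for c in cols:
            if c not in current:
                candidates.append((aic_of(current + [c]), current + [c]))
        for cand_aic, subset in candidates:
            if cand_aic < best - 1e-12:
                best, current, improved = cand_aic, subset, True
                break
    result = fit_regression(y, Xdf[current], None) if current else None
    return current, result


def ogt_regression(df: pd.DataFrame, response: str = "pct_deviation",
                   regressors=("ogt", "gc", "at_skew")):
    """Growth-temperature analysis: OLS of OSC overrepresentation on OGT
    with compositional covariates, plus stepwise AIC selection.

    Categorical OGT labels are mapped to category midpoints when no numeric
    optimum is available.
    """
    midpoints = {"psychrophile": 10.0, "mesophile": 37.0,
                 "thermophile": 60.0, "hyperthermophile": 85.0}
    work = df.copy()
    if work["ogt"].dtype == object:
        work["ogt"] = work["ogt"].map(midpoints)
    fit = fit_regression(work[response], work[list(regressors)],
                         compare_to=[r for r in regressors if r != "ogt"])
    selected, sel_fit = stepwise_aic(work[response], work[list(regressors)])
    return fit, selected, sel_fit
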