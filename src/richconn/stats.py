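"""Group inference and covariate-adjusted correlation.

Group differences in network quantities are tested with a nonparametric
permutation test on the difference of group means. Covariates (age, sex,
education) are removed with the Freedman-Lane scheme: the pooled values are
residualized on the covariates once, and group labels are then permuted over
the residuals, which preserves exchangeability under the null. P-values use
the add-one estimator (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).

Clinical associations use Spearman rank correlation of covariate-residualized
values. Holm-Bonferroni (FWE) and Benjamini-Hochberg (FDR) corrections are
both available; Holm is the default family-wise correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationTestResult:
    observed: float
    n_perm: int
    p_raw: float
    p_adjusted: float | None = None
    method: str | None = None
    seed: int | None = None


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    covariates: tuple = ()
    undefined: bool = False


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, tuple]:
    """Design matrix [1 | covariates] with sex-style columns already numeric."""
    if covariates is None:
        return np.ones((n, 1)), ()
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = tuple(f"c{i}" for i in range(cov.shape[1]))
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match the number of subjects")
    if np.any(~np.isfinite(cov)):
        raise ValueError("covariates contain missing or non-finite values")
    return np.column_stack([np.ones(n), cov]), names


def residualize(values, covariates) -> np.ndarray:
    """OLS residuals of values on intercept + covariates (residuals sum to 0)."""
    y = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("values contain missing or non-finite entries")
    x, _ = _covariate_matrix(covariates, len(y))
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return y - x @ beta


def permutation_group_test(
    g1,
    g2,
    covariates=None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Two-tailed permutation test on the difference of group means.

    ``covariates`` (if given) is the pooled covariate table in the order
    [g1; g2]; values are residualized once (Freedman-Lane) before labels are
    permuted.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([g1, g2])
    res = residualize(pooled, covariates) if covariates is not None else pooled - pooled.mean()
    n1 = len(g1)
    n = len(res)
    observed = res[:n1].mean() - res[n1:].mean()
    rng = np.random.default_rng(seed)
    # vectorized label permutations: mean difference from the permuted first block
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_first = res[idx[:, :n1]].mean(axis=1)
    total_mean = res.mean()
    # mean of complement from the total: (n*mu - n1*m1) / (n - n1)
    perm_second = (n * total_mean - n1 * perm_first) / (n - n1)
    t_perm = perm_first - perm_second
    tol = 1e-12 * max(1.0, abs(observed))
    exceed = int(np.sum(np.abs(t_perm) >= abs(observed) - tol))
    p_raw = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(float(observed), n_perm, float(p_raw), seed=seed)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05):
    """Step-down Holm-Bonferroni FWE adjustment; returns (adjusted, reject)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05):
    """Step-up Benjamini-Hochberg FDR adjustment; returns (adjusted, reject)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def spearman_partial(x, y, covariates=None) -> CorrelationResult:
    """Spearman correlation of covariate-residualized x and y.

    Both variables are residualized on intercept + covariates by OLS, then
    rank-correlated; the two-tailed p uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("at least 4 observations are required")
    _, names = _covariate_matrix(covariates, len(x))
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), names, undefined=True)
    rho, p = sps.spearmanr(rx, ry)
    return CorrelationResult(float(rho), float(p), len(x), names)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with two-tailed p.

    Exact enumeration for small samples (min(n, m) <= 8) without ties;
    otherwise the normal approximation with midrank tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square_2x2(table, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (1 df).

    Continuity (Yates) correction is off by default and available by flag.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=continuity)
    return float(stat), float(p)
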