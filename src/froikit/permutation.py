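"""Matched-sample permutation tests with pooled familywise alpha.

For each region, the six ROI parameters (found-flag included) are
compared between groups with a two-sample t-test; the group labels are
then permuted (25,000 times by default) and the same test applied,
yielding a null matrix of p-values.  All null p-values for the region
are pooled and sorted, and the empirical alpha is the (5 / family_size)
percentile of the pool — the threshold at which the chance of *any*
parameter in the region crossing it under the null is 5%.

The variance analogue replaces the t-test with the Ansari–Bradley
rank test of equal scale and omits the found-flag (its mean and
variance are functionally tied), giving family_size 5 and the 1%
pooled percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationTestResult",
    "pooled_percentile", "pooled_empirical_alpha",
    "matched_mean_test", "matched_variance_test",
    "ansari_bradley", "ab_scores",
]

MEAN_TEST_PARAMS = ("found", "size", "mean_t", "com_x", "com_y", "com_z")
VARIANCE_TEST_PARAMS = ("size", "mean_t", "com_x", "com_y", "com_z")


@dataclass
class PermutationTestResult:
    region: str
    parameter: str
    observed_p: float
    empirical_alpha: float
    significant: bool
    n_perm: int
    seed: int


def pooled_percentile(family_size: int) -> float:
    """The percentile of the pooled null used as the familywise cutoff:
    the 5th percentile divided by the number of comparisons."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return 5.0 / family_size


def pooled_empirical_alpha(null_p_values: np.ndarray,
                           family_size: int) -> float:
    """Pool, sort, and take the (5/family_size) percentile p-value.

    ``null_p_values`` is an (n_perm, n_parameters) matrix (or any
    array); the returned alpha is the order statistic at the pooled
    percentile (lower interpolation, so the alpha is an actually
    attained null p-value).
    """
    pool = np.asarray(null_p_values, dtype=float).ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("empty null p-value pool")
    q = pooled_percentile(family_size)
    return float(np.percentile(pool, q, method="lower"))


def _student_t_p(data: np.ndarray, mask_a: np.ndarray,
                 welch: bool = False) -> np.ndarray:
    """Two-sample t-test p-values, vectorized over columns of ``data``.

    ``mask_a`` is (n,) or (n, n_perm) boolean; returns p of shape
    (n_params,) or (n_params, n_perm)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    mask_a = np.asarray(mask_a, dtype=float)
    squeeze = mask_a.ndim == 1
    if squeeze:
        mask_a = mask_a[:, None]
    na = mask_a.sum(axis=0)  # (n_perm,)
    nb = n - na
    sum_a = data.T @ mask_a  # (k, n_perm)
    sq_a = (data ** 2).T @ mask_a
    tot = data.sum(axis=0)[:, None]
    tot_sq = (data ** 2).sum(axis=0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_a = sum_a / na
        sum_b = tot - sum_a
        sq_b = tot_sq - sq_a
        mean_b = sum_b / nb
        var_a = (sq_a - na * mean_a ** 2) / (na - 1)
        var_b = (sq_b - nb * mean_b ** 2) / (nb - 1)
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if welch:
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(se2)
            df = se2 ** 2 / ((var_a / na) ** 2 / (na - 1)
                             + (var_b / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = np.broadcast_to(na + nb - 2, t.shape)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 1.0)  # zero-variance ties -> p 1
    return p[:, 0] if squeeze else p


def ab_scores(pooled: np.ndarray) -> np.ndarray:
    """Ansari–Bradley scores of a pooled sample, in input order.

    Ranks run from both ends of the sorted pooled sample inward
    (1, 2, ..., and 1, 2, ... from the top), so small scores mark
    extreme values; ties receive the mid-rank of their scores.
    """
    pooled = np.asarray(pooled, dtype=float)
    n = pooled.size
    ranks = stats.rankdata(pooled, method="average")
    # score for untied rank i is min(i, n + 1 - i); with ties, averaging
    # the scores of the tied positions equals applying min() to midranks
    # only when the tie block does not straddle the center, so compute
    # from ordinal ranks then average within ties.
    order = np.argsort(pooled, kind="stable")
    ordinal = np.empty(n, dtype=float)
    ordinal[order] = np.arange(1, n + 1)
    raw = np.minimum(ordinal, n + 1 - ordinal)
    # average raw scores within tied groups
    out = np.empty(n)
    _, inv = np.unique(pooled, return_inverse=True)
    sums = np.bincount(inv, weights=raw)
    counts = np.bincount(inv)
    out = (sums / counts)[inv]
    return out


def _ab_moments(scores: np.ndarray, m: int):
    """Mean and variance of the AB statistic (sum of scores over a random
    m-subset) under the permutation null, from finite-population sampling
    theory of a linear rank statistic."""
    n = scores.size
    mean = m * scores.mean()
    var = (m * (n - m) / (n * (n - 1))) * np.sum((scores - scores.mean()) ** 2)
    return mean, var


def ansari_bradley(x, y, method: str = "auto"):
    """Ansari–Bradley two-sample test of equal scale.

    Returns (statistic, p).  The statistic is the sum of AB scores over
    ``x``.  ``method`` is 'exact' (full enumeration over label
    assignments), 'approx' (normal approximation with tie-corrected
    variance), or 'auto' (exact when the pooled size is <= 16 and there
    is no memory blow-up).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied; scale test undefined")
    scores = ab_scores(pooled)
    m, n = x.size, pooled.size
    statistic = float(scores[:m].sum())
    if method == "auto":
        method = "exact" if n <= 16 else "approx"
    if method == "exact":
        null = np.array([scores[list(idx)].sum()
                         for idx in combinations(range(n), m)])
        p_low = np.mean(null <= statistic + 1e-12)
        p_high = np.mean(null >= statistic - 1e-12)
        p = min(1.0, 2.0 * min(p_low, p_high))
    elif method == "approx":
        mean, var = _ab_moments(scores, m)
        z = (statistic - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return statistic, float(p)


def _ab_p_vectorized(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Normal-approximation AB p-values for many label assignments.

    ``values`` (n,), ``mask_a`` (n,) or (n, n_perm) with a fixed group-A
    size per column."""
    scores = ab_scores(values)
    mask_a = np.asarray(mask_a, dtype=float)
    squeeze = mask_a.ndim == 1
    if squeeze:
        mask_a = mask_a[:, None]
    m = int(round(mask_a[:, 0].sum()))
    mean, var = _ab_moments(scores, m)
    statistic = scores @ mask_a
    z = (statistic - mean) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p[0]) if squeeze else p


def _permutation_masks(n: int, n_a: int, n_perm: int, rng) -> np.ndarray:
    masks = np.zeros((n, n_perm), dtype=bool)
    for j in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        masks[idx, j] = True
    return masks


def _run_family_test(param_matrix: pd.DataFrame, group_labels,
                     parameters, p_fun, n_perm, seed,
                     region: str) -> list[PermutationTestResult]:
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    mask_obs = labels == uniq[0]
    n = labels.size

    usable, data_cols = [], []
    for p_name in parameters:
        col = np.asarray(param_matrix[p_name], dtype=float)
        if np.nanstd(col) == 0 or np.all(~np.isfinite(col)):
            continue  # constant parameter: excluded
        usable.append(p_name)
        data_cols.append(col)
    if not usable:
        raise ValueError("no non-degenerate parameters to test")
    data = np.column_stack(data_cols)
    # listwise completion within the family so every permutation reuses
    # one aligned matrix
    complete = np.all(np.isfinite(data), axis=1)
    data = data[complete]
    mask_obs_c = mask_obs[complete]
    n_c = int(complete.sum())
    n_a = int(mask_obs_c.sum())

    rng = np.random.default_rng(seed)
    observed = p_fun(data, mask_obs_c)
    masks = _permutation_masks(n_c, n_a, n_perm, rng)
    null = p_fun(data, masks)  # (k, n_perm)
    alpha = pooled_empirical_alpha(null.T, family_size=len(parameters))
    results = []
    for i, p_name in enumerate(usable):
        obs_p = float(observed[i])
        results.append(PermutationTestResult(
            region=region, parameter=p_name, observed_p=obs_p,
            empirical_alpha=alpha, significant=bool(obs_p < alpha),
            n_perm=n_perm, seed=int(seed)))
    return results


def matched_mean_test(param_matrix: pd.DataFrame, group_labels,
                      n_perm: int = 25000, seed: int = 0,
                      region: str = "", welch: bool = False,
                      parameters=MEAN_TEST_PARAMS):
    """Permutation-calibrated group mean comparison over ROI parameters.

    All six parameters enter (the found-flag as a 0/1 t-test on
    proportions); family_size is the number of parameters requested,
    6 by default, so the pooled alpha sits at the 0.83 percentile.
    """
    return _run_family_test(
        param_matrix, group_labels, parameters,
        lambda d, m_: _student_t_p(d, m_, welch=welch),
        n_perm, seed, region)


def matched_variance_test(param_matrix: pd.DataFrame, group_labels,
                          n_perm: int = 25000, seed: int = 0,
                          region: str = "",
                          parameters=VARIANCE_TEST_PARAMS):
    """Permutation-calibrated group variance comparison (Ansari–Bradley).

    The found-flag is omitted (family_size 5, pooled percentile 1%).
    """
    def p_fun(data, mask):
        if mask.ndim == 1:
            return np.array([_ab_p_vectorized(data[:, i], mask)
                             for i in range(data.shape[1])])
        return np.vstack([_ab_p_vectorized(data[:, i], mask)
                          for i in range(data.shape[1])])
    return _run_family_test(param_matrix, group_labels, parameters,
                            p_fun, n_perm, seed, region)
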