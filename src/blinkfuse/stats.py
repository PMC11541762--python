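"""Group statistics: paired t-tests with FDR and the extreme-pixel permutation test.

Method contrasts (e.g. fused vs unimodal decoding curves) are tested with
two-sided paired t-tests across participants, Benjamini–Hochberg corrected
over comparison points.  Family-wise inference over temporal generalization
matrices uses an extreme-pixel permutation test: per permutation the
participant condition assignment is randomly flipped, the mean difference
map is computed, and its single maximum and minimum pixels are recorded;
observed pixels beyond the tail quantiles of these extreme-value
distributions are significant, which controls the family-wise error without
a cluster-forming threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ttest_rel
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedTestResult:
    """Pointwise paired-t results with FDR-adjusted p-values."""

    t_stat: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray     # p_fdr < alpha
    alpha: float
    undefined: np.ndarray       # zero-variance differences


@dataclass
class PermutationNull:
    """Extreme-pixel null distributions and the resulting significance mask."""

    n_perm: int
    max_dist: np.ndarray
    min_dist: np.ndarray
    upper_critical: float
    lower_critical: float
    observed_map: np.ndarray
    significance_mask: np.ndarray
    alpha: float


def fdr_correct(p_raw: np.ndarray, alpha: float = 0.05,
                method: str = "fdr_bh") -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR correction; returns (reject flags, adjusted p-values).

    Benjamini–Hochberg by default; Benjamini–Yekutieli (``fdr_by``) for
    dependent tests.
    """
    reject, p_adj, _, _ = multipletests(np.asarray(p_raw, dtype=float),
                                        alpha=alpha, method=method)
    return reject, p_adj


def paired_t_fdr(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> PairedTestResult:
    """Two-sided paired t per point with Benjamini–Hochberg correction.

    ``a`` and ``b`` are participants x points; 1-D inputs are treated as a
    single comparison point with one value per participant.  Points whose
    paired differences have zero variance (but are not exactly equal) are
    flagged undefined and excluded from the correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shapes")
    if a.ndim == 1:
        a, b = a[:, None], b[:, None]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 participants for a paired t-test")

    diffs = a - b
    undefined = diffs.std(axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_stat, p_raw = ttest_rel(a, b, axis=0)
    t_stat = np.asarray(t_stat, dtype=float)
    p_raw = np.asarray(p_raw, dtype=float)
    # a = b exactly at a point: t = 0, p = 1 (no rejection), not undefined-NaN
    zero_diff = undefined & np.all(diffs == 0, axis=0)
    t_stat[zero_diff] = 0.0
    p_raw[zero_diff] = 1.0
    undefined = undefined & ~zero_diff
    p_raw[undefined] = np.nan

    p_fdr = np.full_like(p_raw, np.nan)
    valid = ~np.isnan(p_raw)
    if valid.any():
        _, p_adj, _, _ = multipletests(p_raw[valid], alpha=alpha, method=method)
        p_fdr[valid] = p_adj
    significant = np.zeros_like(valid)
    significant[valid] = p_fdr[valid] < alpha
    return PairedTestResult(t_stat=t_stat, p_raw=p_raw, p_fdr=p_fdr,
                            significant=significant, alpha=alpha,
                            undefined=undefined)


def extreme_pixel_permutation(
    observed_maps: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> PermutationNull:
    """Two-tailed extreme-pixel permutation test on paired difference maps.

    ``observed_maps`` is participants x (map shape): one difference map per
    participant (condition A minus condition B).  Each permutation flips the
    sign of every participant's map independently — equivalent to randomly
    reallocating participants between the two paired conditions — and the
    mean map's extreme pixels are collected over ``n_perm`` iterations.  At
    the default alpha = 0.01 the criticals are the 99.5th percentile of the
    maximum distribution and the 0.5th percentile of the minimum
    distribution.
    """
    maps = np.asarray(observed_maps, dtype=float)
    if maps.ndim < 2:
        raise ValueError("observed_maps must be participants x map")
    n_p = maps.shape[0]
    if n_p < 2:
        raise ValueError("need at least 2 participants")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable extreme-value quantiles",
                      stacklevel=2)

    flat = maps.reshape(n_p, -1)
    rng = np.random.default_rng(seed)
    max_dist = np.empty(n_perm)
    min_dist = np.empty(n_perm)
    chunk = max(1, int(5e7 // max(flat.size, 1)))  # bound permutation memory
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_p))
        perm_means = signs @ flat / n_p
        max_dist[done:done + m] = perm_means.max(axis=1)
        min_dist[done:done + m] = perm_means.min(axis=1)
        done += m

    upper = float(np.quantile(max_dist, 1.0 - alpha / 2.0))
    lower = float(np.quantile(min_dist, alpha / 2.0))
    observed = maps.mean(axis=0)
    mask = (observed > upper) | (observed < lower)
    return PermutationNull(
        n_perm=n_perm, max_dist=max_dist, min_dist=min_dist,
        upper_critical=upper, lower_critical=lower,
        observed_map=observed, significance_mask=mask, alpha=alpha,
    )
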