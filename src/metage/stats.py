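"""Statistical primitives used throughout the pipeline.

Two-tailed Wilcoxon rank-sum and signed-rank tests, Benjamini-Hochberg
FDR adjustment, the Pearson-correlation t-test, log10 median-ratio
effect sizes, and 2x2 chi-squared enrichment.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "bh_adjust",
    "pearson_r_test",
    "log_median_ratio",
    "chi_square_enrichment",
]

_EXACT_MAX_N = 12


def rank_sum_test(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    The exact permutation distribution is used when both groups have at
    most 12 observations and there are no ties; otherwise the normal
    approximation with midranks, tie correction and continuity
    correction.  If every value in both groups is identical the test is
    degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be nonempty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def signed_rank_test(values) -> float:
    """Two-tailed Wilcoxon signed-rank p for the null of zero median.

    Zeros are dropped (Wilcoxon's original treatment).  For n <= 12 the
    exact distribution is computed by enumerating all 2^n sign vectors,
    with midranks for tied magnitudes, so exactness survives ties; for
    larger n the normal approximation with tie correction and continuity
    correction is used.  All-zero input gives p = 1.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    v = v[v != 0]
    n = v.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())
    if n <= _EXACT_MAX_N:
        # exact: distribution of W+ over all sign assignments
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        mean = ranks.sum() / 2.0
        dev = abs(w_plus - mean)
        p = np.mean(np.abs(totals - mean) >= dev - 1e-9)
        return float(min(p, 1.0))
    res = sps.wilcoxon(v, alternative="two-sided", method="approx", correction=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r_test(pred, true) -> tuple[float, float]:
    """Pearson r with the two-tailed t-test on n-2 degrees of freedom.

    t = r * sqrt(n - 2) / sqrt(1 - r^2).
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    n = pred.size
    if n != true.size or n < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(pred, true)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def log_median_ratio(x, y, pseudocount: float = 1e-10) -> float:
    """log10 of (median(x) + eps) / (median(y) + eps).

    The pseudocount guards zero medians; with eps = 0 and positive
    medians this is the plain log ratio of medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("vectors must be nonempty")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    mx = float(np.median(x)) + pseudocount
    my = float(np.median(y)) + pseudocount
    if mx <= 0 or my <= 0:
        raise ValueError("zero median with zero pseudocount")
    return float(np.log10(mx / my))


def chi_square_enrichment(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 table, 1 df.

    No continuity correction by default.  Zero row or column marginals
    make expected counts undefined and raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p)
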