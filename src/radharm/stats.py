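"""Statistical utilities: DeLong's test for paired ROC AUCs, Holm-Bonferroni
adjustment, Wilcoxon signed-rank wrappers, and confidence intervals.

DeLong's procedure estimates the variance of the difference of two AUCs
computed on the same test samples from the structural components
(placement values) of each score vector: V10_i = mean_j psi(x_i, y_j) over
negatives for each positive i, V01_j likewise over positives, with
psi = 1, 1/2, 0 for correct order, tie, inversion.  The AUC difference
divided by its standard error is compared with a standard normal
(two-sided).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def auc_from_scores(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC (probability a positive outranks a negative, ties
    counting half)."""
    labels = np.asarray(labels).astype(bool)
    pos = np.asarray(scores, float)[labels]
    neg = np.asarray(scores, float)[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: test set has a single class")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _placements(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    labels = np.asarray(labels).astype(bool)
    pos = np.asarray(scores, float)[labels]
    neg = np.asarray(scores, float)[~labels]
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_test(labels: np.ndarray, scores_a: np.ndarray,
                scores_b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided DeLong test for two correlated ROC curves.

    Returns (auc_a - auc_b, its variance, two-sided p).  Both score
    vectors must be for the same samples/labels.
    """
    v10a, v01a, auc_a = _placements(labels, scores_a)
    v10b, v01b, auc_b = _placements(labels, scores_b)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >=2 samples per class")
    s10 = np.cov(np.vstack([v10a, v10b]))  # ddof=1
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        # identical (or perfectly coupled) score vectors: no evidence of a
        # difference
        return diff, max(var, 0.0), 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return diff, var, float(p)


def delong_variance(labels: np.ndarray, scores_a: np.ndarray,
                    scores_b: np.ndarray) -> float:
    """Variance of the paired AUC difference (DeLong estimator)."""
    return delong_test(labels, scores_a, scores_b)[1]


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples; zero
    differences dropped (the classic treatment)."""
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float),
                         zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def t_confidence_interval(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi) t-distribution CI for a continuous sample."""
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    mean = float(arr.mean())
    if len(arr) < 2 or arr.std(ddof=1) == 0:
        return mean, mean, mean
    half = stats.t.ppf(0.5 + confidence / 2, len(arr) - 1) * arr.std(ddof=1) / np.sqrt(len(arr))
    return mean, mean - half, mean + half


def poisson_confidence_interval(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi) CI for a mean count, from the exact (chi-square)
    Poisson interval on the total count scaled back by the sample size."""
    arr = np.asarray(values, float)
    n = len(arr)
    total = float(arr.sum())
    a = 1.0 - confidence
    lo = stats.chi2.ppf(a / 2, 2 * total) / 2 if total > 0 else 0.0
    hi = stats.chi2.ppf(1 - a / 2, 2 * total + 2) / 2
    return total / n, lo / n, hi / n
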