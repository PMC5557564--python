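"""Paired Wilcoxon signed-rank testing and the pairwise comparison report.

All cross-subject comparisons in the study use the two-sided Wilcoxon
signed-rank test at alpha = 0.05, with no multiple-comparison correction
(each pair is tested at its own alpha, as in the source protocol).  Zero
differences are dropped (the classical Wilcoxon policy).  The null
distribution of W+ is enumerated exactly over all 2^n sign assignments for
n <= 15 pairs and approximated by a tie-corrected normal otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ConfigurationError

EXACT_LIMIT = 15


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided p by full enumeration of sign assignments over the actual
    (possibly tied, hence fractional) ranks."""
    n = len(ranks)
    # all 2^n subset sums of the rank vector
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    total = len(sums)
    eps = 1e-9
    p_le = np.sum(sums <= w_plus + eps) / total
    p_ge = np.sum(sums >= w_plus - eps) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Tie- and continuity-corrected normal approximation."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns (W, p) with W = min(W+, W-).  Zero differences are dropped; if
    every difference is zero the result is (0, 1) with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if len(d) <= EXACT_LIMIT:
        p = _exact_two_sided_p(w_plus, ranks)
    else:
        p = _normal_two_sided_p(w_plus, ranks)
    return w, p


@dataclass
class PairedScores:
    """Subjects x conditions score table (F1, parameter counts, or EOF)."""

    condition_labels: list[str]
    scores: np.ndarray  # (n_subjects, n_conditions)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        if self.scores.ndim != 2 or self.scores.shape[1] < 2:
            raise ConfigurationError("need a 2-D table with >= 2 conditions")
        if self.scores.shape[1] != len(self.condition_labels):
            raise ConfigurationError("labels do not match the table width")
        if not np.all(np.isfinite(self.scores)):
            raise ConfigurationError("score table has missing/non-finite cells")


def _boxplot_summary(col: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(col, [25, 50, 75])
    iqr = q3 - q1
    in_whisker = col[(col >= q1 - 1.5 * iqr) & (col <= q3 + 1.5 * iqr)]
    return {"mean": float(col.mean()),
            "std": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(in_whisker.min()),
            "whisker_high": float(in_whisker.max())}


@dataclass
class ComparisonReport:
    condition_labels: list[str]
    p_values: np.ndarray        # symmetric matrix, diagonal 1
    significant: np.ndarray     # boolean matrix at alpha
    summaries: list[dict]
    alpha: float

    def to_dict(self) -> dict:
        return {"conditions": self.condition_labels,
                "alpha": self.alpha,
                "p_values": self.p_values.tolist(),
                "significant": self.significant.tolist(),
                "summaries": self.summaries}


def pairwise_compare(scores: PairedScores, alpha: float = 0.05) -> ComparisonReport:
    """Wilcoxon test on every condition pair plus boxplot-style summaries."""
    k = scores.scores.shape[1]
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, pij = wilcoxon_signed_rank(scores.scores[:, i], scores.scores[:, j])
            p[i, j] = p[j, i] = pij
    sig = (p < alpha) & ~np.eye(k, dtype=bool)
    summaries = [_boxplot_summary(scores.scores[:, i]) for i in range(k)]
    return ComparisonReport(condition_labels=list(scores.condition_labels),
                            p_values=p, significant=sig,
                            summaries=summaries, alpha=alpha)
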