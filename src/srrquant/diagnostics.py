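"""Diagnostic evaluation of the SRR: ROC analysis, cutoff metrics, paired tests.

Orientation is fixed throughout: a *lower* SRR indicates disease (striatal
dopamine-transporter loss), so a subject is called diseased when
``SRR <= cutoff``.  The AUC is computed as the tie-adjusted Mann-Whitney
probability P(control > diseased) + P(tie)/2, and the optimal cutoff
maximizes the Youden index J = sensitivity + specificity − 1 (ties broken
toward the higher cutoff, favouring sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "roc_analysis",
    "classify_at_cutoff",
    "mcnemar_test",
    "two_sample_t",
    "mann_whitney_auc",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray          # sorted unique candidate cutoffs
    sensitivity: np.ndarray         # P(SRR <= thr | diseased)
    specificity: np.ndarray         # P(SRR >  thr | control)
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    accuracy_at_cutoff: float
    orientation: str = "lower_is_diseased"


def mann_whitney_auc(diseased: np.ndarray, control: np.ndarray) -> float:
    """Tie-adjusted AUC: P(control > diseased) + P(control == diseased)/2."""
    pooled = np.concatenate([diseased, control])
    ranks = stats.rankdata(pooled)                      # average ranks handle ties
    r_control = ranks[len(diseased):].sum()
    n_c, n_d = len(control), len(diseased)
    return float((r_control - n_c * (n_c + 1) / 2) / (n_c * n_d))


def roc_analysis(diseased_scores, control_scores,
                 criterion: str = "youden") -> ROCResult:
    """ROC analysis of a lower-is-diseased score.

    ``criterion`` selects the optimal cutoff: ``"youden"`` (default)
    maximizes sensitivity + specificity − 1, ``"accuracy"`` maximizes overall
    accuracy at the input prevalence.
    """
    d = np.asarray(diseased_scores, dtype=float)
    c = np.asarray(control_scores, dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("both score lists must be non-empty")
    if criterion not in ("youden", "accuracy"):
        raise ValueError(f"unknown cutoff criterion {criterion!r}")

    pooled = np.concatenate([d, c])
    constant = np.ptp(pooled) == 0
    auc = 0.5 if constant else mann_whitney_auc(d, c)

    thresholds = np.unique(pooled)
    sens = np.array([(d <= t).mean() for t in thresholds])
    spec = np.array([(c > t).mean() for t in thresholds])
    acc = (sens * d.size + spec * c.size) / (d.size + c.size)
    score = sens + spec - 1 if criterion == "youden" else acc
    # ties broken toward the higher cutoff
    best = np.flatnonzero(score == score.max())[-1]
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, optimal_cutoff=float(thresholds[best]),
                     sensitivity_at_cutoff=float(sens[best]),
                     specificity_at_cutoff=float(spec[best]),
                     accuracy_at_cutoff=float(acc[best]))


def classify_at_cutoff(scores, truth, cutoff: float) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy calling diseased when score <= cutoff.

    ``truth`` is 1/True for diseased subjects.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    if y.all() or (~y).all():
        raise ValueError("truth must contain both classes")
    called = s <= cutoff
    sens = float(called[y].mean())
    spec = float((~called)[~y].mean())
    acc = float((called == y).mean())
    return sens, spec, acc


def mcnemar_test(correct_a, correct_b) -> tuple[float, float]:
    """McNemar chi-square with continuity correction for paired classifiers.

    ``correct_a[i]`` / ``correct_b[i]`` flag whether each method classified
    subject ``i`` correctly.  chi2 = (max(0, |b−c| − 1))² / (b + c) on the
    discordant counts, with chi2 = 0 and p = 1 when there is no discordance.
    """
    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    n_ab = int(np.sum(a & ~b))     # A correct, B wrong
    n_ba = int(np.sum(~a & b))     # B correct, A wrong
    disc = n_ab + n_ba
    if disc == 0:
        return 0.0, 1.0
    chi2 = max(0.0, abs(n_ab - n_ba) - 1) ** 2 / disc
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> tuple[float, float, float]:
    """Welch's two-sample t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ValueError("zero pooled variance: t undefined for equal means")
        return float("inf"), float(n1 + n2 - 2), 0.0
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)
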