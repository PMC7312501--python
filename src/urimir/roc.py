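"""Per-marker ROC analysis and Youden-index cutoff selection.

A marker's discriminative ability is summarized by the empirical ROC curve
and its trapezoidal AUC, which equals the Mann-Whitney U statistic divided
by n1*n2 (ties counted 1/2).  The operating cutoff maximizes the Youden
index J = sensitivity + specificity - 1 over candidate thresholds placed
at midpoints between consecutive sorted distinct values (plus the two
degenerate all-positive / all-negative thresholds).

Markers carry a fixed regulation direction: for an up-regulated marker a
sample is test-positive when its value is >= the threshold; for a
down-regulated marker when it is <= the threshold.  Directions are
pre-assigned from the known regulation of each marker in disease rather
than auto-oriented, which prevents sign flips on noisy resamples
(auto-orientation is available via ``infer_direction``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .qpcr import GROUP_CASE

__all__ = ["RocResult", "MarkerCutoff", "roc", "youden_cutoff",
           "infer_direction", "PAPER_DIRECTIONS"]

#: regulation in disease for the markers with diagnostic signal; used to
#: orient ROC analyses when no explicit direction is supplied
PAPER_DIRECTIONS: dict[str, str] = {
    "hsa-miR-21": "up",
    "hsa-miR-96": "up",
    "hsa-miR-125b": "down",
    "hsa-miR-126": "up",
    "hsa-miR-145": "down",
    "hsa-miR-183": "up",
    "hsa-miR-205": "down",
    "hsa-miR-210": "down",
    "hsa-miR-221": "down",
}


@dataclass
class RocResult:
    miRNA: str
    auc: float
    p_raw: float
    p_adjusted: float
    points: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    direction: str


@dataclass
class MarkerCutoff:
    """Decision rule for one marker: threshold, orientation and Youden J."""

    miRNA: str
    cutoff: float
    direction: str
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def _validate(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    case = labels == GROUP_CASE
    if case.all() or not case.any():
        raise ValueError("need at least one case and one control")
    return values, case


def _oriented(values: np.ndarray, direction: str) -> np.ndarray:
    if direction == "up":
        return values
    if direction == "down":
        return -values
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def roc(values, labels, direction: str, miRNA: str = "",
        n_tests: int = 9) -> RocResult:
    """Empirical ROC curve, trapezoidal AUC, and AUC != 0.5 significance.

    The p-value tests the null AUC = 0.5 through the tie-corrected normal
    approximation of the Mann-Whitney U statistic (two-sided); the adjusted
    p-value applies the Bonferroni factor for the marker family.
    """
    from .stats import bonferroni  # local import avoids a cycle

    values, case = _validate(values, labels)
    score = _oriented(values, direction)
    pos, neg = score[case], score[~case]
    n1, n2 = pos.size, neg.size

    # sweep thresholds from +inf downward over distinct scores
    thresholds = np.unique(score)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    points = np.column_stack([fpr, tpr])

    # AUC via average ranks == trapezoidal area under the empirical curve
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n2)

    res = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    p_raw = float(min(res.pvalue, 1.0))
    return RocResult(miRNA, auc, p_raw, bonferroni(p_raw, n_tests),
                     points, direction)


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def youden_cutoff(values, labels, direction: str,
                  miRNA: str = "") -> MarkerCutoff:
    """Cutoff maximizing J = sens + spec - 1 over midpoint thresholds.

    Ties in J are broken toward higher specificity, then toward the
    threshold farther from the data median (a more extreme, hence more
    conservative, operating point), then toward the larger threshold.
    Because the candidate set contains both degenerate thresholds, the
    maximal J is never negative.
    """
    values, case = _validate(values, labels)
    pos, neg = values[case], values[~case]
    median = float(np.median(values))

    best: tuple[float, float, float, float] | None = None
    best_rule: MarkerCutoff | None = None
    for t in _candidate_cutoffs(values):
        if direction == "up":
            sens = float(np.mean(pos >= t))
            spec = float(np.mean(neg < t))
        else:
            sens = float(np.mean(pos <= t))
            spec = float(np.mean(neg > t))
        j = sens + spec - 1.0
        dist = abs(t - median) if np.isfinite(t) else np.inf
        key = (j, spec, dist, t)
        if best is None or key > best:
            best = key
            best_rule = MarkerCutoff(miRNA, float(t), direction, j, sens, spec)
    assert best_rule is not None
    return best_rule


def infer_direction(values, labels) -> str:
    """Auto-orientation: the direction giving AUC >= 0.5 on this data."""
    values, case = _validate(values, labels)
    ranks = sps.rankdata(values)
    n1, n2 = int(case.sum()), int((~case).sum())
    u_up = float(ranks[case].sum() - n1 * (n1 + 1) / 2)
    return "up" if u_up / (n1 * n2) >= 0.5 else "down"
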