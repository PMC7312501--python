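"""Univariate group comparisons and rank correlations.

Case-vs-control differences per miRNA are tested with the two-tailed
Mann-Whitney U test and Bonferroni-adjusted for the nine markers by
multiplying raw p-values by 9 (capped at 1).  Associations among markers
and with ordinal clinical covariates use Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qpcr import (GRADES_1973, GRADES_2004, GROUP_CASE, STAGES,
                   SampleRecord)

__all__ = [
    "GroupComparison", "CorrelationResult", "mann_whitney", "bonferroni",
    "spearman", "group_comparisons", "marker_correlations",
    "stage_grade_correlations",
]

#: number of primary hypotheses (one per assayed miRNA)
N_MARKERS = 9

ALPHA = 0.05

# ordinal codings for the clinical covariates
STAGE_CODE = {s: i + 1 for i, s in enumerate(STAGES)}          # pTa=1 .. >=pT2=4
GRADE73_CODE = {g: i + 1 for i, g in enumerate(GRADES_1973)}   # G1<G2<G3
GRADE04_CODE = {g: i + 1 for i, g in enumerate(GRADES_2004)}   # low<high


@dataclass
class GroupComparison:
    miRNA: str
    u_statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # up | down | not_different


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    p: float


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 continuity: bool = False) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses the exact null distribution when ``len(x) * len(y) <= 400`` and
    there are no ties, otherwise the tie-corrected normal approximation
    (without continuity correction unless requested).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=continuity)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_raw: float, m: int = N_MARKERS) -> float:
    """Bonferroni adjustment: min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    return min(1.0, m * p_raw)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Raises ``ValueError`` for constant input, where the coefficient is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_comparisons(expr: pd.DataFrame, records: Sequence[SampleRecord],
                      alpha: float = ALPHA) -> list[GroupComparison]:
    """Mann-Whitney comparison of every miRNA between BCa and controls.

    ``direction`` reports the regulation in disease (by mean rank of the
    case group) whenever the Bonferroni-adjusted p-value is below
    ``alpha``, else ``not_different``.
    """
    groups = {r.sample_id: r.group for r in records}
    labels = expr.index.map(groups)
    case_mask = np.asarray(labels == GROUP_CASE)
    if case_mask.all() or not case_mask.any():
        raise ValueError("need both BCa and control samples")
    out = []
    for mirna in expr.columns:
        values = expr[mirna].to_numpy(dtype=float)
        u, p = mann_whitney(values[case_mask], values[~case_mask])
        p_adj = bonferroni(p)
        if p_adj >= alpha:
            direction = "not_different"
        else:
            # U > n1*n2/2 means cases rank higher than controls
            n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
            direction = "up" if u > n1 * n2 / 2 else "down"
        out.append(GroupComparison(mirna, u, p, p_adj, direction))
    return out


def marker_correlations(expr: pd.DataFrame) -> list[CorrelationResult]:
    """Pairwise Spearman correlations among the marker expression levels."""
    out = []
    for a, b in combinations(expr.columns, 2):
        r, p = spearman(expr[a].to_numpy(), expr[b].to_numpy())
        out.append(CorrelationResult((a, b), r, p))
    return out


def stage_grade_correlations(expr: pd.DataFrame,
                             records: Sequence[SampleRecord],
                             ) -> list[CorrelationResult]:
    """Spearman correlation of each miRNA with stage and grade (tumors only).

    Stage is coded pTa=1 < pT1=2 < pTis=3 < >=pT2=4 (concomitant carcinoma
    in situ counted as the most severe non-muscle-invasive stage), WHO-1973
    grade G1<G2<G3, WHO-2004 low<high.
    """
    cases = {r.sample_id: r for r in records if r.group == GROUP_CASE}
    ids = [sid for sid in expr.index if sid in cases]
    if len(ids) < 3:
        raise ValueError("need at least 3 graded tumor samples")
    covariates = {
        "stage": [STAGE_CODE[cases[sid].stage] for sid in ids],
        "grade_1973": [GRADE73_CODE[cases[sid].grade73] for sid in ids],
        "grade_2004": [GRADE04_CODE[cases[sid].grade04] for sid in ids],
    }
    sub = expr.loc[ids]
    out = []
    for mirna in expr.columns:
        values = sub[mirna].to_numpy(dtype=float)
        for cov_name, codes in covariates.items():
            r, p = spearman(values, np.asarray(codes, dtype=float))
            out.append(CorrelationResult((mirna, cov_name), r, p))
    return out


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabular view of the group comparisons (one row per miRNA)."""
    return pd.DataFrame([{
        "miRNA": c.miRNA,
        "direction": c.direction,
        "U": c.u_statistic,
        "p_raw": c.p_raw,
        "p_adjusted": c.p_adjusted,
    } for c in comparisons])


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "var1": r.pair[0], "var2": r.pair[1], "r_s": r.r_s, "p": r.p,
    } for r in results])
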