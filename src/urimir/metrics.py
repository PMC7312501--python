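"""Confusion matrices and diagnostic performance measures.

Seven standard measures are derived from the 2x2 table: sensitivity (SNS),
specificity (SPC), positive/negative predictive value (PPV/NPV),
positive/negative likelihood ratio (pLR/nLR) and accuracy (ACC).  A zero
denominator (e.g. pLR at specificity 1) yields the distinguished
not-determinable marker ``None``, rendered as ``n.d.`` in reports — never
infinity and never an exception.  Values are kept at full precision
internally and rounded to three decimals only at report time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .qpcr import GROUP_CASE

__all__ = ["ConfusionMatrix", "DiagnosticMetrics", "confusion", "metrics",
           "counts_from_rates", "metrics_table", "ND_LABEL"]

ND_LABEL = "n.d."

METRIC_ORDER = ("sns", "spc", "ppv", "npv", "plr", "nlr", "acc")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The seven measures; ``None`` marks a not-determinable value."""

    sns: float | None
    spc: float | None
    ppv: float | None
    npv: float | None
    plr: float | None
    nlr: float | None
    acc: float | None

    def rounded(self, ndigits: int = 3) -> dict[str, float | str]:
        """Report-time view: 3-decimal rounding, ``n.d.`` for undefined."""
        return {k: (ND_LABEL if v is None else round(v, ndigits))
                for k, v in self.as_dict().items()}

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in METRIC_ORDER}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def confusion(calls: Mapping[str, str], truth: Mapping[str, str]
              ) -> ConfusionMatrix:
    """2x2 tally of per-sample calls against group labels (BCa = positive).

    ``calls`` maps sample id to ``positive``/``negative``; ``truth`` maps
    the same ids to ``BCa``/``control``.
    """
    if set(calls) != set(truth):
        raise ValueError("calls and truth must cover the same sample ids")
    tp = fp = tn = fn = 0
    for sid, call in calls.items():
        positive = call == "positive"
        diseased = truth[sid] == GROUP_CASE
        if diseased:
            tp, fn = tp + positive, fn + (not positive)
        else:
            fp, tn = fp + positive, tn + (not positive)
    return ConfusionMatrix(tp, fp, tn, fn)


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Derive the seven performance measures from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sns = _ratio(cm.tp, cm.tp + cm.fn)
    spc = _ratio(cm.tn, cm.tn + cm.fp)
    plr = None if sns is None or spc is None else _ratio(sns, 1.0 - spc)
    nlr = None if sns is None or spc is None else _ratio(1.0 - sns, spc)
    return DiagnosticMetrics(
        sns=sns,
        spc=spc,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        plr=plr,
        nlr=nlr,
        acc=(cm.tp + cm.tn) / cm.total,
    )


def counts_from_rates(sns: float, spc: float, n_cases: int, n_controls: int
                      ) -> ConfusionMatrix:
    """Reconstruct the 2x2 table behind reported sensitivity/specificity.

    Rounds sns*n_cases and spc*n_controls to the nearest count and warns
    when the round trip moves either rate by more than half a count.
    """
    if not (0.0 <= sns <= 1.0 and 0.0 <= spc <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp = round(sns * n_cases)
    tn = round(spc * n_controls)
    cm = ConfusionMatrix(tp, n_controls - tn, tn, n_cases - tp)
    back = metrics(cm)
    if (abs(back.sns - sns) > 0.5 / max(n_cases, 1)
            or abs(back.spc - spc) > 0.5 / max(n_controls, 1)):
        warnings.warn(
            f"rates ({sns}, {spc}) are not consistent with cohort sizes "
            f"({n_cases}, {n_controls})", stacklevel=2)
    return cm


def metrics_table(columns: Mapping[str, DiagnosticMetrics],
                  ndigits: int = 3) -> pd.DataFrame:
    """Report table: one column per marker/panel, one row per measure.

    Mirrors the layout of a diagnostic-performance summary, with undefined
    entries shown as ``n.d.``.
    """
    data = {name: dm.rounded(ndigits) for name, dm in columns.items()}
    frame = pd.DataFrame(data)
    return frame.reindex([m for m in METRIC_ORDER])


def metrics_report(columns: Mapping[str, DiagnosticMetrics]) -> dict:
    """Full-precision JSON-ready report (undefined values as ``"n.d."``)."""
    return {name: {k: (ND_LABEL if v is None else v)
                   for k, v in dm.as_dict().items()}
            for name, dm in columns.items()}
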