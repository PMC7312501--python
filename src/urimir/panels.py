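"""Marker binarization and k-of-m panel combination rules.

Each marker is dichotomized at its Youden-optimal cutoff into a tumor
indicator (1 = suggestive of disease, 0 = not), with the boundary value
counted toward the diseased side.  A panel rule calls a sample positive
when at least ``min_positive`` of its indicators are 1; voided urine
cytology (VUC) can be appended as one additional binary indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .qpcr import MIRNAS, ExpressionProfile
from .roc import MarkerCutoff

__all__ = ["PanelRule", "PanelCall", "binarize", "apply_panel",
           "paper_panels", "PANEL_6MIR", "PANEL_4MIR"]

#: the six markers with group-level diagnostic signal
PANEL_6MIR = ("hsa-miR-96", "hsa-miR-125b", "hsa-miR-126",
              "hsa-miR-145", "hsa-miR-183", "hsa-miR-221")
#: the four markers with the highest single-marker AUCs
PANEL_4MIR = ("hsa-miR-125b", "hsa-miR-145", "hsa-miR-183", "hsa-miR-221")


@dataclass
class PanelRule:
    name: str
    markers: tuple[str, ...]
    min_positive: int
    include_vuc: bool = False

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        unknown = [m for m in self.markers if m not in MIRNAS]
        if unknown:
            raise ValueError(f"unknown markers in panel: {unknown}")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in panel")
        n_indicators = len(self.markers) + (1 if self.include_vuc else 0)
        if not 1 <= self.min_positive <= n_indicators:
            raise ValueError(
                f"min_positive must lie in [1, {n_indicators}]")


@dataclass
class PanelCall:
    sample_id: str
    indicators: dict[str, int]
    vuc_indicator: int | None  # None when VUC is not counted
    positive_count: int
    call: str  # positive | negative


def binarize(value: float, cutoff: MarkerCutoff) -> int:
    """Tumor indicator for one marker value at its cutoff.

    Up-regulated marker: 1 iff value >= cutoff; down-regulated: 1 iff
    value <= cutoff.  A value exactly at the cutoff counts as positive.
    """
    if cutoff.direction == "up":
        return int(value >= cutoff.cutoff)
    if cutoff.direction == "down":
        return int(value <= cutoff.cutoff)
    raise ValueError(f"cutoff has no valid direction: {cutoff.direction!r}")


def apply_panel(profile: ExpressionProfile | Mapping[str, float],
                vuc: str,
                cutoffs: Mapping[str, MarkerCutoff],
                rule: PanelRule) -> PanelCall:
    """Evaluate one sample against a panel rule.

    ``vuc`` is the cytology result (``positive``/``negative``); it enters
    the positive count only when the rule includes VUC.
    """
    if isinstance(profile, ExpressionProfile):
        sample_id, rel = profile.sample_id, profile.rel_expr
    else:
        sample_id, rel = "", profile
    indicators: dict[str, int] = {}
    for marker in rule.markers:
        if marker not in rel:
            raise KeyError(f"profile lacks marker {marker}")
        if marker not in cutoffs:
            raise KeyError(f"no cutoff supplied for marker {marker}")
        indicators[marker] = binarize(rel[marker], cutoffs[marker])

    vuc_indicator: int | None = None
    total = sum(indicators.values())
    if rule.include_vuc:
        vuc_indicator = int(vuc == "positive")
        total += vuc_indicator
    return PanelCall(sample_id, indicators, vuc_indicator, total,
                     "positive" if total >= rule.min_positive else "negative")


def paper_panels() -> list[PanelRule]:
    """The four shipped combination rules.

    6-marker panel calling on >=4 positives, 4-marker panel on >=3, and
    both with VUC appended as one further indicator at the same minimum
    count (>=4 of 7, >=3 of 5).
    """
    return [
        PanelRule("6mir", PANEL_6MIR, min_positive=4),
        PanelRule("4mir", PANEL_4MIR, min_positive=3),
        PanelRule("6mir_vuc", PANEL_6MIR, min_positive=4, include_vuc=True),
        PanelRule("4mir_vuc", PANEL_4MIR, min_positive=3, include_vuc=True),
    ]


def calls_frame(calls: Sequence[PanelCall], rule: PanelRule) -> pd.DataFrame:
    """Per-sample call table: indicators, VUC, positive count, final call."""
    rows = []
    for c in calls:
        row: dict[str, object] = {"sample_id": c.sample_id}
        row.update(c.indicators)
        if rule.include_vuc:
            row["vuc"] = c.vuc_indicator
        row["positive_count"] = c.positive_count
        row["call"] = c.call
        rows.append(row)
    return pd.DataFrame(rows)
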