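"""End-to-end driver: simulate -> normalize -> stats -> ROC -> panels -> metrics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import panels as panels_mod
from . import roc as roc_mod
from . import stats as stats_mod
from .metrics import ConfusionMatrix, DiagnosticMetrics, confusion, metrics
from .panels import PanelCall, PanelRule, apply_panel, paper_panels
from .qpcr import MIRNAS, ExpressionProfile, SampleRecord, normalize_cohort
from .roc import PAPER_DIRECTIONS, MarkerCutoff, RocResult, youden_cutoff
from .stats import CorrelationResult, GroupComparison
from .synthetic import CohortSpec, generate_cohort

__all__ = ["PipelineResult", "run_pipeline", "analyze_cohort"]


@dataclass
class PipelineResult:
    records: list[SampleRecord]
    expression: pd.DataFrame
    profiles: list[ExpressionProfile]
    comparisons: list[GroupComparison]
    marker_correlations: list[CorrelationResult]
    stage_grade_correlations: list[CorrelationResult]
    roc_results: dict[str, RocResult]
    cutoffs: dict[str, MarkerCutoff]
    panel_calls: dict[str, list[PanelCall]]
    confusions: dict[str, ConfusionMatrix]
    metrics: dict[str, DiagnosticMetrics]


def analyze_cohort(records: list[SampleRecord],
                   calibrator_delta: float = 0.0,
                   directions: dict[str, str] | None = None,
                   rules: list[PanelRule] | None = None) -> PipelineResult:
    """Run the full analysis on an existing cohort of Ct records.

    ``directions`` overrides the fixed marker orientations; ``rules``
    overrides the shipped panel definitions.  Cutoffs are fit on the full
    cohort (resubstitution), so the resulting performance estimates are
    optimistic by construction.
    """
    directions = directions or PAPER_DIRECTIONS
    rules = rules if rules is not None else paper_panels()

    expr, profiles = normalize_cohort(records, calibrator_delta)
    by_id = {r.sample_id: r for r in records}
    usable = [by_id[sid] for sid in expr.index]
    truth = {r.sample_id: r.group for r in usable}
    labels = expr.index.map(truth).to_numpy()

    comparisons = stats_mod.group_comparisons(expr, usable)
    marker_corr = stats_mod.marker_correlations(expr)
    stage_corr = stats_mod.stage_grade_correlations(expr, usable)

    roc_results: dict[str, RocResult] = {}
    cutoffs: dict[str, MarkerCutoff] = {}
    for mirna in MIRNAS:
        values = expr[mirna].to_numpy()
        d = directions[mirna]
        roc_results[mirna] = roc_mod.roc(values, labels, d, miRNA=mirna)
        cutoffs[mirna] = youden_cutoff(values, labels, d, miRNA=mirna)

    confusions: dict[str, ConfusionMatrix] = {}
    all_metrics: dict[str, DiagnosticMetrics] = {}

    # single markers at their Youden cutoffs
    for mirna in MIRNAS:
        calls = {
            sid: ("positive"
                  if panels_mod.binarize(expr.at[sid, mirna], cutoffs[mirna])
                  else "negative")
            for sid in expr.index}
        confusions[mirna] = confusion(calls, truth)
        all_metrics[mirna] = metrics(confusions[mirna])

    # cytology alone
    vuc_calls = {r.sample_id: r.vuc for r in usable}
    confusions["VUC"] = confusion(vuc_calls, truth)
    all_metrics["VUC"] = metrics(confusions["VUC"])

    # combination rules
    panel_calls: dict[str, list[PanelCall]] = {}
    for rule in rules:
        calls_list = [apply_panel(
            {m: float(expr.at[r.sample_id, m]) for m in rule.markers},
            r.vuc, cutoffs, rule) for r in usable]
        for call, r in zip(calls_list, usable):
            call.sample_id = r.sample_id
        panel_calls[rule.name] = calls_list
        call_map = {c.sample_id: c.call for c in calls_list}
        confusions[rule.name] = confusion(call_map, truth)
        all_metrics[rule.name] = metrics(confusions[rule.name])

    return PipelineResult(
        records=records,
        expression=expr,
        profiles=profiles,
        comparisons=comparisons,
        marker_correlations=marker_corr,
        stage_grade_correlations=stage_corr,
        roc_results=roc_results,
        cutoffs=cutoffs,
        panel_calls=panel_calls,
        confusions=confusions,
        metrics=all_metrics,
    )


def run_pipeline(spec: CohortSpec, calibrator_delta: float = 0.0,
                 **kwargs) -> PipelineResult:
    """Generate a synthetic cohort from ``spec`` and analyze it."""
    return analyze_cohort(generate_cohort(spec), calibrator_delta, **kwargs)
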