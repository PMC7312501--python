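"""Synthetic qPCR cohort generator.

Emulates a case/control study of urinary miRNA markers measured by qPCR in
urine sediments: 104 bladder-cancer (BCa) patients and 46 controls, nine
target miRNAs plus the two reference RNAs RNU44/RNU48, duplicate reactions
per assay, voided urine cytology (VUC) as a binary comparator, and the
clinical strata (tumor stage, WHO 1973/2004 grade, focality).

Generative model
----------------
Threshold cycles are drawn from a Gaussian copula on the Ct scale: a
latent multivariate normal with the configured inter-marker correlation
matrix, scaled by marker-specific standard deviations around a control
mean.  Disease shifts the mean Ct of each marker by ``ct_shift_case``
(negative = fewer cycles = up-regulated in BCa), optionally plus a linear
trend over tumor-stage steps (pTa < pT1 < pTis < >=pT2).  Duplicate
reactions add independent replicate noise; non-detection is an independent
Bernoulli mask per assay that propagates to relative expression 0.  VUC is
drawn per group from a (sensitivity, specificity) operating point,
independent of the marker values.

The Ct scale is convenient because every downstream statistic is
rank-based: 2^-ddCt is a strictly decreasing transform of Ct, so the
copula's rank structure carries through normalization unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .qpcr import (FOCALITY, GRADES_1973, GRADES_2004, GROUP_CASE,
                   GROUP_CONTROL, MIRNAS, REFERENCES, STAGES, SampleRecord)

__all__ = [
    "MarkerSpec", "CohortSpec", "generate_cohort", "default_paper_spec",
    "null_spec", "expected_auc", "spec_to_yaml", "spec_from_yaml",
]


@dataclass
class MarkerSpec:
    """Generative parameters for one miRNA assay (all Ct units in cycles)."""

    name: str
    ct_mean_control: float
    ct_shift_case: float = 0.0     # negative = up-regulated in BCa
    ct_sd: float = 1.0
    nondetect_prob_control: float = 0.0
    nondetect_prob_case: float = 0.0
    stage_trend: float = 0.0       # cycles per stage step, 0 if none
    replicate_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.ct_sd <= 0:
            raise ValueError(f"{self.name}: ct_sd must be > 0")
        if self.replicate_sd < 0:
            raise ValueError(f"{self.name}: replicate_sd must be >= 0")
        for p in (self.nondetect_prob_control, self.nondetect_prob_case):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: non-detection probability "
                                 f"{p} outside [0, 1]")

    @property
    def direction(self) -> str:
        """Regulation direction in disease implied by the Ct shift."""
        return "down" if self.ct_shift_case > 0 else "up"


def _check_probs(name: str, p: Sequence[float], k: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (k,):
        raise ValueError(f"{name}: expected {k} probabilities, got {arr.shape}")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must be >= 0 and sum to 1")
    return arr


@dataclass
class CohortSpec:
    """Full description of a synthetic case/control cohort."""

    n_cases: int
    n_controls: int
    markers: list[MarkerSpec]
    correlation: np.ndarray                      # latent scale, markers x markers
    stage_distribution: Sequence[float]          # pTa, pT1, pTis, >=pT2
    grade73_distribution: Sequence[float]        # G1, G2, G3
    grade04_distribution: Sequence[float]        # low, high
    vuc_sensitivity: float
    vuc_specificity: float
    seed: int = 0
    multifocal_prob: float = 0.308
    ref_ct_means: tuple[float, float] = (24.5, 25.5)  # RNU44, RNU48
    ref_ct_sd: float = 0.15
    ref_replicate_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        self.correlation = np.asarray(self.correlation, dtype=float)
        m = len(self.markers)
        if self.correlation.shape != (m, m):
            raise ValueError("correlation matrix shape does not match the "
                             "number of markers")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.correlation)
        if eigvals.min() < -1e-9:
            raise ValueError(
                "correlation matrix is not positive semidefinite: smallest "
                f"eigenvalue {eigvals.min():.3e}")
        _check_probs("stage_distribution", self.stage_distribution, 4)
        _check_probs("grade73_distribution", self.grade73_distribution, 3)
        _check_probs("grade04_distribution", self.grade04_distribution, 2)
        for label, v in (("vuc_sensitivity", self.vuc_sensitivity),
                         ("vuc_specificity", self.vuc_specificity),
                         ("multifocal_prob", self.multifocal_prob)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")

    def marker(self, name: str) -> MarkerSpec:
        for mk in self.markers:
            if mk.name == name:
                return mk
        raise KeyError(name)


def _copula_factor(correlation: np.ndarray) -> np.ndarray:
    # eigen factorization tolerates an exactly singular (PSD) matrix
    eigvals, eigvecs = np.linalg.eigh(correlation)
    return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def generate_cohort(spec: CohortSpec) -> list[SampleRecord]:
    """Draw a full cohort of :class:`SampleRecord` from ``spec``.

    Cases come first (``BCa-001`` ...), then controls (``CTRL-001`` ...).
    Reproducible: a fixed seed yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n0 = spec.n_cases, spec.n_controls
    n = n1 + n0
    m = len(spec.markers)
    is_case = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])

    # clinical strata (cases only); draw order is fixed for determinism
    stage_idx = rng.choice(4, size=n1, p=np.asarray(spec.stage_distribution))
    grade73_idx = rng.choice(3, size=n1,
                             p=np.asarray(spec.grade73_distribution))
    grade04_idx = rng.choice(2, size=n1,
                             p=np.asarray(spec.grade04_distribution))
    multifocal = rng.random(n1) < spec.multifocal_prob

    # latent copula draw on the Ct scale
    factor = _copula_factor(spec.correlation)
    z = rng.standard_normal((n, m)) @ factor.T

    means = np.empty((n, m))
    sds = np.array([mk.ct_sd for mk in spec.markers])
    for j, mk in enumerate(spec.markers):
        mu = np.full(n, mk.ct_mean_control)
        mu[:n1] += mk.ct_shift_case + mk.stage_trend * stage_idx
        means[:, j] = mu
    ct_true = means + sds * z

    reps = ct_true[:, :, None] + rng.normal(
        0.0, [mk.replicate_sd for mk in spec.markers],
        size=(n, 2, m)).transpose(0, 2, 1)
    reps = np.clip(reps, 0.01, 45.0)

    nd_prob = np.where(
        is_case[:, None],
        [mk.nondetect_prob_case for mk in spec.markers],
        [mk.nondetect_prob_control for mk in spec.markers])
    nondetect = rng.random((n, m)) < nd_prob

    ref_true = np.asarray(spec.ref_ct_means) + rng.normal(
        0.0, spec.ref_ct_sd, size=(n, 2))
    ref_reps = np.clip(ref_true[:, :, None] + rng.normal(
        0.0, spec.ref_replicate_sd, size=(n, 2, 2)), 0.01, 45.0)

    vuc_prob = np.where(is_case, spec.vuc_sensitivity,
                        1.0 - spec.vuc_specificity)
    vuc_positive = rng.random(n) < vuc_prob

    records: list[SampleRecord] = []
    for i in range(n):
        case = bool(is_case[i])
        sid = f"BCa-{i + 1:03d}" if case else f"CTRL-{i - n1 + 1:03d}"
        ct: dict[str, list[float] | None] = {}
        for j, mk in enumerate(spec.markers):
            ct[mk.name] = (None if nondetect[i, j]
                           else [float(reps[i, j, 0]), float(reps[i, j, 1])])
        for k, ref in enumerate(REFERENCES):
            ct[ref] = [float(ref_reps[i, k, 0]), float(ref_reps[i, k, 1])]
        records.append(SampleRecord(
            sample_id=sid,
            group=GROUP_CASE if case else GROUP_CONTROL,
            stage=STAGES[stage_idx[i]] if case else None,
            grade73=GRADES_1973[grade73_idx[i]] if case else None,
            grade04=GRADES_2004[grade04_idx[i]] if case else None,
            focality=(FOCALITY[1] if multifocal[i] else FOCALITY[0])
            if case else None,
            vuc="positive" if vuc_positive[i] else "negative",
            ct=ct,
        ))
    return records


def expected_auc(spec: CohortSpec, marker_name: str) -> float:
    """Closed-form AUC implied by the generator for one marker.

    For detected pairs the normal-theory AUC is Phi(|shift| / (sqrt(2) *
    sigma)) per stage stratum (sigma includes the small replicate- and
    reference-noise contributions after duplicate averaging), mixed over
    the stage distribution when a stage trend is configured.  Non-detected
    values sit at relative expression 0, the extreme of the down-regulated
    side, and are mixed in exactly.
    """
    mk = spec.marker(marker_name)
    ref_var = sum(spec.ref_ct_sd ** 2 + spec.ref_replicate_sd ** 2 / 2
                  for _ in REFERENCES) / 4.0
    sigma = np.sqrt(mk.ct_sd ** 2 + mk.replicate_sd ** 2 / 2 + ref_var)
    sign = 1.0 if mk.direction == "down" else -1.0
    stage_p = np.asarray(spec.stage_distribution)
    shifts = mk.ct_shift_case + mk.stage_trend * np.arange(4)
    auc_detected = float(
        (stage_p * norm.cdf(sign * shifts / (np.sqrt(2) * sigma))).sum())

    q0, q1 = mk.nondetect_prob_control, mk.nondetect_prob_case
    both = (1 - q0) * (1 - q1)
    if mk.direction == "up":
        # control non-detected ranks below any detected case
        extra = q0 * (1 - q1)
    else:
        # case non-detected (expression 0) is maximally "diseased"
        extra = q1 * (1 - q0)
    return both * auc_detected + extra + 0.5 * q0 * q1


# ---------------------------------------------------------------------------
# Shipped calibration
# ---------------------------------------------------------------------------

# Synthetic calibration constants (invented): per-marker Ct shifts chosen by
# inverting the closed form above so that each marker's population AUC lands
# at the magnitude observed for it in urinary-sediment studies, with unit Ct
# SD.  Control-mean Cts are plausible abundances, not measured values.
_CALIBRATION: list[MarkerSpec] = [
    MarkerSpec("hsa-miR-21", ct_mean_control=25.0, ct_shift_case=-0.292731),
    MarkerSpec("hsa-miR-96", ct_mean_control=33.0, ct_shift_case=-0.068692,
               nondetect_prob_control=0.20, nondetect_prob_case=0.02),
    MarkerSpec("hsa-miR-125b", ct_mean_control=28.0, ct_shift_case=0.383698,
               stage_trend=0.5),
    MarkerSpec("hsa-miR-126", ct_mean_control=27.0, ct_shift_case=-0.618020),
    MarkerSpec("hsa-miR-145", ct_mean_control=29.0, ct_shift_case=0.697800),
    MarkerSpec("hsa-miR-183", ct_mean_control=31.0, ct_shift_case=-0.834502),
    MarkerSpec("hsa-miR-205", ct_mean_control=27.5, ct_shift_case=0.132982),
    MarkerSpec("hsa-miR-210", ct_mean_control=30.0, ct_shift_case=0.093379),
    MarkerSpec("hsa-miR-221", ct_mean_control=28.5, ct_shift_case=1.067321),
]

# Latent inter-marker correlations (synthetic): one positive block over
# miR-21/-125b/-205/-210/-221, a second over miR-96/-126/-183, and negative
# couplings of miR-145 with miR-205/-210; checked positive definite.
_CORR_ENTRIES = {
    ("hsa-miR-21", "hsa-miR-125b"): 0.60,
    ("hsa-miR-21", "hsa-miR-205"): 0.62,
    ("hsa-miR-21", "hsa-miR-210"): 0.58,
    ("hsa-miR-21", "hsa-miR-221"): 0.60,
    ("hsa-miR-125b", "hsa-miR-205"): 0.63,
    ("hsa-miR-125b", "hsa-miR-210"): 0.60,
    ("hsa-miR-125b", "hsa-miR-221"): 0.825,
    ("hsa-miR-205", "hsa-miR-210"): 0.70,
    ("hsa-miR-205", "hsa-miR-221"): 0.60,
    ("hsa-miR-210", "hsa-miR-221"): 0.566,
    ("hsa-miR-96", "hsa-miR-183"): 0.557,
    ("hsa-miR-96", "hsa-miR-126"): 0.311,
    ("hsa-miR-126", "hsa-miR-183"): 0.483,
    ("hsa-miR-145", "hsa-miR-205"): -0.433,
    ("hsa-miR-145", "hsa-miR-210"): -0.483,
    ("hsa-miR-145", "hsa-miR-21"): -0.20,
    ("hsa-miR-145", "hsa-miR-125b"): -0.20,
    ("hsa-miR-145", "hsa-miR-221"): -0.20,
}


def _default_correlation() -> np.ndarray:
    idx = {name: i for i, name in enumerate(MIRNAS)}
    corr = np.eye(len(MIRNAS))
    for (a, b), v in _CORR_ENTRIES.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = v
    return corr


def default_paper_spec(seed: int = 0) -> CohortSpec:
    """The shipped study-like calibration: 104 cases / 46 controls.

    Stage mix 48.1/21.2/14.4/16.3 % over pTa/pT1/pTis/>=pT2, WHO-1973
    grades 13.5/50.0/36.5 %, WHO-2004 16.3 % low- / 83.7 % high-grade,
    30.8 % multifocal, and VUC operating at sensitivity 0.769 with
    specificity 1.000.
    """
    return CohortSpec(
        n_cases=104,
        n_controls=46,
        markers=[replace(mk) for mk in _CALIBRATION],
        correlation=_default_correlation(),
        stage_distribution=(0.481, 0.212, 0.144, 0.163),
        grade73_distribution=(0.135, 0.500, 0.365),
        grade04_distribution=(0.163, 0.837),
        vuc_sensitivity=0.769,
        vuc_specificity=1.000,
        seed=seed,
    )


def null_spec(seed: int = 0) -> CohortSpec:
    """Same cohort layout with every disease effect switched off.

    All Ct shifts, stage trends and non-detection probabilities are zero,
    so marker distributions are identical in cases and controls.
    """
    spec = default_paper_spec(seed=seed)
    spec.markers = [replace(mk, ct_shift_case=0.0, stage_trend=0.0,
                            nondetect_prob_control=0.0,
                            nondetect_prob_case=0.0)
                    for mk in spec.markers]
    return spec


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: CohortSpec, path) -> None:
    doc = {
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "markers": [{
            "name": mk.name,
            "ct_mean_control": mk.ct_mean_control,
            "ct_shift_case": mk.ct_shift_case,
            "ct_sd": mk.ct_sd,
            "nondetect_prob_control": mk.nondetect_prob_control,
            "nondetect_prob_case": mk.nondetect_prob_case,
            "stage_trend": mk.stage_trend,
            "replicate_sd": mk.replicate_sd,
        } for mk in spec.markers],
        "correlation": spec.correlation.tolist(),
        "stage_distribution": list(spec.stage_distribution),
        "grade73_distribution": list(spec.grade73_distribution),
        "grade04_distribution": list(spec.grade04_distribution),
        "vuc_sensitivity": spec.vuc_sensitivity,
        "vuc_specificity": spec.vuc_specificity,
        "seed": spec.seed,
        "multifocal_prob": spec.multifocal_prob,
        "ref_ct_means": list(spec.ref_ct_means),
        "ref_ct_sd": spec.ref_ct_sd,
        "ref_replicate_sd": spec.ref_replicate_sd,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    markers = [MarkerSpec(**mk) for mk in doc.pop("markers")]
    doc["ref_ct_means"] = tuple(doc.get("ref_ct_means", (24.5, 25.5)))
    return CohortSpec(markers=markers,
                      correlation=np.asarray(doc.pop("correlation")), **doc)
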