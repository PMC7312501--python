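"""Technical-replicate QC and delta-delta-Ct relative quantification.

qPCR threshold cycles (Ct) are averaged over technical replicates, checked
against a replicate-deviation tolerance, and converted to relative
expression on the 2^-ddCt scale, normalized to the geometric mean of the
two endogenous reference transcripts RNU44 and RNU48.

Conventions
-----------
* A non-detected assay (no amplification within the run) carries the value
  ``None`` in :class:`SampleRecord` and the literal token ``ND`` in the CSV
  dialect; a non-detected *target* maps to relative expression 0.
* A non-detected *reference* makes the whole sample non-quantifiable: the
  sample is flagged ``reference_missing`` and excluded downstream.
* The calibrator offset of the second "delta" defaults to 0 (expression
  relative to the references only).  Every downstream statistic used here
  is rank-based and therefore invariant to this choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# The nine target miRNAs and two small-nucleolar reference RNAs, by the
# canonical assay names used throughout the package and in the CSV dialect.
MIRNAS: tuple[str, ...] = (
    "hsa-miR-21",
    "hsa-miR-96",
    "hsa-miR-125b",
    "hsa-miR-126",
    "hsa-miR-145",
    "hsa-miR-183",
    "hsa-miR-205",
    "hsa-miR-210",
    "hsa-miR-221",
)
REFERENCES: tuple[str, str] = ("RNU44", "RNU48")
ASSAYS: tuple[str, ...] = MIRNAS + REFERENCES

STAGES: tuple[str, ...] = ("pTa", "pT1", "pTis", "≥pT2")
GRADES_1973: tuple[str, ...] = ("G1", "G2", "G3")
GRADES_2004: tuple[str, ...] = ("low", "high")
FOCALITY: tuple[str, ...] = ("unifocal", "multifocal")

GROUP_CASE = "BCa"
GROUP_CONTROL = "control"

ND_TOKEN = "ND"
NONE_TOKEN = "none"

#: maximum tolerated mean absolute deviation of replicate Ct values (cycles)
REPLICATE_TOLERANCE = 0.25

#: maximum plausible threshold cycle for a 45-cycle run
CT_MAX = 45.0

FLAG_REPLICATE_DEVIATION = "replicate_deviation"
FLAG_REFERENCE_MISSING = "reference_missing"


@dataclass
class SampleRecord:
    """One subject: clinical metadata plus raw replicate Ct values per assay.

    ``ct`` maps assay name to a list of replicate Ct values in cycles, or
    ``None`` for a non-detected assay.  Controls carry no stage/grade/
    focality (``None``).
    """

    sample_id: str
    group: str
    stage: str | None
    grade73: str | None
    grade04: str | None
    focality: str | None
    vuc: str
    ct: dict[str, list[float] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CASE, GROUP_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == GROUP_CONTROL:
            if not (self.stage is None and self.grade73 is None
                    and self.grade04 is None and self.focality is None):
                raise ValueError(
                    f"control sample {self.sample_id} must not carry "
                    "stage/grade/focality annotations")
        for assay, reps in self.ct.items():
            if reps is None:
                continue
            if len(reps) < 1:
                raise ValueError(
                    f"sample {self.sample_id}, assay {assay}: empty "
                    "replicate list (use None for non-detection)")
            for v in reps:
                if not (0.0 < v <= CT_MAX):
                    raise ValueError(
                        f"sample {self.sample_id}, assay {assay}: Ct {v} "
                        f"outside (0, {CT_MAX}]")

    @property
    def is_case(self) -> bool:
        return self.group == GROUP_CASE


@dataclass
class ExpressionProfile:
    """Per-sample normalized relative expression (2^-ddCt units)."""

    sample_id: str
    rel_expr: dict[str, float]
    qc_flags: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return FLAG_REFERENCE_MISSING not in self.qc_flags


def average_replicates(replicates: Sequence[float]) -> tuple[float, bool]:
    """Average technical replicate Ct values; flag excessive scatter.

    Returns the arithmetic mean and a flag that is set when the mean
    absolute deviation from the mean exceeds 0.25 cycles — the point at
    which the measurement would be repeated on the instrument.

    Raises ``ValueError`` on an empty list (a missing assay must be encoded
    as non-detected, not as zero replicates).
    """
    if len(replicates) == 0:
        raise ValueError("no replicate Ct values: assay missing")
    mean = float(np.mean(replicates))
    mad = float(np.mean(np.abs(np.asarray(replicates, dtype=float) - mean)))
    return mean, mad > REPLICATE_TOLERANCE


def reference_geomean(ct_rnu44: float | None, ct_rnu48: float | None) -> float:
    """Geometric mean of the two reference-RNA Ct values, in cycles.

    Raises ``ValueError`` when either reference is non-detected; callers
    translate this into the ``reference_missing`` sample flag.
    """
    if ct_rnu44 is None or ct_rnu48 is None or \
            not (math.isfinite(ct_rnu44) and math.isfinite(ct_rnu48)):
        raise ValueError("reference RNA not detected: sample not quantifiable")
    return math.sqrt(ct_rnu44 * ct_rnu48)


def relative_expression(ct_target: float | None, ct_ref: float,
                        calibrator_delta: float = 0.0) -> float:
    """Relative expression 2^-((ct_target - ct_ref) - calibrator_delta).

    A non-detected target (``None``/non-finite) maps to 0.
    """
    if ct_target is None or not math.isfinite(ct_target):
        return 0.0
    if not math.isfinite(ct_ref):
        raise ValueError("reference Ct must be finite")
    return 2.0 ** (-((ct_target - ct_ref) - calibrator_delta))


def quantify_sample(record: SampleRecord,
                    calibrator_delta: float = 0.0) -> ExpressionProfile:
    """ddCt quantification of one sample against the RNU44/RNU48 geomean."""
    flags: set[str] = set()

    def _mean(assay: str) -> float | None:
        reps = record.ct.get(assay)
        if reps is None:
            return None
        mean, flagged = average_replicates(reps)
        if flagged:
            flags.add(FLAG_REPLICATE_DEVIATION)
        return mean

    ref_means = [_mean(r) for r in REFERENCES]
    try:
        ct_ref = reference_geomean(*ref_means)
    except ValueError:
        flags.add(FLAG_REFERENCE_MISSING)
        return ExpressionProfile(record.sample_id,
                                 {m: float("nan") for m in MIRNAS}, flags)

    rel = {m: relative_expression(_mean(m), ct_ref, calibrator_delta)
           for m in MIRNAS}
    return ExpressionProfile(record.sample_id, rel, flags)


def normalize_cohort(records: Iterable[SampleRecord],
                     calibrator_delta: float = 0.0,
                     ) -> tuple[pd.DataFrame, list[ExpressionProfile]]:
    """Quantify every sample; return the expression matrix and profiles.

    The returned DataFrame (samples x 9 miRNAs, indexed by ``sample_id``)
    contains only quantifiable samples: anyone missing a reference RNA is
    dropped from the matrix but still present in the profile list with the
    ``reference_missing`` flag.
    """
    profiles = [quantify_sample(r, calibrator_delta) for r in records]
    n_dev = sum(FLAG_REPLICATE_DEVIATION in p.qc_flags for p in profiles)
    n_ref = sum(FLAG_REFERENCE_MISSING in p.qc_flags for p in profiles)
    if n_dev or n_ref:
        warnings.warn(
            f"{n_dev} sample(s) with replicate deviation > "
            f"{REPLICATE_TOLERANCE} cycles; {n_ref} excluded for a missing "
            "reference RNA", stacklevel=2)
    usable = [p for p in profiles if p.usable]
    frame = pd.DataFrame([p.rel_expr for p in usable],
                         index=pd.Index([p.sample_id for p in usable],
                                        name="sample_id"),
                         columns=list(MIRNAS))
    return frame, profiles


# ---------------------------------------------------------------------------
# CSV dialect: one row per sample, duplicate Ct columns per assay
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "group", "stage", "grade_1973", "grade_2004",
                "focality", "vuc")


def _ct_columns() -> list[str]:
    cols: list[str] = []
    for assay in ASSAYS:
        cols += [f"{assay}_ct1", f"{assay}_ct2"]
    return cols


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Flatten records into the Ct-table layout (duplicates as _ct1/_ct2)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "group": r.group,
            "stage": r.stage or NONE_TOKEN,
            "grade_1973": r.grade73 or NONE_TOKEN,
            "grade_2004": r.grade04 or NONE_TOKEN,
            "focality": r.focality or NONE_TOKEN,
            "vuc": r.vuc,
        }
        for assay in ASSAYS:
            reps = r.ct.get(assay)
            if reps is None:
                row[f"{assay}_ct1"] = ND_TOKEN
                row[f"{assay}_ct2"] = ND_TOKEN
            else:
                row[f"{assay}_ct1"] = f"{reps[0]:.4f}"
                row[f"{assay}_ct2"] = (f"{reps[1]:.4f}" if len(reps) > 1
                                       else "")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + _ct_columns())


def write_ct_csv(records: Sequence[SampleRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _parse_ct(c1: object, c2: object) -> list[float] | None:
    vals = []
    for c in (c1, c2):
        if c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        s = str(c).strip()
        if s in ("", ND_TOKEN):
            continue
        vals.append(float(s))
    return vals or None


def read_ct_csv(path) -> list[SampleRecord]:
    """Read a Ct-table CSV back into :class:`SampleRecord` objects."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        def _opt(col: str) -> str | None:
            v = row[col]
            return None if (pd.isna(v) or v == NONE_TOKEN) else str(v)

        ct = {assay: _parse_ct(row.get(f"{assay}_ct1"),
                               row.get(f"{assay}_ct2"))
              for assay in ASSAYS}
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            stage=_opt("stage"),
            grade73=_opt("grade_1973"),
            grade04=_opt("grade_2004"),
            focality=_opt("focality"),
            vuc=str(row["vuc"]),
            ct=ct,
        ))
    return records


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Clinical metadata (no Ct columns), indexed by sample_id."""
    df = records_to_frame(records)[list(META_COLUMNS)]
    return df.set_index("sample_id")
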