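# Methods

## Study design being modeled

The package evaluates urinary miRNAs as non-invasive markers for bladder
cancer in a case/control design: 104 patients with histologically proven
primary BCa and 46 controls (patients with benign urological findings).
Nine candidate miRNAs and two reference RNAs (RNU44, RNU48) are measured
by qPCR in duplicate from urine-sediment RNA; voided urine cytology (VUC)
provides the clinical comparator as a binary call. Tumors carry stage
(pTa, pT1, pTis, ≥pT2 — concomitant carcinoma in situ coded as the most
severe non-muscle-invasive stage), WHO 1973 grade (G1–G3), WHO 2004 grade
(low/high) and focality.

## Relative quantification

Duplicate threshold cycles per assay are averaged arithmetically. A mean
absolute deviation above 0.25 cycles marks the measurement as one that
would be repeated on the bench; the sample is flagged
(`replicate_deviation`) but not excluded — exclusion is left to the
caller, since re-measurement is not possible for simulated or archived
data. Relative expression is

    rel = 2^-((Ct_target − Ct_ref) − Δ_cal),  Ct_ref = √(Ct_RNU44 · Ct_RNU48)

with three conventions:

* **Non-detection.** A target that never amplifies is assigned expression
  0 — the natural limit of `2^-ΔCt` as Ct → ∞ — so that zero-inflated
  markers (miR-96 in controls) remain usable by the rank-based tests,
  with ties handled by average ranks.
* **Missing reference.** If either RNU44 or RNU48 is undetected the
  sample cannot be normalized at all; it is flagged
  (`reference_missing`) and dropped from the expression matrix.
* **Calibrator.** The second "delta" Δ_cal defaults to 0 (expression
  relative to the references only). Every downstream statistic — the
  Mann–Whitney U test, Spearman correlation, AUC, and the classification
  at a Youden cutoff refit on the same data — depends only on
  within-marker ranks, which a common multiplicative constant cannot
  change. This invariance is enforced by an end-to-end test, so the
  choice of calibrator is provably irrelevant to the analysis.

## Statistical procedures

* **Group differences:** two-tailed Mann–Whitney U per miRNA. The exact
  permutation null is used when `n₁·n₂ ≤ 400` and the pooled sample is
  tie-free; otherwise the tie-corrected normal approximation without
  continuity correction. Family-wise control is Bonferroni's
  `min(1, 9·p)` for the nine markers; correlation analyses are reported
  unadjusted, mirroring common practice of adjusting only the primary
  hypothesis family. A marker's regulation direction (up/down in disease)
  is taken from the mean-rank orientation of U — not from group medians,
  which can tie at zero for zero-inflated markers.
* **Correlations:** Spearman's r_s (average ranks) with the two-sided
  t-approximation; constant input raises an error rather than returning a
  silent NaN. Stage and grades enter as ordinal codes
  (pTa=1 … ≥pT2=4; G1<G2<G3; low<high), computed over tumors only.
* **ROC/AUC:** empirical curve over all distinct thresholds; for an
  up-regulated marker a sample is test-positive at value ≥ threshold, for
  a down-regulated one at value ≤ threshold. The trapezoidal AUC equals
  `U/(n₁n₂)` with ties counted ½ (a tested cross-module identity, also
  cross-checked against scikit-learn). The AUC = 0.5 test uses the
  tie-corrected normal approximation of U.
* **Youden cutoff:** J = sens + spec − 1 maximized over midpoints between
  consecutive distinct values plus the two degenerate thresholds (hence
  J ≥ 0 always). Ties in J prefer higher specificity — the design goal is
  not to sacrifice cytology-grade specificity — then the threshold
  farther from the data median, then the larger threshold. Midpoint
  candidates classify the training data identically to observed-value
  candidates but are reproducible and never coincide with a data point,
  which makes the "boundary counts positive" convention (≥ / ≤ inclusive
  toward the diseased side) unambiguous in practice.
* **Marker orientation is fixed, not refit:** up for miR-96/-126/-183,
  down for miR-125b/-145/-221 (and, from the generator calibration, up
  for miR-21, down for miR-205/-210, whose shifts are too small to matter).
  Auto-orientation (`infer_direction`) exists but is off by default: on
  noisy resamples it can flip the sign of a near-null marker and silently
  turn an anti-marker into a marker.
* **Cutoffs are fit and evaluated on the same cohort** (resubstitution),
  so single-marker and panel performance estimates are optimistic. An
  honest external estimate would need a held-out split or new cohort;
  providing one is out of scope here because the point of the pipeline is
  to reproduce the in-sample evaluation procedure.
* **Panels:** indicators are summed; a sample is positive at
  `positive_count ≥ min_positive`. VUC, when included, is one ordinary
  indicator. The call depends on the indicator sum only, is monotone in
  every indicator, and with `min_positive = 1` plus VUC dominates VUC's
  sensitivity (union rule) — all property-tested.
* **Metrics:** SNS, SPC, PPV, NPV, pLR = SNS/(1−SPC), nLR = (1−SNS)/SPC,
  ACC. A zero denominator yields a distinguished not-determinable marker
  (`n.d.` in tables, `None` in code) — never infinity, so CSV/JSON round
  trips stay lossless. Full precision is kept internally; rounding to
  three decimals happens only at report time.
  `counts_from_rates(sns, spc, n₁, n₀)` reconstructs the integer 2×2
  table behind published rates by nearest-count rounding, which is exact
  whenever the rates were themselves computed from integer counts.

## Synthetic cohort generator

No raw per-patient data are available, so the generator is calibrated to
reproduce the *statistical structure* the analysis assumes, not any
individual measurement:

* **Model.** Gaussian copula on the Ct scale: latent multivariate normal
  with unit-diagonal correlation matrix, scaled per marker (SD 1 cycle)
  around a control mean, shifted by `ct_shift_case` in tumors, plus an
  optional linear stage trend. Duplicate reactions add N(0, 0.15²)
  replicate noise; references are N(24.5/25.5, 0.15²) with 0.10-cycle
  replicate noise. Because downstream statistics are rank-based, any
  monotone marginal would give the same answers; normal marginals make
  the closed-form AUC available for calibration.
* **Closed-form AUC.** For a trend- and non-detection-free marker,
  AUC = Φ(|shift|/(√2·σ_eff)) with
  σ_eff² = ct_sd² + replicate_sd²/2 + Var(reference geomean) ≈ 1.0125².
  A stage trend turns the case distribution into a normal mixture over
  the stage frequencies; non-detection (expression 0, the extreme of the
  down-regulated side) is mixed in exactly. `expected_auc` implements
  this and is the oracle the simulation tests check against (±0.02 at
  5,000 samples per group).
* **Calibration (invented constants, marked as such in `synthetic.py`).**
  Shifts are the closed-form inverses of the target per-marker AUC
  magnitudes 0.581/0.605/0.714/0.667/0.687/0.720/0.537/0.526/0.772;
  miR-96 additionally gets 20 % non-detection in controls (≈9 of 46
  zeros, enough to break likelihood-based methods, as zero-inflation does
  in practice) and 2 % in cases; miR-125b gets a 0.5-cycle/stage-step
  trend with its base shift solved so the mixture AUC stays 0.714.
  Control-mean Cts (25–33) are plausible urinary abundances only.
* **Correlation matrix.** Hand-built positive-definite matrix with a
  strong positive block over miR-21/-125b/-205/-210/-221 (0.566–0.825),
  a second block over miR-96/-126/-183 (0.311–0.557), and negative
  couplings of miR-145 with miR-205/-210 (−0.433/−0.483); remaining
  cross-block entries 0 or mildly negative. Smallest eigenvalue ≈ 0.17;
  a non-PSD input is rejected with the offending eigenvalue named.
* **Clinical strata.** Stage (0.481, 0.212, 0.144, 0.163), WHO-1973 grade
  (0.135, 0.500, 0.365), WHO-2004 grade (0.163, 0.837) and multifocality
  (0.308) are drawn independently per case; VUC is Bernoulli per group at
  (sensitivity 0.769, specificity 1.000), independent of marker values
  given disease status, since no joint distribution is reported.
* **Determinism.** All draws come from one `numpy` Generator seeded by
  the spec; a fixed seed yields a byte-identical Ct CSV.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: qPCR efficiency differences and standard
curves, hemocyte/bacterial background in sediments, correlation between
VUC and marker levels, stage–grade association, batch effects, and any
marginal non-normality of real Ct values. Tests on synthetic cohorts
validate the *procedures* (their identities, error control and parameter
recovery), not the clinical performance of the markers.

## Problem sizes used in the shipped checks

Simulation-based checks run at the sizes where their guarantees are
sharp but cheap: AUC/direction recovery at 5,000 per group (AUC standard
error ≈ 0.006, against a ±0.02 band), copula recovery at 5,000 samples
(±0.05), stage-trend monotonicity at 10,000 cases, null type-I control
over 200 cohorts of 104/46 (1,800 marker tests), and oracle equivalence
on 500 random instances of up to 30 per group.

## Known limitations

* Published p-values and AUCs of the real cohort cannot be reproduced —
  the raw expression data were never deposited; only arithmetic
  consequences of the printed counts and rates are reproduced exactly.
* The exact-vs-asymptotic Mann–Whitney switch is this package's contract;
  other software (e.g. SPSS) may choose differently near the boundary.
* `counts_from_rates` assumes the published rates came from the stated
  denominators; rates computed after exclusions would reconstruct a
  different table (it warns when the round trip is inconsistent).
* The Youden tie-break (specificity first) is one defensible convention;
  cutoffs from software with a different tie-break can differ even on
  identical data while J is tied.
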