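# Methods

`nedose` quantifies how the convention used to report norepinephrine (NE)
doses — free base molecule vs tartrate, bitartrate or hydrochloride salt —
distorts mortality prediction in septic shock. This note documents the model,
the synthetic-data generator, the numerical choices, and what the tests do and
do not establish.

## The reporting-convention identity

Salt formulations contain less active base per milligram, so the same infusion
is charted at different numbers under different conventions:

    d_f = c_f · d_base,   c_base = 1,  c_hydrochloride = 1.22,
                          c_bitartrate = 1.89,  c_tartrate = 2.

The factors are stored to this (literature) precision in
`src/nedose/data/conversion.yaml`; no extra chemistry-derived digits are
added, and the registry is runtime-overridable.

If 28-day mortality follows a logistic dose–response on the base scale,
`logit(p) = α + β·d_base`, then re-expressing doses under convention *f*
changes nothing about the patients but reparameterises the model:

    β_f = β / c_f,    OR_f = exp(β_f) = OR^(1/c_f),    α_f = α.

Two exact consequences drive everything downstream:

* **OR distortion.** A per-unit OR of 9.4 on the base scale becomes
  9.4^(1/1.22) ≈ 6.3, 9.4^(1/1.89) ≈ 3.27 and 9.4^(1/2) ≈ 3.07 under
  hydrochloride, bitartrate and tartrate reporting — 33%, 65% and 67% lower.
* **Prediction equivariance.** `p_f(d) = p_base(d / c_f)`: the risk read off
  at a *reported* dose depends on the convention, and because the curve is
  sigmoid, the gap between conventions widens with dose.

These identities are implemented as closed forms (`expected_slope`,
`fit_from_anchors`) and serve as the analytic oracle against which the fitted
models are tested (`β_f·c_f = β_base` to 1e-8; interaction vs separate fits to
1e-6).

## Anchor calibration

Published threshold tables give mortality at dose cut-offs; solving the
two-parameter logistic through two such anchors on the logit scale recovers
(α, β) exactly. The shipped anchors are the base-molecule cells at 0.1 and
1.0 µg/kg/min:

* diagnosis dose: (0.1, 0.36), (1.0, 0.81) → α = −0.8004, β = 2.2504
  (OR ≈ 9.49, consistent with the published 9.4 [6.1–14.7]);
* peak dose: (0.1, 0.27), (1.0, 0.83) → α = −1.2813, β = 2.8669.

With more than two anchors the solve is least squares on the logit scale.

## Dose variables from infusion streams

Infusion streams are piecewise-constant rate functions (rate holds on
[start, end); gaps mean the pump is off, i.e. rate 0). Three variables per
patient:

* **Stability-filtered peak dose** (24 h window after shock diagnosis): among
  distinct observed rates in descending order, the first rate *r* such that
  the rate function stays within the multiplicative band [0.9r, 1.1r] over a
  contiguous interval of ≥ 5 min containing at least one record at exactly
  *r*. This filters sub-5-minute pump spikes and registry glitches. The band
  is centred multiplicatively on the candidate (symmetric and scale-free; the
  alternative — a band anchored on the maximum — is not used). Exhaustion of
  candidates returns *missing*, and such patients are excluded downstream for
  absent dose values. The implementation is tested against an independent
  exhaustive interval scanner on randomized ≤10-event streams.
* **Diagnosis dose**: the rate of the record whose start is nearest the shock
  diagnosis time, ties broken toward the earlier record.
* **Peak NE-equivalent rate**: max over time of Σ w_d·rate_d across
  concurrent vasopressors, with the weight table transcribed from the updated
  vasopressor-equivalence formulas (Kotani et al., 2023): NE 1, epinephrine 1,
  phenylephrine 0.1, dopamine 0.01, metaraminol 0.125, vasopressin 2.5 per
  U/min, angiotensin II 10. Weights apply to native units; unit mismatches
  are rejected, never silently converted.

Registry-error outliers (rate > 5 µg/kg/min base by default, configurable)
are removed before extraction and counted; absolute rates (µg/min) are
weight-normalised, and a missing weight is an exclusion, not a default.

## Sepsis-3 screen

Eligibility: age ≥ 18; suspected infection (antibiotic within 72 h after a
culture, or culture within 24 h after an antibiotic — the conventional pairing
windows, config-exposed); SOFA ≥ 2 at/after the suspicion time; NE use;
lactate ≥ 2 mmol/L nearest NE start within ±6 h (configurable); NE start
within (−12 h, +72 h) of the sepsis diagnosis; complete demographics; valid
dose values after outlier removal. Criteria are applied in that fixed order
and each exclusion is charged to the first failing criterion, so the ledger
is reproducible and conserves counts (input = retained + Σ excluded);
screening is idempotent.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
ICU physiology:

* **Peak dose**: log-normal with median 0.24 µg/kg/min and σ chosen to match
  the quartile *ratio* 0.42/0.12 (σ = ln(3.5)/(2·z₀.₇₅) ≈ 0.929), clipped to
  [0.02, 4.9]. A log-normal cannot match a log-asymmetric IQR exactly; the
  realised quartiles are ≈ 0.13/0.45 against the target 0.12/0.42, with the
  median exact. Parameterisation is median/quartiles and overridable.
* **Diagnosis dose**: peak × Beta(2.5, 3.4) fraction (median fraction ≈ 0.42),
  putting the median diagnosis dose near 0.1 µg/kg/min.
* **Mortality**: one Bernoulli draw per patient on
  expit(α + β·peak_dose), defaulting to the peak-anchor calibration above. No
  censoring or time-to-event structure — the outcome is a binary 28-day
  indicator. Because mortality is keyed to the *peak* dose, the
  diagnosis-dose regression on a full synthetic cohort is a misspecified
  proxy model and is *not* calibrated to the published diagnosis-dose OR;
  recovery of that OR is checked with the direct simulation path
  (`simulate_dose_mortality`), which draws diagnosis doses from their own
  log-normal (median 0.1, IQR 0.05–0.2) with Bernoulli mortality.
* **Infusion streams**: up-titration (diagnosis dose, then midpoint), a
  sustained ≥ 30 min segment at exactly the latent peak, then down-titration;
  optional sub-5-minute spikes at 1.5× peak (bracketed by down-rate segments
  so no two spikes can merge into a pseudo-stable run; expected 0.2 per
  patient), and 2% of patients get a one-minute registry-error record at
  60 µg/kg/min. With spikes and outliers disabled the stability-filtered
  extractor recovers the latent peak exactly for every patient — the
  generator/extractor consistency tests rely on this.
* **Second vasopressors** in 57% of patients (vasopressin / phenylephrine /
  epinephrine at 45/32/23 within that group, native units).
* **Screen pass fraction** configurable; failing patients are assigned one
  named failure mode (low lactate, SOFA 1, NE start at +80 h, missing weight,
  or all-outlier doses), so ledger counts are exactly predictable.
* **Covariates** (age, weight, SOFA, lactate values) are drawn independently
  of dose and of each other around the published medians; they are
  deliberately non-calibrated beyond that, since the joint distribution is
  not described. Nothing downstream conditions on them.
* **Determinism**: one master seed; each table draws from an independently
  spawned substream, so adding a table never perturbs the others. Two runs at
  the same seed produce byte-identical CSVs.

What passing tests therefore show: the pipeline's algebra, filtering and fits
behave correctly on data with the assumed structure. What they do not show:
robustness to real-EHR pathologies the generator omits (overlapping pump
records, unit chaos beyond µg/min vs µg/kg/min, missing-not-at-random labs,
multi-stay patients).

## Fitting and uncertainty

* Default variant fits four independent logistic regressions (Newton,
  tolerance 1e-12); the stacked interaction model (per-formulation intercept
  and slope, cell-means coding) is provided and tested to agree — the stacked
  rows carry no extra information. A patient-level random-intercept variant
  (variational Bayes) exists for completeness; on this design the variance
  component is weakly identified (each patient contributes four deterministic
  copies of one observation), so it is reported but never interpreted, and
  its coefficients are not expected to match the ML fits.
* Predicted-mortality CIs use the delta method on the logit scale
  (var(α̂ + β̂d) from the coefficient covariance, ±1.96·SE, then the logistic
  transform), guaranteeing CI ⊂ [0,1] and containing the point estimate.
* Dose enters linearly on the logit scale only (no splines): the published
  curves are plain sigmoids.
* Table rendering rounds half-up to integer percent.
* Degenerate inputs (single-class outcome, zero dose variation, perfect
  separation, non-convergence) raise an explicit fit error with diagnostics
  rather than returning silent estimates.

## Problem sizes

The test suite simulates cohorts of 150–12 000 patients (12 000 for the
end-to-end Monte-Carlo reproduction of the threshold table, within ±2
percentage points of the closed-form cells), 200 replicates of n = 4086 for
parameter recovery, and one n = 50 000 replicate for the single-cohort OR
check; the analysis drivers default to the study-sized n = 4086. These sizes
give Monte-Carlo error comfortably inside the tolerances asserted while
keeping a full run in minutes on one core.

## Known limitations

* The two-anchor reconstruction reproduces published table cells to ±1
  integer percent (e.g. it gives 56 where one published peak-dose cell prints
  57); anchoring on more cells via the least-squares path would trade exact
  interpolation for overall fit.
* The generator's diagnosis dose is a deterministic Beta-thinning of the
  peak; real diagnosis/peak joint structure is richer.
* Overlapping concurrent NE infusions (multiple pumps) are rejected at
  validation rather than reconciled.
* The NEE weight table is a transcription of a published consensus formula;
  institutions using other equivalences should override the config.
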