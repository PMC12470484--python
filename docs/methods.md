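# Methods

This note documents the models, conventions and design choices behind
`afscreen`, in the spirit of a statistical-software methods appendix. It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Synthetic cohort and waveform model

**Purpose.** The pipeline targets longitudinal clinical ECG archives that
cannot be redistributed. The generator therefore emulates the *structure*
such data must have for a two-stage screen to be meaningful: a latent
atrial-remodeling burden expressed in sinus-rhythm waveform features, paired
baseline/follow-up recordings, configurable prevalence, and covariates
correlated with the outcome.

**Latent risk.** Each patient carries `latent_risk` in [0, 1]: cases
(`future_AF`) draw from Beta(5, 2) and controls from Beta(2, 5). The two
distributions overlap — no feature separates the classes deterministically —
but are separable enough that a sensitivity band of 0.85–0.90 is attainable
at realistic specificity. Case ages are drawn with a higher mean than
control ages (65.7 ± 13.0 vs 56.5 ± 13.5 years) and cases are slightly more
often male (53.9% vs 46.9%), matching the usual directionality of AF
cohorts; roughly half of cases carry a prior-stroke flag
(`stroke_fraction_in_cases = 0.51`), and stroke history is only assigned
within cases.

**Waveform synthesis.** Each record is 10 s, 9 leads (I, II, III, V1–V6;
augmented limb leads are linear combinations and add no information),
500 Hz, quantized to 5 μV. Waveforms are additive templates: per beat, a
Gaussian P wave (biphasic in V1), Q/R/S bumps and a Gaussian T wave are
placed on a baseline-wandered trace with white measurement noise
(`noise_sd`, default 0.02 mV) and a shared narrow-band 4–9 Hz "atrial
activity" component. An additive template was chosen over a dynamical
(ODE-based) heart model deliberately: it gives exact, closed-form control of
every fiducial and parameter, so the generator can hand downstream tests
their ground truth. The cost is physiological fidelity (see §8).

**Risk coupling.** The risk drive is `effect_size * latent_risk`, plus
`progression_rate * latent_risk` at the follow-up visit *for cases only*.
Risk-linked parameters, all non-decreasing in the drive:

| parameter | base (approx.) | slope per unit drive | direction |
|---|---|---|---|
| P duration | 98 ms | +11 ms | ↑ |
| PR interval | 155 ms | +12 ms | ↑ |
| RR jitter (SDNN driver) | 22 ms | +14 ms | ↑ |
| inter-lead P timing jitter | 1 ms | +4 ms | ↑ |
| inter-lead P amplitude dispersion | 0.04 | +0.10 | ↑ |
| 4–9 Hz atrial-band amplitude | 0.004 mV | +0.009 mV | ↑ |

Between-subject scatter is seeded per patient and held fixed across visits,
so the only systematic within-patient change between visits is the case
progression term — exactly the signal the serial model is meant to read.
Setting `effect_size = progression_rate = 0` removes all label information
from the waveforms; every downstream discrimination metric must then be
consistent with chance, and the test suite checks this null regime.

Default study conditions for the end-to-end evaluation: n = 2000 patients,
prevalence 0.10, follow-up at 90 days, `effect_size = 1.0`,
`progression_rate = 0.6`. Identical configurations are bit-reproducible.

## 2. Preprocessing and delineation

* **Band-pass, 0.5–40 Hz by default.** Implemented as a zero-phase spectral
  (real-FFT mask) filter with narrow raised-cosine transitions (±30% around
  the low cutoff, ±10% around the high cutoff). A mask filter has exactly
  zero phase (fiducial timing untouched) and is idempotent outside its
  narrow transition bands, which an IIR design cannot achieve at the 0.5 Hz
  edge where real ECG beat trains hold appreciable energy.
* **R detection** is a Pan–Tompkins-style chain (5–18 Hz band-pass,
  derivative, squaring, 150 ms moving-window integration, peak picking with
  a 250 ms refractory), refined to the local raw-signal maximum. A
  flat-line lead returns an empty result with a quality warning, not an
  exception.
* **Delineation** is windowed search relative to each R peak. QRS onset and
  offset are anchored 12 ms outside the Q and S nadirs. The P wave is
  searched in [R−300 ms, R−55 ms] (bounded below by the previous T offset):
  the isoelectric baseline is taken from the trailing PR-segment end of the
  window, the P peak must clear 0.05 mV (otherwise the beat is flagged
  `quality=False` — absent waves are never fabricated), boundaries are the
  10%-of-peak crossings extrapolated to a 2.5 σ Gaussian bound, and either
  half-width is capped at 1.5× the other (a compact P is near-symmetric;
  the cap stops one-sided runaway along low-amplitude ripple). T offset
  uses the tangent method: steepest post-peak downslope extrapolated to
  baseline. Indices are 0-based; intervals half-open `[onset, offset)`.

## 3. Feature vector

One fixed-order vector per ECG (`feature_order_version = "1.0"`, 58
entries): 11 beat-level quantities (P/R/T peak amplitudes; PR, QRS, QT, RR
intervals; PR- and ST-segment levels; P and T durations) each summarized
across quality beats by mean / min / max / SD; four P-shape indices
(rectified P area, peak-position symmetry, inter-lead P-duration dispersion
on R-aligned mean beats, P terminal force in V1, ≤ 0 by convention);
beat-wise Pearson correlations against the per-record sample-wise median
template (mean / min / SD); the atrial-band index (Welch power in 4–9 Hz
over 0.5–40 Hz after subtracting the R-aligned median beat, i.e. after
ventricular suppression; bounded in [0, 1]); HRV summaries (SDNN, RMSSD,
pNN50, mean HR); and age and sex (0 = female, 1 = male).

Conventions fixed for reproducibility: SD uses the n−1 denominator; a
single observation has SD 0; quantities that cannot be computed are NaN
missing markers, which the tree learner handles natively — nothing is
imputed. Units are ms and mV. Lead access is by label, so storage order is
irrelevant.

**Serial (delta) features** are the element-wise follow-up − baseline
differences of the 56 ECG-derived entries; age and sex enter as their
follow-up values (a sex delta is meaningless and an age delta is collinear
with the pair interval), and the inter-ECG interval in days is carried
alongside. Deltas are antisymmetric and exactly zero for identical inputs.

## 4. Cohort assembly

Adjudication applies six exclusion criteria in a fixed order, recording the
first match per patient: (i) AF documented before the first NSR ECG,
(ii) no NSR ECG before the index AF date, (iii) fewer than two NSR ECGs,
(iv) an AF indication without a positive AF ECG, (v) incomplete records,
(vi) unclassifiable rhythm calls. The index AF date is the earliest
documented AF date. Decisions depend only on the individual record, so
input order cannot change inclusion.

Serial pairs are **adjacent consecutive** NSR ECGs (not all combinations),
matching the two-visit protocol structure. The blanking rule is explicit
and configurable: both members of a case's pair must precede
`index_af_date − blanking_days` (default 0, i.e. strictly pre-index); the
default is a declared choice, since only the existence of a prespecified
blanking rule — not its width — is part of the protocol description.

Splits are at the patient level (every ECG of a patient lands in one of
train/validation/test) with a seeded random mode and a temporal mode that
assigns by first-ECG date against calendar boundaries; leakage is asserted
on every split.

## 5. Risk models

Both classifiers are LightGBM gradient-boosted trees with a logistic
objective, early stopping on validation log-loss (30 rounds patience) and
class weighting via `scale_pos_weight` (defaulting to the negative/positive
ratio when not searched). Hyperparameter search is Gaussian-process
expected improvement over a bounded space — n_estimators 100–2000, learning
rate 0.005–0.3 (log), num_leaves 15–255, row/column subsampling 0.5–1.0,
min_data_in_leaf 10–200, positive-class weight 1–20 — with the first third
of the budget as seeded random exploration and a Matérn-5/2 GP (on the unit
cube, log-warped where flagged) proposing subsequent points from a random
candidate set. Failed trials are logged and skipped, never fatal. The exact
bounds and budget are declared defaults: they are configurable because no
canonical published values exist for this protocol. Model selection
maximizes validation AUROC.

Determinism: LightGBM runs single-threaded with `deterministic=True`, and
the trial sequence, acquisition sampler and GP are all seeded — two runs
with the same data, config and seed produce bit-identical scores. Scoring
refuses feature matrices whose column order differs from training (no
silent reordering), and the training wrapper asserts that no test-partition
patient contributes rows to the training or validation matrices.

## 6. Operating points and protocol

Candidate thresholds are the unique observed validation scores plus a +∞
sentinel (the all-negative rule); a subject is positive iff
score ≥ threshold; ties in the selection objective break toward the larger
threshold (higher specificity). Stage 1 uses the sensitivity-band rule:
among candidates with validation sensitivity in [0.85, 0.90] (inclusive),
maximize specificity; if the band is unattainable, fall back to the
candidate with sensitivity closest to 0.85 from above. Whether the original
protocol maximized specificity within the band or targeted a fixed
sensitivity is not documented; maximizing specificity is this package's
declared resolution, and both selectors are verified against brute-force
enumeration. Stage 2 uses Youden's J. Both are computed on validation
scores only.

The protocol engine short-circuits: the serial model is never evaluated for
stage-1 positives (the engine counts its stage-2 evaluations so the
property is testable). Patients lacking a follow-up ECG after a negative
stage 1 are flagged incomplete and receive no final classification rather
than an imputed one. The stage-1 threshold is selected on baseline-visit
validation rows, mirroring how it is applied.

## 7. Evaluation conventions

Sensitivity, specificity, PPV, NPV, accuracy and F1 derive from the 2×2
counts with NaN markers for zero denominators (F1 is 0 when either
precision or recall is 0). AUROC is the Mann–Whitney concordance
probability with ties counted ½; PR-AUC is step-wise average precision;
calibration intercept and slope come from a logistic recalibration of the
outcome on logit(score) (scores clipped at 10⁻⁶ before the logit;
degenerate designs return NaN). Confidence intervals are percentile
bootstrap (2.5/97.5) with the patient as resampling unit — percentile
rather than BCa because nothing in the protocol's reporting requires
second-order accuracy — with undefined resamples redrawn and counted.
Reported tables round to three decimals, half-up.

## 8. Problem sizes in the test suite

The acceptance-level tests run the full study at n = 2000 patients
(prevalence 0.10) across five seeds for the serial-advantage sign test,
n = 800 for the null regime, n = 120 for bit-determinism, 100 cohorts for
the leakage property, and n = 50,000 synthetic scores for calibration
self-consistency. These sizes were chosen as the smallest at which the
binomial/bootstrap tolerances of the corresponding checks are meaningful.

## 9. Known limitations

* The waveform model is a feature-level emulation: no vectorcardiographic
  consistency across leads, no AF-rhythm waveforms, no pathological
  morphologies beyond the risk-linked parameter shifts, no pediatric ECGs.
  Passing tests demonstrate the pipeline's correctness and the protocol's
  internal logic on data with the stated structure — they do not certify
  discrimination on real clinical ECGs.
* Delineation accuracy degrades gracefully as the synthetic atrial-band
  ripple grows with risk drive (boundaries blur exactly as they would
  physiologically); feature noise at high risk is therefore part of the
  simulation, not an artifact to be removed.
* The serial stage is evaluated on the single available pair per synthetic
  patient; multi-pair policies beyond adjacent pairing are out of scope.
* Synthetic effect sizes are tuning knobs of the generator, not estimates
  of any real cohort's feature distributions.
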