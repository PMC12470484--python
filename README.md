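# afscreen

Two-stage AI-ECG screening for atrial fibrillation, as a reusable and fully
tested Python pipeline.

## The problem

Atrial fibrillation (AF) is frequently paroxysmal: a patient at high risk can
present in normal sinus rhythm (NSR), so single-timepoint rhythm checks miss
many cases, while indiscriminate ambulatory monitoring is too expensive to
apply population-wide. Subtle atrial-remodeling signatures in a sinus-rhythm
12-lead ECG — P-wave prolongation and dispersion, PR-interval changes,
heart-rate-variability shifts, excess narrow-band atrial activity — carry
information about near-term AF risk. `afscreen` implements a sequential
screening protocol built on that signal:

1. **Stage 1 (baseline visit).** A gradient-boosted tree classifier scores a
   fixed-order feature vector engineered from a single sinus-rhythm ECG. The
   decision threshold is *sensitivity-targeted* (validation sensitivity in
   [0.85, 0.90]): a negative screen should safely defer monitoring, so the
   protocol prioritizes negative predictive value at entry.
2. **Stage 2 (short-interval follow-up, ~90 days).** For screen-negative
   patients only, a *serial* classifier scores the element-wise change
   (follow-up − baseline) of the same ECG features, thresholded at Youden's
   J (maximum sensitivity + specificity − 1) to recover precision.
   A positive at either stage refers the patient to intensive wearable
   monitoring; a double negative returns to routine six-monthly ECG.

Because clinical ECG archives of this kind are not redistributable, the
package includes a first-class synthetic cohort generator: additive-template
ECG waveforms (Gaussian P-QRS-T bumps, baseline wander, quantization, noise)
whose risk-linked parameters are monotone in a latent atrial-remodeling
variable, with stored ground-truth fiducials so that every downstream stage —
beat detection, delineation, feature extraction, model training, threshold
selection, protocol evaluation — can be tested against exact oracles.

## Who it is for

Researchers prototyping sequential (multi-visit) diagnostic screening
policies, and developers who need a transparent, deterministic reference
implementation of the screening-metric arithmetic (confusion-matrix panel,
Mann–Whitney AUROC, PR-AUC, calibration intercept/slope, percentile
bootstrap CIs) used to report such protocols.

## Worked example

```python
from afscreen import SimulationConfig, run_screening_study
from afscreen.models import TrainingConfig

cfg = SimulationConfig(n_patients=300, prevalence=0.10, seed=1)
res = run_screening_study(cfg, TrainingConfig(n_trials=0, seed=1))

print("stage-1 threshold:", round(res.stage1_point.threshold, 3),
      "(validation sensitivity", round(res.stage1_point.sensitivity, 3), ")")
print("stage-2 threshold:", round(res.stage2_point.threshold, 3),
      "(Youden J", round(res.stage2_point.J, 3), ")")
for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1",
          "auroc_single_test", "auroc_serial_stage2"):
    print(f"{k}: {res.metrics[k]:.3f}")
```

prints (exactly, given the fixed seed):

```
stage-1 threshold: 0.046 (validation sensitivity 0.889 )
stage-2 threshold: 0.201 (Youden J 0.672 )
sensitivity: 0.900
specificity: 0.738
ppv: 0.346
npv: 0.980
accuracy: 0.760
f1: 0.500
auroc_single_test: 0.860
auroc_serial_stage2: 0.752
```

Reading: on the held-out test patients the two-stage protocol catches 90% of
future-AF cases while keeping NPV at 0.980 — a negative pathway is a safe
deferral — and the serial model still discriminates (AUROC 0.752) exactly on
the subpopulation the baseline screen let through. PPV is modest, as
expected at 10% prevalence; that is the cost the sensitivity-first design
accepts at stage 1 and claws back at stage 2. (At the n = 2000 study size
used by the acceptance script these estimates tighten considerably.)

The evaluation module also reproduces published-style confusion arithmetic
exactly: `metrics_from_confusion(ConfusionMatrix(tp=947, fn=128, fp=2186,
tn=8088))` returns sensitivity 0.881, specificity 0.787, PPV 0.302, NPV
0.984, accuracy 0.796 and F1 0.450 at three decimals.

## Layout

| module | contents |
|---|---|
| `afscreen.sim` | synthetic cohort + waveform generator with ground truth |
| `afscreen.records` | `ECGRecord` / `BeatAnnotation` containers, CSV/JSON I/O |
| `afscreen.preprocess` | zero-phase band-pass, R detection, delineation |
| `afscreen.features` | engineered feature vector and serial delta features |
| `afscreen.cohort` | adjudication, serial pairs with blanking, splits |
| `afscreen.models` | `AFRiskClassifier` (LightGBM + GP Bayesian search) |
| `afscreen.thresholds` | Youden and sensitivity-band operating points |
| `afscreen.protocol` | the two-visit sequential decision engine |
| `afscreen.evaluation` | metric panel, bootstrap CIs, calibration, subgroups |
| `afscreen.pipeline` | `run_screening_study`: everything wired end to end |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
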