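# Methods

## Problem and data model

A body-pressure measurement mat on the seat of a chair records the contact
pressure distribution of a seated person as a 32 × 32 grid of
non-negative sensor values at 50 Hz. During seated reaching, people with
post-stroke upper-limb impairment recruit compensatory trunk strategies —
trunk lean-forward (TLF), trunk rotation (TR), shoulder elevation (SE) —
that redistribute seat pressure in characteristic ways, while unimpaired
("healthy-side") reaches do not (NC). One *trial* is a pre-segmented
single reach; the package classifies trials into these posture classes.

Coordinates are fixed by convention, since mat mounting is arbitrary:
column index = lateral coordinate *x* (left edge = 1), row index =
longitudinal coordinate *y* (front edge = 1). Both are configurable at
the feature level (`flip_lateral`, `flip_longitudinal`).

Raw mats carry a per-sensor bias; `remove_offset` subtracts a recorded
bias matrix and clips at zero, because pressure cannot be negative and
the correct handling of over-subtraction is otherwise undefined.

## Features

Five per-trial scalars: ASV (mean frame total) and the standard
deviations of LatCOP, LonCOP, LRratio and FBratio (definitions in the
README). Choices that required a decision:

- **Ratio axes.** The half-ratio named "left/right" splits the lateral
  axis and "front/back" the longitudinal axis (`axis_mode="semantic"`,
  the default). A `"literal"` mode that swaps the axes is retained for
  compatibility with a formula variant in which the two ratios are
  written over each other's axes; the semantic reading matches the
  posture phenomenology (rotation → lateral asymmetry, lean-forward →
  front/back shift) and is what the classifiers use.
- **Degenerate frames.** COP and ratios are undefined when a frame total
  or a denominator half-sum is zero. Such frames are flagged invalid and
  excluded from all four SDs (never raised), while ASV always averages
  over all *T* frames, since total time is well defined regardless.
  Fewer than two valid frames is an error naming the trial.
- **SD convention.** Sample SD (ddof = 1). Any consistent convention
  works for classification; this one is stated so results are exactly
  reproducible.
- **Granularity.** One feature vector per repetition (per reach), giving
  1440 vectors for the full 8-subject design.

## Classifiers and cross-validation

Features are standardised to zero mean, unit variance (population SD,
the usual z-score convention) with moments learned from the training
rows of each fold only — test subjects never influence standardisation.

- **k-NN**: Euclidean distance, majority vote. Determinism requires
  explicit tie rules: equal distances rank by training-row index; among
  classes with equal votes the nearest neighbour's class wins. k is
  selected per fold from {1, 3, 5, 7, 9, 11, 13, 15} by an inner
  subject-grouped sweep maximising pooled macro F1, ties to the smallest
  k (small k = lower variance estimate preferred).
- **SVM**: linear soft margin, C = 1 by default (real data need not be
  separable); the solver is libsvm's SMO via scikit-learn, and the
  contract — zero training error and margin ≥ 1 − ε on separable data at
  large C — is tested directly. Multiclass uses one-vs-one pairwise
  machines by default: with these five features SE lies *between* NC and
  TR along the lateral-magnitude direction, and a linear one-vs-rest
  machine cannot isolate a middle band, while pairwise machines can.
  One-vs-rest remains available (`scheme="ovr"`).
- **Cross-validation** partitions subjects, 4 folds × 2 test subjects
  for 8 subjects, seeded. Reports carry per-fold confusion matrices and
  both aggregations (pooled-confusion metrics and mean-over-folds),
  since either convention is common.

Two framings: binary detection (NC vs any compensation, positive class =
compensation) per reaching task, and 4-class recognition over all tasks.

## Metrics and statistics

Per-class precision, recall, F1 from the confusion matrix; macro
(unweighted) averaging; 0/0 cells reported as 0 with a warning so reports
stay total. Printed reports round half-up to 3 decimals — half-up (not
banker's) is required for the published-table consistency checks, where
cells like 0.98075 print as 0.981. Paired comparisons use the two-sided
paired t-test with explicit degenerate handling (identical pairs → t = 0,
p = 1; constant nonzero difference → flagged). The Friedman test is the
tie-corrected rank chi-square, implemented directly because the common
library routine requires ≥ 3 conditions while two-condition tables (e.g.
two classifiers across subjects) are also of interest; it is cross-checked
against that routine for k ≥ 3.

## sEMG verification chain

Per channel, in order: mean subtraction, zero-phase 4th-order Butterworth
band-pass 20–200 Hz, zero-phase 4th-order Butterworth band-stop 48–52 Hz
(mains notch), full-wave rectification, amplitude normalisation.
Zero-phase (forward-backward) filtering avoids phase distortion of the
amplitude envelope at the cost of doubling the effective order. The
notch width (±2 Hz) and the baseline method (mean subtraction rather
than detrending) are package conventions, stated here because narrower
or wider choices are equally defensible.

Normalisation defaults to the per-channel trial maximum (no MVC
reference is assumed). Note that max-normalised RMS is scale-free:
cross-side *amplitude* comparisons (Ave-RMS affected vs healthy) must use
`normalize="none"` or a common external reference, and the package's
verification tests do so. RMS is computed over the whole motion segment,
one value per trial per muscle; Ave-RMS first averages trials within
subject, then reports the across-subject mean and SD (SD = 0 by
convention for a single subject; empty cells are absent, not errors).

## Synthetic data generator

No clinical recordings are deposited, so the generator emulates the
statistical structure the method assumes: a seated pressure map of two
Gaussian ischial-tuberosity peaks (rows ≈ 22, columns 12.5/20.5,
σ = 2.6, amplitude 45 device units) plus a broad anterior thigh band
(row 7), swaying along a smooth out-and-back reach envelope
e(t) = sin²(πt/(T−1)). Label effects ride on m(t) = e(t)/mean(e), so the
*trial-mean* applied displacement equals the configured effect size:

| effect | default | meaning |
|---|---|---|
| `tlf_forward_shift` | 3.0 rows | mean forward COP displacement (TLF) |
| `tr_lateral_shift` | 2.5 cols | mean contralateral displacement (TR) |
| `tr_load_asymmetry` | 0.3 | relative ischial load/unload swing (TR) |
| `se_ipsilateral_shift` | 0.6 cols | small ipsilateral displacement (SE) |
| `se_amp_asymmetry` | 0.25 | ipsilateral extra loading (SE) |
| `mult_noise_sd` / `add_noise_sd` | 0.08 / 0.3 | per-sensor noise |
| `subject_center_sd` | 1.0 rows/cols | anatomical peak placement |
| `subject_amp_sd` / `subject_effect_sd` | 0.15 | body-mass / severity spread (lognormal) |
| `trial_effect_sd` / `trial_sway_sd` | 0.10 / 0.15 | execution variability |

NC sway amplitudes are task-dependent (back-and-forth 0.7 rows
longitudinal, side-to-side 0.6 columns lateral, up-and-down 0.25 each),
reflecting the motion direction of each reach. The full design is
8 subjects × 2 sides × 3 tasks × 30 repetitions = 1440 trials of 3 s at
50 Hz, seed 42; healthy-side trials are NC and each task's affected-side
trials carry one dominant compensation (back-and-forth → TLF,
side-to-side → TR, up-and-down → SE) — which pattern dominates which task
is a free design choice, and the mapping is configurable.

Defaults were chosen once to place the default dataset in a separable but
non-trivial regime (cross-validated F1 in the 0.95–1.0 range): geometry
keeps the ischial peaks away from the front/back half boundary (ratio
denominators otherwise collapse under TLF, making the FB ratio
heavy-tailed), and SE is deliberately the subtlest pattern. Companion
sEMG trials are 20–200 Hz noise carriers modulated by the reach envelope
on 9 trunk-muscle channels, with a ×1.5 affected-side gain on the muscle
group associated with the trial's pattern (TLF → rectus abdominis,
obliquus externus, thoracic erector spinae; TR → lumbar erector spinae;
SE → descending trapezius).

What the generator does *not* emulate: biomechanically accurate
body–seat contact, anthropometric covariation, drift and hysteresis of
piezoresistive sensors, compound compensations, or within-trial pattern
onset/offset. Passing tests therefore demonstrate the correctness and
statistical honesty of the pipeline under the assumed structure, not
clinical-grade accuracy on real patients.

## Determinism and problem sizes

All randomness derives from one root seed through per-subject and
per-trial child streams; a trial's draws do not depend on its label, so
zeroing the effect sizes makes a compensation trial bit-identical to its
NC counterpart — the null-effect tests rely on this. Property tests run
on scaled-down configurations (4 subjects × 8 repetitions, 1.2 s trials;
monotonicity at 3 effect levels × 6 seeds; the sEMG Monte-Carlo at 100
seeds × 4 subjects × 0.5 s), sizes chosen to exercise the invariants with
adequate Monte-Carlo resolution; the acceptance run uses the full
1440-trial design.

## Known limitations

- The five features are unsigned volatilities: they cannot distinguish
  direction (e.g. left- vs right-rotation), only magnitude patterns.
- Half-pressure ratios are unstable when a denominator half carries
  little mass; the generator avoids that regime, real seating may not.
- Segmentation of continuous recordings into trials is out of scope;
  inputs arrive pre-segmented.
- Compensation is detected and categorised, not graded; compound
  compensations are reported as the dominant pattern only.
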