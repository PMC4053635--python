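# Methods

## Problem setting

After intravenous thrombolysis for acute ischemic stroke, a minority of
patients deteriorate from symptomatic intracranial haemorrhage (SICH).
The pipeline implemented here asks whether a classifier reading the whole
baseline CT image — together with clinical severity — can pick those
patients out better than composite bedside scores (SEDAN, HAT) built from
a few radiologist-judged features.  The package reproduces the full
analysis chain on synthetic cohorts, since clinical cohorts of this kind
are not deposited: generation, image preprocessing, scoring, weighted SVM
training and repeated case–foil evaluation.

## Synthetic cohort generator

The generator is the package's definition of the study conditions, not a
tuning knob.

**Risk model.**  Each subject carries latent radiological truths (acute
ischemia presence and MCA-territory fraction, hyperdense MCA, Fazekas
grade 0–3, a diffuse non-negative "background burden") and clinical
covariates.  SICH risk is logistic in standardized NIHSS, ischemia
fraction and background burden with coefficients (0.5, 1.0, 1.0); the
intercept −3.75 puts the population complication rate near the ~6%
reported for thrombolysis at large.  A fixed case–control composition
(default 16 + 100) is obtained by rejection sampling, which leaves the
joint latent–outcome distribution intact, and the cohort is shuffled so
subject order carries no outcome information (deterministic tie-breaks
downstream must not see the case/control structure in the ordering).

**Marginals.**  NIHSS is a clipped integer normal (mean 11, SD 5) plus
5 × ischemia fraction, coupling clinical severity to infarct extent;
ischemia is present in 30% of the population with Beta(2, 3) fractional
extent; the hyperdense MCA sign co-occurs with ischemia (45% vs 5%);
background burden is Gamma(2, 0.5).  Under the risk model these reproduce
the target group contrasts approximately: an NIHSS gap of ~3 points
(cases ~14.5 vs controls ~11.4) and ischemia prevalence ~63–73% in cases
vs ~27% in controls.  Covariates outside the risk model (age, glucose,
gender, blood pressure, INR, platelets, anti-thrombotic history) are
outcome-independent, matching their non-significant univariate odds
ratios in the clinical population emulated.

**Raters.**  Three independent readers see each latent truth through a
symmetric misclassification channel.  For two raters flipping a binary
truth of prevalence p with probability ε, observed agreement is
(1−ε)² + ε² and the common marginal is q = p(1−ε) + (1−p)ε, giving a
closed-form expected Cohen's κ; `calibrate_rater_noise` inverts it by
bisection.  Defaults target the published agreement levels: κ 0.355 for
acute ischemic change (prevalence 0.27) and 0.673 for the hyperdense MCA
sign (prevalence 0.17).  Extent (> 1/3 MCA) is forced negative whenever
the rater saw no ischemia; Fazekas is read with ±1 discrete noise clamped
to 0–3.  The error model is symmetric because only κ is observable —
asymmetric false-positive/false-negative structure is not inferable from
a single agreement coefficient.  Consensus is 2-of-3 majority for binary
features and the arithmetic mean for Fazekas; only the binary consensus
flags enter scores.

## CT phantom and preprocessing

Acquisitions come in two blocks — upper cerebrum and brain base — so the
phantom renders an ellipsoidal brain (parenchyma ~33 HU, ventricles
~8 HU, skull shell 700 HU) on a common grid (default 64 × 64 × 40 voxels;
the lower section covers slices 0–15, the upper 12–39) and slices it into
two overlapping sections.  Truth-driven features: an ischemic wedge of
angular size proportional to the MCA fraction (−8 HU), an optional
hyperdense vessel dot (+32 HU), periventricular hypodense caps scaled by
Fazekas grade, and a smooth random texture whose amplitude scales with
background burden.  A single `amplitude` factor scales all of them, so
amplitude 0 produces images statistically independent of outcome — the
null condition used to check that discrimination collapses to chance.
Each section receives a small rigid jitter (in-plane SD 0.5 voxel,
through-plane 0.25, rotation SD 1°, all truncated) standing in for
imperfect template normalisation, plus Gaussian noise (default SD 2 HU).
The jitter truncation and the mask's safety margin inside the skull are
matched so that a noiseless phantom never presents out-of-range HU inside
the brain mask — cleaning deletes nothing on clean input.

Full nonlinear template normalisation is deliberately out of scope; its
surrogate is a rigid coarse-to-fine grid search (3 translations, 1
in-plane rotation) maximising normalized cross-correlation against a
feature-free template rendering, with a correlation floor that turns
structureless input into an explicit registration failure.

Joining averages voxels sampled by both sections and marks voxels sampled
by neither with NaN — never a fabricated HU value.  The cohort matrix is
flattened x-fastest (Fortran order) so column i means the same grid
coordinate for every subject.  Cleaning treats a cell as anomalous when
< 0 HU, > 200 HU or unsampled; voxels anomalous in ≥ 5 subjects are
deleted, rarer anomalies are imputed with the column mean over clean
subjects (unsampled join voxels fall under the same rule — one uniform
policy).  Global intensity correction is multiplicative scaling of each
subject's row to the pre-correction grand mean; a multiplicative rather
than additive correction preserves HU ratios and non-negativity.

## Weighted SVM

The classifier is a two-class soft-margin SVM whose dual box constraints
are per-subject: C_i = C · NIHSS_i / mean(NIHSS) (mean-normalized so the
overall regularisation scale is unchanged; zero-NIHSS subjects are floored
at 0.01 C rather than dropped).  Mean-normalized proportionality is a
declared reading of "severity-proportional contribution" — the constant of
proportionality is not otherwise identified.  The solver is SMO with
maximal-violating-pair working-set selection, lowest-index tie-breaks
(fully deterministic), bound-snapping to keep working-set membership
exact, and a pair-curvature floor so the indefinite tanh kernel yields
bounded descent steps under a finite iteration budget; non-convergence is
reported in model diagnostics, not raised.  With uniform caps the
formulation reduces exactly to the standard C-SVM, which is how it is
cross-checked (decision values match an independent reference solver to
1e-4, and a dense SLSQP dual QP on tiny sets).

The default pipeline kernel is linear.  The sigmoid
(tanh(scale·⟨u,v⟩ + offset)) kernel is implemented and selectable, but on
raw-HU image vectors the inner products are of order 10⁶, so at the
conventional scale 1 / offset −1 the kernel saturates to ±1 and the Gram
matrix degenerates; linear is the robust default for whole-image features,
with the sigmoid exercised at toy scale.  Whole-image features enter raw
(post intensity correction), with no per-voxel standardization; the
"manual" SVM — NIHSS, ischemia extent coded 0/1/2, hyperdense MCA 0/1 —
standardizes its three incommensurate columns, storing the affine
transform on the model.

Ablations: NO_NIHSS replaces the severity-proportional caps by uniform
ones; NO_BASE drops voxel columns sampled only by the brain-base section;
SINGLE_HEMISPHERE keeps the lesion-side half-grid per subject, mirroring
right-sided lesions onto left-hemisphere columns so all subjects share a
feature basis (columns whose mirror was deleted are excluded).

## Evaluation

Each SICH case is tested against 110 mutually distinct, uniformly drawn
9-foil sets (the draw scheme is a declared choice; only the count of
distinct combinations is fixed by the design), giving 1760 splits of
106/10 at the default composition.  Rank 1 = most negative distance;
rank and modal-rank ties break toward rank 1 — deterministic, and
conservative only in the sense of being documented.  The ROC uses ten
thresholds evenly spaced over the *pooled* distances of all splits
(per-split thresholds would not yield one curve per model), augmented
with (0,0) and (1,1) and integrated by trapezoid; on continuous scores
the coarse grid stays within ±0.1 of the exact Mann–Whitney AUC
(property-tested) and agrees exactly when the scores take ≤ 10 aligned
values.  Chance probabilities use exact integer binomial coefficients.
Model comparison is a paired bootstrap over SICH cases (resample cases,
recompute pooled AUC per model, two-sided tail of the difference); it is
a surrogate for an unspecified original procedure and is labelled as such
in the report output.

## Problem sizes and numerical choices

Desk-scale defaults are deliberate: grid 64 × 64 × 40 (≈ 37k brain-mask
voxels) instead of full 2-mm template resolution, and the heavier
property checks run at 32 × 32 × 20 with 16 + 100 cohorts, 12 foil sets
per case for the identified-count comparison, 8 for the null-AUC check,
over 10 generator seeds.  "Strong image-borne risk" is amplitude 2.0 (twice
the default feature contrast); the null condition is amplitude 0.  The
per-split SVM solves reuse one precomputed cohort Gram matrix, which is
what makes hundreds of splits cheap.  SMO tolerance defaults to 1e-3 on
the KKT gap; cleaning bounds are strict inequalities (a 0 HU or 200 HU
voxel is legal brain); the bisection for κ runs 200 halvings (exact to
float precision).

## What passing tests do and do not show

The phantom is a geometric stand-in, not anatomy: no gyri, no beam
hardening, no partial-volume effects, no real normalisation errors beyond
rigid jitter.  Passing the end-to-end checks shows the pipeline recovers
image-borne risk *when the generator's assumptions hold* (risk loading on
diffuse texture plus focal hypoattenuation, severity coupled to extent)
and shows no discrimination when images carry no signal; it says nothing
about real-cohort effect sizes, and the clinical AUC/identified-count
figures of the emulated study are not reproducible without its
(undeposited) data.  The univariate odds-ratio path and the κ
calibration, by contrast, are checked against published numeric anchors
directly.

## Known limitations

- Rater error is symmetric and independent across raters and features;
  real readers share systematic biases.
- The generator's case–control contrasts are approximate; only the NIHSS
  gap and rater-agreement targets are calibrated quantitatively.
- The modal-rank "identified" statistic is sensitive to foil-set count at
  desk scale (12 sets per case vs 110 in the full design).
- Sigmoid-kernel training on whole-image features requires a sensible
  scale choice by the user; the package does not auto-scale it.
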