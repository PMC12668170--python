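# Methods

`ventseg` re-implements, end to end and on synthetic data, a study design for
automated breath segmentation of mechanical-ventilator waveforms: a deep
segmentation model against two published rule-based baselines, evaluated by
tolerance-window event matching and by the downstream quantification of
patient–ventilator asynchronies (PVAs).

## Problem and data model

A ventilator produces two 50 Hz channels — airway pressure (cm H2O) and flow
(L/min).  Segmentation means locating two event types per breath at
single-sample resolution: the **inspiratory onset** (the machine begins
insufflation; flow turns positive) and the **expiratory onset** (the machine
cycles to expiration; flow turns negative).  Onsets are 0-based sample
indices; labels are one-hot at exactly one timestep, with no smearing.
Records are CSV (`time,pressure,flow[,insp_onset,exp_onset,breath_type]`)
with a strictly uniform 1/rate time step (checked to 1e-9 s).

## Segmentation model

A dual-head attention-gated 1-D U-Net maps a normalized 352-sample window
(7.04 s) of pressure and flow to per-timestep onset probabilities over the
central 176 samples (3.52 s, about one average breath).  Each window is
z-scored per channel (population SD; constant channels map to zeros).
Output spans tile a record without overlap; records are reflection-padded by
88 samples at the edges so border windows keep full input context (edge
behavior is a package choice — "central output" architectures leave it
open).

Architecture (defaults in `ModelConfig`): four encoder blocks of
conv(k=7)+LeakyReLU pairs with filter counts doubling from `base_filters`,
each followed by stride-2 max pooling; a bottleneck of dilated convolutions
(rates 1, 2, 4) with dropout 0.3; a decoder of stride-2 transposed
convolutions whose skip connections pass an additive attention gate (1×1
convs on skip and gating signal, summed, ReLU, 1×1 conv to one channel,
sigmoid, multiplied into the skip) before concatenation; then a center crop
to the output span and two task-specific heads (conv → layer norm → dropout
0.2 → position-wise dense with GELU → 1×1 conv → sigmoid).  The published
source names the component types but not the filter counts; all sizes are
configuration here, and no attempt is made to match the published parameter
count.

The network, its gradients and its optimizer are implemented on a small
in-package numpy autodiff (`ventseg.nn`) because no deep-learning framework
is available in the target environment; every operation's gradient is tested
against central finite differences.

## Loss and training

Training minimizes an uncertainty-weighted composite

    L_total = L_focal/(2σ₁²) + L_dice/(2σ₂²) + log σ₁ + log σ₂

with σ learned as log σ² (initialized 0).  The focal term,
−α(1−p_t)^γ log p_t (α = 0.25, γ = 2), addresses the extreme class imbalance
(about 0.7 % of output samples are onsets); the dice term,
1 − (2Σp·g+ε)/(Σp+Σg+ε), rewards temporal overlap; the log terms keep the σ
from diverging.  By default one σ weighs each loss *term*, as the equation
reads; a `per_head_sigma` flag selects the alternative reading (one σ per
task head over focal+dice), since the prose "balance the contributions of
the two outputs" admits both.  For fixed component losses the stationary
point is σ² = L, which a test verifies by gradient descent.

Optimization: He initialization, AdamW (lr 5e-4, decoupled weight decay 1e-2
on weight matrices only — the decay magnitude is not published), batch 32,
early stopping on validation loss (patience 10, min delta 1e-4), restoring
the best validation epoch.  All randomness (init, shuffling, dropout) flows
from one seed; training is bitwise reproducible.  Probabilities are clipped
to [1e-7, 1−1e-7] before logarithms.

Inference stitches the non-overlapping output spans into full-length traces
and post-processes: local maxima strictly above 0.5 are candidates;
candidates of the same type closer than 5 samples (0.1 s, the evaluation
tolerance — the published debounce width is not stated) are merged keeping
the highest; between consecutive inspiratory onsets only the
highest-probability expiratory candidate survives, and expiratory candidates
in the open segments before the first / after the last inspiratory onset are
kept only if unique.  One expiratory onset may therefore precede the first
inspiratory onset (a breath truncated by the record start); the annotation
validator allows exactly one such leading event.

## Heuristic baselines

Both baselines are reproduced from their textual descriptions (the original
source code is unavailable), with the ambiguous phrases pinned as
parameters:

* **Zero crossing** — inspiratory onset at every negative→positive flow
  crossing, expiratory at every positive→negative crossing; deliberately no
  debouncing or pairing.  A crossing belongs to the first sample on the new
  sign's side; exact zeros count as non-negative.
* **Derivative backtracking** — inspiration: from each run of flow
  > 12 L/min, step backward while the first difference of flow keeps its
  sign and magnitude above `derivative_eps` (default 0.5 L/min per sample);
  "the derivative began to change" is operationalized as a sign change or a
  drop below that plateau tolerance.  Expiration: per inspiratory interval,
  the first sample < −5 L/min whose following 2 samples (25 ms at 50 Hz,
  rounded up) stay negative, backtracked to the nearest earlier sample with
  flow ≥ 0 or a plateaued derivative; at most one per interval.
* **Reference expiratory candidates** — the zero crossing after the
  positive-flow lobe with the largest trapezoidal area in each breath
  interval (the rule used to seed a human-reviewed reference standard).

## Synthetic cohort generator

Because the clinical dataset is not public, the generator emulates its
published structure: Ti ~ U(0.75, 0.95) s, normal Te ~ U(1.1, 2.8) s, peak
flow ~ U(50, 85) L/min, peak pressure ~ U(20, 35) cm H2O, PEEP ~ U(4, 6),
linearly decelerating inspiratory flow (tidal volumes then land in the
published 280–510 mL IQR band), and an exponential expiratory decay (time
constant Te/3) rescaled so the exhaled volume equals `exhale_fraction` × the
inhaled volume.  Records begin with a 1 s strictly-negative run-in so the
first onset is a genuine crossing.  Breath types are drawn i.i.d.: double
triggers (Te ~ U(0.12, 0.25) s, exhale fraction U(0.05, 0.20) — the next
drawn breath then starts immediately, forming the second insufflation of the
pair), stacked breaths (Te ~ U(0.5, 1.6) s, exhale fraction U(0.40, 0.85)),
artifact breaths (a 0.3 s cough-like 8–12 Hz flow burst during expiration),
and normal breaths (exhale fraction ≥ 0.97).  The planted parameters keep at
least 0.05 margin from every decision boundary of the asynchrony
definitions.  Defaults follow the published cohort where a number exists
(294 breaths/patient, 28 % asynchrony, 6 % artifacts); the split between
double triggering and stacking within the asynchronous fraction is exposed
as a parameter because the source reports it only for one subset.

Noise is added only after ground-truth onsets are recorded: white Gaussian
noise per channel (defaults 1 L/min flow, 0.5 cm H2O pressure) plus slow
sinusoidal baseline wander.  The wander default is deliberately small
(0.2 per channel): a slow additive flow offset integrates into tidal-volume
error (±1 L/min shifts measured TVe/TVi by up to ~0.15 over a long
expiration), which makes the volumetric asynchrony definitions ill-posed
regardless of segmentation quality; 0.2 L/min keeps drift-induced ratio
error under 0.04, inside the 0.05 margins the definitions rely on.  Real
flow channels are auto-zeroed by the ventilator, so small flow drift is also
the physically faithful choice.

What a green test on this generator does **not** establish: performance on
real waveforms with mode changes, patient effort, leaks, condensation
artifacts or annotation noise.  The generator has no lung mechanics (no
resistance/compliance ODEs) and no esophageal-pressure channel; asynchrony
prevalences are planted, not emergent.

## Evaluation protocol

Predicted onsets are matched one-to-one to reference onsets, exactly
(tolerance 0) and within ±0.1 s (5 samples, inclusive).  The default matcher
is greedy by increasing |offset| with ties broken toward the earlier
reference event; an optimal-assignment mode (max cardinality, then minimum
total offset, Hungarian algorithm) is provided as a cross-check.  When
reference events are separated by more than twice the tolerance — always
true of breath onsets, which are ≥ ~50 samples apart at tolerance 5 — the
bipartite match graph is a disjoint union of stars and the two matchers
provably coincide; a test documents the adversarial counterexample
(reference [0, 2], predicted [2, 4], tolerance 2) where greedy drops a pair.
Precision, recall and F1 are reported pooled and stratified by breath type
(normal / PVA / artifact), each event assigned to the stratum of its
enclosing reference breath so per-stratum counts partition the pooled
counts.  The sample-size helper uses the unpooled two-sample normal
approximation, which reproduces the published minimum of 291 breaths for
detecting 70 %→80 % accurate segmentation at 80 % power; the pooled (Fleiss)
variant (294) is behind a flag.

## Asynchrony quantification

A breath is the interval between consecutive inspiratory onsets.  Features:
Ti, Te from the onsets; TVi/TVe by trapezoidal integration of the
positive/negative part of flow over the respective phase (L/min → mL/s,
×1000/60).  Definitions: double trigger (1) Te < 50 % of the mean Ti — the
mean is taken over the analyzed cohort, since the source does not state the
scope, with a per-patient option; (2) Te ≤ 0.3 s and (TVe/TVi < 0.25 or
TVe/TVi < 0.50 with TVe < 100 mL); stacked: Te > 0.3 s and TVe/TVi < 0.9.
Breaths without a detected expiratory onset or successor are excluded and
counted.  Frequencies from different segmentation sources are compared by
Pearson chi-squared on 2×2 tables without continuity correction (the source
names only "chi-squared tests"); Welch t-tests serve continuous features.

## Numerical and design choices

* Population (divide-by-n) SD in normalization; one convention had to be
  pinned for reproducibility.
* `window_samples` requires duration × rate integral to 1e-9.
* Threshold comparisons follow the printed inequalities exactly (strict
  where printed strict: Te < 0.5·meanTi, TVe/TVi < 0.25/0.5/0.9; inclusive
  Te ≤ 0.3 s; event threshold strictly > 0.5; matching tolerance inclusive).
* Grad-CAM differentiates the pre-sigmoid logit (standard practice; the
  source does not say logit vs probability) with respect to the final
  decoder convolution before the center crop, the last *shared* trunk layer;
  channel weights are time-averaged gradients, the rectified weighted sum is
  linearly interpolated to the input length and max-normalized.
* The sigma-weighted loss can drive the total below zero late in training
  (the log regularizers are unbounded below); early stopping on validation
  loss still selects a well-calibrated epoch because train and validation
  move together on synthetic data.

## Known limitations

* Pure-numpy training limits practical model sizes; the shipped defaults
  (base 8–32 filters) train in minutes on one CPU but are far smaller than a
  GPU-scale model.  The published headline F1 values on the clinical cohort
  are not reproducible (data unavailable) and are not asserted anywhere;
  tests assert the qualitative ordering (model > heuristics in noise) and
  absolute recovery on synthetic data.
* Greedy matching is suboptimal on event streams denser than twice the
  tolerance; use `method="optimal"` there.
* The volumetric asynchrony definitions are sensitive to flow-baseline
  drift; with drift beyond ~0.5 L/min their labels stop being identifiable
  even from perfect onsets.
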