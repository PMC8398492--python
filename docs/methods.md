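# Methods

## Pipeline overview

The package classifies diagnostic groups from resting-state BOLD ROI time
series in four stages: cohort harmonisation, spectral node selection,
pairwise wavelet coherence, and CNN classification of the rendered coherence
scalograms. Each stage is an independent module with the orchestration in
`boldwct.pipeline`.

## Cohort harmonisation

Multi-site cohorts arrive with unequal scan lengths and group sizes.
Recordings are truncated to the shortest common length, keeping the leading
segment — the earliest samples are the ones guaranteed to exist at every
site, and truncation must not alter retained values. Groups are then
down-sampled to the smallest group size by seeded uniform draws without
replacement, preserving subject order. Both operations are idempotent.

## Node selection

Per subject, the Welch PSD of every node is estimated with 64-sample Hamming
segments at 50% overlap and per-segment mean detrending — conventional
settings for ~145-point series, configurable via `WelchConfig`. All PSD
values of one subject are z-scored **jointly over nodes × frequencies**, then
averaged over frequency (DC excluded) to one score per node. The joint
z-score is the normalisation axis chosen here: it removes any affine
per-subject distortion (site gain/offset) while preserving between-node
contrasts; normalising per node instead would erase exactly the contrast the
ANOVA needs. A per-band restriction (e.g. 0.01–0.1 Hz) is available.

Each node's scores are compared across groups with a one-way fixed-effects
ANOVA (F on (k−1, N−k) degrees of freedom). Degenerate nodes — all
observations identical — are assigned p = 1 (uninformative); zero
within-group variance with distinct means gives p = 0. Nodes with p ≤ α
(default 0.05, raw — no multiple-testing correction; pass a corrected α
explicitly if desired) are ranked ascending by p with ties broken by node
index; the first is the seed node for the coherence stage. The ranking is
invariant to subject order and to global signal rescaling.

## Wavelet coherence

The CWT uses a complex Morlet mother wavelet with dimensionless centre
frequency ω₀ = 6, evaluated in the Fourier domain on a zero-padded signal
(next power of two ≥ 2N) with L2 (1/√a) normalisation. Scales are log-spaced
at 12 voices per octave over Fourier periods from 2·TR (Nyquist) to a
quarter of the record length. ω₀ = 6 pins the Fourier-period/scale ratio
4π/(ω₀+√(2+ω₀²)) ≈ 1.03, making scale readable as period; it is also the
conventional choice that balances time and frequency resolution for slow
physiological signals. A cone-of-influence (e-folding boundary) is stored
per time point but not masked in rendered images.

Squared coherence is |S(W_x* W_y)|² / (S|W_x|² · S|W_y|²), clipped to [0, 1]
after floating point. The smoothing operator S is Gaussian in time with SD
equal to the scale (factor 1.0, configurable) and a boxcar spanning 0.6
decades of scale. Without smoothing the ratio is identically 1 — the
degeneracy is exposed as a diagnostic mode (`smoothing_enabled=False`) and
asserted in tests; smoothing is what makes coherence an estimator.
Self-coherence is 1 by construction, coherence is symmetric in its
arguments, and any positive smoothing kernel applied identically to
numerator and denominator keeps values within [0, 1] (Cauchy–Schwarz).
Constant signals are rejected (coherence undefined).

Maps are rendered deterministically: bilinear resampling on a (log-period ×
time) grid to the configured raster (default 224 × 224, top row = shortest
period), then a fixed viridis palette anchored to [0, 1]. The palette,
magnitude-only colouring (no phase arrows), and unmasked cone of influence
are explicit rendering choices recorded in `CoherenceConfig`.

## Synthetic cohorts

Each node signal is a sum of three sinusoids with random frequencies in
0.01–0.1 Hz (the resting-state band at TR = 2 s) and random phases, plus
white Gaussian noise (SD 0.5 against a per-sinusoid amplitude of 1). Two
group effects are planted:

* the planted node's oscillation amplitude is multiplied by the group's
  power factor (defaults 1.6 / 1.4 / 1.2 / 1.0 for ASD / APD / PDD-NOS / NC,
  encoding a power ordering with highest in ASD and lowest in controls);
* partner nodes mix the planted node's components with weight c and private
  components with weight √(1−c²) (defaults c = 0.9 / 0.7 / 0.5 / 0.1), so
  band coherence to the planted node is ≈ c² while the partner's marginal
  power is group-independent — coupling and power effects are orthogonal by
  construction.

Site heterogeneity is a linear gain and offset applied last (defaults: four
sites, gains 0.85–1.2, offsets −4 to 6), which is the simplest mechanism
that makes the PSD normalisation consequential. Per-subject random streams
derive deterministically from (master seed, site, group, within-index), so
identical specs are bit-identical and subject sets are extendable.

No quantitative subtype effect sizes exist to emulate; the defaults are
chosen for testability. The generator omits hemodynamic response shape,
physiological and motion noise, scanner drift, and inter-subject anatomical
variability — passing tests demonstrate that the pipeline detects the
*kind* of structure it targets (group-dependent spectral power and phase
coupling), not that real cohorts carry effects of this size.

## Classifier

Three blocks of [3×3 same-padding convolution → ReLU → 2×2 max pool], then
flatten and a dense softmax over 2 or 4 classes. Default filter counts
(8, 16, 32) keep CPU training practical; only the three-block shape is
fixed. Weights are He-initialised from a seeded generator; training shuffles
with the same generator, so runs are bit-reproducible. Optimizers: Adam
(β = 0.9/0.999), SGD with momentum 0.9, RMSprop with decay 0.9 — momentum
and decay are conventional defaults. Inputs are pixel values in [0, 1].
The implementation is plain NumPy (im2col-free: nine shifted matrix
products per convolution), which is why determinism is exact.

## Evaluation

Per-class metrics follow the standard confusion-matrix formulas, reported in
percent and rounded to one decimal in formatted reports. Undefined ratios
(0/0) are reported as 0 and flagged. Multi-class reports binarise each class
one-vs-rest and macro-average without support weighting; zero-support
classes are flagged and either enter as zeros or are excluded, per
configuration. Split protocols: stratified hold-out with largest-remainder
allocation (sizes within ±1 of exact ratios), stratified round-robin
k-fold, and leave-one-site-out where only sites containing every required
class are eligible test sites (ineligible sites always remain in training).
Splits default to image level, mirroring per-image dataset counts; subject-
level splitting keeps all of a subject's images in one partition and is the
right choice when subject-level generalisation is the claim — image-level
splits of multi-image subjects can leak subject identity, and the pipeline
logs a warning when that applies. Cross-validated tables report per-round
rows plus a mean ± SD row computed from the rounded rows (matching how
printed tables are aggregated).

## Numerical choices

* ANOVA degeneracy threshold: sums of squares below ~100·ε·N·scale² are
  treated as zero.
* Coherence denominator guarded by the smallest positive float; values
  clipped to [0, 1].
* Smoothing kernels are edge-renormalised (nearest-mode), so constants are
  preserved exactly.
* Holdout/k-fold tie-breaks: largest-remainder fractions resolved in
  partition order; ranking ties by node index; argmax prediction ties by
  class order.

## Problem sizes

Statistical suites run at reduced scale chosen to make each property
decisive yet quick: planted-node recovery over 20 cohorts of 4 × 12 subjects
with 8 nodes; ANOVA calibration against a 10,000-draw permutation oracle on
5–6 observations per group; type-I-error calibration over 200 null cohorts;
end-to-end experiments on 12-node cohorts with 32 × 32 scalograms, a
(4, 8, 16)-filter network and 8 epochs. These sizes are the package's test
conditions; the full-scale defaults (116 nodes, 224 × 224, (8, 16, 32)
filters, 20 epochs) remain the configured defaults throughout.

## Known limitations

* The CNN is CPU-oriented; full-scale training (thousands of 224 × 224
  images) is slow compared to GPU frameworks.
* No coherence significance testing against red-noise nulls and no
  phase-lag decomposition; maps feed the classifier as magnitudes only.
* The synthetic generator's realism limits are listed above; conclusions
  about real multi-site cohorts require real data.
* Macro-averaging with absent classes is configuration-dependent (zeros vs.
  excluded); reports flag which was used.
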