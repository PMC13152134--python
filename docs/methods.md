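# Methods note

This note records the model behind each audit, the parameter defaults and
the reasoning for them, what the synthetic generator does and does not
emulate, and the numerical conventions. Empirical behaviour quoted here is
exactly what the test suite and `scripts/acceptance.py` compute.

## 1. Occlusion masking ("eclipse")

An image of height `H` and width `W` is masked by the ellipse centred at
pixel-centre coordinates `((W−1)/2, (H−1)/2)` with semi-axes
`(e·W/2, e·H/2)` for extent `e ∈ [0, 1]`; pixels whose centres satisfy the
ellipse inequality **inclusively** are set to black in all channels. The
inclusive boundary makes masks nested: the masked set at a smaller extent is
a subset of the masked set at any larger extent, and `e = 0` is exactly the
identity. At `e = 1` the masked fraction converges to π/4 as resolution
grows (0.78542 on 512×512, i.e. within 0.5% of π/4).

The audit refits the classifier from scratch at each extent and evaluates on
images masked at the *same* extent, so train and evaluation distributions
match and any residual AUC reflects information outside the mask.

## 2. Color counterfactual

**HSV conversion** follows the standard hexcone model with hue in degrees
`[0, 360)` and saturation/value on the 0–255 scale; achromatic pixels get
hue 0. The implementation is vectorised and matches `colorsys` per pixel to
~1e-13. Per-image features are the mean and **population** standard
deviation of each channel (`hue_mean, hue_std, sat_mean, sat_std, val_mean,
val_std`); hue statistics are linear (not circular) — adequate for otoscopic
imagery, which occupies a narrow warm hue range, but a documented limitation
for hue distributions wrapping 0°/360°. An optional field-of-view mask
(V > 10) restricts statistics to non-black pixels.

**Logistic regression** is unpenalised maximum likelihood via
iteratively-reweighted least squares (Newton) with step-halving to keep the
log-likelihood monotone, convergence at 1e-8 change in coefficients, at most
100 iterations. The covariance is the inverse observed Fisher information;
odds-ratio CIs are Wald intervals `exp(β ± z·SE)`. Perfect separation is
detected (non-convergence, or fitted probabilities collapsing onto the
labels) and reported via `SeparationWarning` with `converged=False`;
odds ratios are refused for non-converged fits. Exactly collinear feature
sets raise `CollinearityError`, naming the features spanning the null space.
Coefficients and CIs match an independent Newton–Raphson maximiser
(statsmodels) to 1e-6 in the tests; 95% Wald CI coverage is empirically
0.93–0.97 at n = 200.

Feature sets: `hsv6` (all six) and `sat_std_only` (saturation spread alone),
the single feature that most cleanly isolates a saturation artifact.

## 3. ROC statistics

AUC is the Mann–Whitney statistic with the ½ tie convention, computed from
the rank-sum identity so that it equals exhaustive pair counting
bit-for-bit. DeLong structural components are midrank placements; the AUC
variance is `var(V₁₀)/m + var(V₀₁)/n` with `ddof=1`, the CI is the normal
approximation truncated to [0, 1]. The paired test uses the covariance of
placement differences; the unpaired test uses
`z = (A₁ − A₂)/√(v₁ + v₂)` against the **normal** reference distribution
(some implementations use a Welch–Satterthwaite t reference; the statistic
is identical — on a frozen fixture it matches R's `pROC` to 5 decimals — and
at audit sample sizes the difference is negligible; empirical one-sided
type-I error is 0.035–0.065 at nominal 0.05). Zero-variance cases (perfect
separation, constant scores) emit `DegenerateVarianceWarning` and return a
point CI, or p = 1/0 for equal/unequal AUCs, rather than failing.

## 4. Embeddings, duplicates, styles

The default embedding concatenates per-channel 32-bin histograms (96
dimensions, counts normalised by pixel count) with a 16×16 bilinearly
downsampled luminance map (256 dimensions, scaled by 1/255), then
L2-normalises (352 dimensions). It is deterministic, training-free, and
sensitive to exactly what duplicate/style audits need: global color
distribution and coarse spatial layout. A trainable embedder can be plugged
in via `crossfold_embeddings(..., embedder_factory=...)`, in which case each
image is embedded by the folds that did not train on it (stratified k-fold,
default k = 5) and the fold embeddings are averaged and renormalised — the
embedding of an image never depends on a model that saw it.

Clustering is single linkage: connected components of the graph joining
pairs with cosine distance ≤ α. Two thresholds with distinct roles:

- `alpha_dup = 0.003` — near-duplicate threshold. Calibrated on the
  generator: exact and sub-pixel-jittered copies land below 0.003 while the
  closest distinct renders sit at ≈ 0.005–0.006. Recovery of planted
  duplicates is exact (precision = recall = 1.0) for duplicate jitter ≤ 0.5
  (noise-only, no integer translation); integer-pixel translations move
  histogram and luminance cells and are not guaranteed to be recovered.
- `alpha_style = 0.06` — stylistic-cluster threshold. Within-style
  nearest-neighbour distances max out near 0.018 while between-style
  distances start near 0.15, so 0.06 merges each framing style into one
  component without bridging styles.

The redundancy report counts duplicate sets, redundant images
(Σ(size − 1)), and partitions the internal-validation split into images
with/without a training-set duplicate; the leakage audit compares the
configured classifier's AUC on the two partitions with a one-sided unpaired
DeLong test. Style clusters of at least `min_size = 20` images are flagged
when label purity ≥ 0.9 with a Fisher exact test against the remaining
images.

## 5. Synthetic generator

Each image is a stylised otoscopic frame at 64×64 (configurable, minimum
32×32): a dark warm-textured border, a bright circular field of view, a
canal annulus with radial streaks, and a central membrane disk (55% of the
field radius) with a specular highlight. Two framing styles emulate
site-specific acquisition: Style I (full field, radius 0.48·min(H, W),
centred) and Style II (zoomed, radius 0.34, offset (0.06, 0.10)); per-image
framing jitter (radius ×U(0.95, 1.05), centre ±3%) and a lognormal(0, 0.35)
saturation-spread factor provide benign within-site variability, without
which renders are so uniform that any two images look like near-duplicates.

Planted effects, each driven by an independent substream of a
`SeedSequence` so toggling one bias never changes another:

- **Clinical signal** (`clinical_contrast`, default 80 intensity levels):
  abnormal images get a blob (radius 4–6% of min dimension, offset ≤ 8%)
  wholly inside the extent-0.5 ellipse, where the G and B channels drop by
  the contrast — a reddened lesion on the membrane, removable by occlusion.
  The contrast is chosen so the default classifier separates the classes
  (internal AUC ≥ 0.9 at n = 500/class) while full occlusion returns it to
  chance; both checked by simulation in the acceptance tests.
- **Saturation bias** (`saturation_bias`): abnormal images have their
  saturation spread scaled by (1 + bias) about the image mean — a global
  artifact that survives occlusion. Bias 1.0 yields `sat_std_only` AUCs
  ≈ 0.9 internally and externally without being degenerate (no separation).
- **Style bias** (`style_bias_prob`): probability that the framing style is
  assigned by label rather than at random.
- **Duplicates** (`duplicate_fraction`, `duplicate_jitter`,
  `leak_across_split`): selected sources get 1–3 copies, shifted by up to
  ⌊jitter⌋ pixels (edge-replicate) plus Gaussian noise σ = jitter; with
  leakage on, the first copy goes to the opposite split.

The generator emulates *statistical* structure — label-artifact
correlations, site styles, redundancy — not anatomy: there is no malleus,
no cone of light, no pathology taxonomy, and renders are far simpler than
real otoscopy. It exists to give the audits a ground truth, not to train
deployable models.

Sample sizes used in the self-checks follow from binomial arithmetic, not
tuning: the null-band check (AUC ∈ [0.40, 0.60] with all biases off) uses
800/class so the band is ≳3 standard deviations of a null AUC at the
resulting validation size; the signal and artifact checks use 500 and 400
per class for the same reason at their thresholds.

## 6. Pipeline and determinism

`run_all` executes the three audits, isolates stage failures, and (when
`out_dir` is set) writes CSV tables, `report.json`, and a bundle manifest
with the package version, seed, config, and SHA-256 digests of input
manifests. Everything is deterministic given the config seed: classifiers
are seeded, splits use `numpy.random.default_rng(seed)`, and re-running a
config writes byte-identical files.

Default classifiers: `logistic_on_embedding` — scikit-learn logistic
regression (lbfgs, C = 10) on the default embedding; the weak penalty lets
it latch onto subtle peripheral artifacts the way an over-parameterised
network would, which is the behaviour the occlusion audit must be able to
expose. `nearest_neighbor` — a 1-NN scorer that memorises training images,
included to demonstrate duplicate-leakage inflation. Any object with
`fit(images, labels)` / `score(images)` can be registered.

`stratified_split` holds out `max(1, floor(f·n + 0.5))` images per class
(default f = 0.2); `by_patient=True` groups by `patient_id` so no patient
straddles the split — recommended whenever patient identifiers exist.

## 7. Limitations

- Linear hue statistics; circular statistics would be needed for hue
  distributions spanning the 0°/360° wrap.
- The default embedding is translation- and crop-sensitive by design;
  duplicates created by large geometric edits need a trainable embedder.
- Wald/DeLong inference is asymptotic; very small validation splits
  (< ~20 per class) give unreliable intervals, and degenerate cases are
  reported via warnings rather than corrected.
- The generator's simplicity means audit thresholds (`alpha_dup`,
  `alpha_style`) calibrated on it should be re-examined on real imagery,
  e.g. by inspecting the cosine-distance histogram for a gap.
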