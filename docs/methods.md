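# Methods

## The analysis problem

A holographic cytometer produces a reconstructed phase image φ(x, y)
(radians) per cell; the optical path length per pixel is OPL = φ·λ/(2π) with
λ = 640 nm by default. Sickle cell disease (SCD) deforms only a fraction of a
patient's red blood cells; the rest are morphologically normal. Donor-status
labels at the cell level are therefore heavily noisy, and the package's core
procedure — selective-search refinement — replaces them with an automatically
constructed, nearly pure "critically sickled" training set before any
classifier is fit.

## Morphometry

Twenty-five parameters are extracted per cell:

* **Mask shape (10)** — area (pixel count × pitch²), perimeter, circularity
  4πA/P², eccentricity, elongation ratio, solidity, extent, equivalent
  diameter, bounding-box aspect ratio, perimeter/area. Eccentricity is the
  inter-focal half-distance over the semi-major axis of the second-moment
  ellipse (0 = circle); elongation is the major/minor axis ratio. Both are
  computed from the mask's second central moments via
  `skimage.measure.regionprops`. Perimeter uses the Crofton estimator, which
  is noticeably less rasterization-noisy than chain-code length at the
  ~25-px cell radii this pipeline works at.
* **Phase statistics (9)** — mean, max, min, sd, median, 25th/75th
  percentiles, skewness and excess kurtosis of masked phase values. Moments
  use the biased (population) convention; a constant patch has skewness and
  kurtosis defined as 0 so every feature is finite.
* **OPL (3)** — integrated OPL (a dry-mass/volume surrogate, µm³), mean OPL,
  and the mean of the top quartile of per-pixel OPL ("top-25% OPL"; the top
  ⌈n/4⌉ values, a definitional choice since only the name of the quantity is
  standard).
* **Phase gradients (3)** — max, mean and sd of |∇φ| in rad/µm, central
  differences (one-sided at the image border). Gradient statistics are taken
  over the mask eroded by one pixel: boundary pixels see the step to the
  background, which would otherwise dominate every cell's gradient figures
  with a segmentation artifact rather than intracellular structure. If
  erosion empties the mask the full mask is used.

QC rules partition the feature table, each excluded cell annotated with the
first rule it violated. Defaults: normal cells with mean phase < 0.4 rad and
SCD cells < 0.3 rad are excluded (low-signal cutoffs, class-specific because
sickled cells are legitimately dimmer on average); area ∈ [12, 90] µm² and
solidity ≥ 0.85 remove debris and clumps (values are this package's
defaults; all rules are configurable).

## Selective search (training-set refinement)

For each parameter and each tail direction, candidate thresholds are the
sorted unique pooled values; the tail is closed (ties included). With
population sizes N_s (SCD) and N_n (normal) and tail counts n_s(t), n_n(t),
the smoothed population-fraction ratio is

    r(t) = [n_s(t)/N_s] / [(n_n(t)+c)/(N_n+c)],   c = 1 by default.

The pseudo-count c prevents single-cell tails from qualifying through an
empty normal tail. Among thresholds with r(t) ≥ 21 the most inclusive
(maximal n_s) is returned — high selectivity while keeping a usable diseased
cell count. The refined SCD set is the union of all qualifying tails (each
cell once, with provenance recording which criteria selected it); an
equal-size uniform random draw of normal cells balances it. If the union is
smaller than `min_refined_size` (default 5000) a warning is attached, since
downstream models benefit from several thousand training cells.

Two consequences of the most-inclusive rule are worth knowing. First, each
criterion's threshold always advances into the shared (non-sickled) region
until the normal tail has absorbed about f_crit·N_n/ratio cells, so a single
criterion's tail is ~96% pure at the default study conditions, never 100%.
Second, count fluctuations let the threshold overshoot that point by a
couple of standard deviations. The union over ~20 criteria therefore has
purity noticeably below the per-criterion figure unless the criteria select
consistent cell sets — which they do when deformation expresses itself
consistently across parameters (see the generator below).

## Classifiers

Both model families share one protocol: `repeats` (default 5) stratified
90/10 train/validation splits; per-split sensitivity (SCD positive),
specificity, accuracy; means ± sd across repeats; ROC/AUC pooled over the
validation scores; final refit on all data. The identity
accuracy = (sens·P + spec·N)/(P+N) holds exactly per split.

* **LR** — scikit-learn logistic regression behind a standardizer fit on the
  training split only, with mild L2 (C = 1); unregularized fits diverge on
  the linearly separable refined data.
* **CNN** — a compact numpy network: 3 × [3×3 conv (pad 1) → ReLU → 2×2
  average pool] with 16/32/64 channels, global average pooling, single-logit
  head; Adam on binary cross-entropy, default 6 epochs, batch 64, lr 1e-3,
  float32. Inputs are phase crops block-averaged to 32×32 and scaled to
  [0, 1] by a fixed cap (2.5 rad). Convolution is im2col + BLAS matmul;
  training is a pure function of its seeds and bit-reproducible. Average
  pooling (not max) keeps the backward pass trivial and deterministic.

Hard labels use score > 0.5 strictly, so an exact 0.5 is called normal. ROC
is swept over all score thresholds and AUC computed by the trapezoidal rule,
which equals the tie-aware pairwise-concordance probability; the test suite
checks that identity against a brute-force oracle.

## Decision model

A sample's cells are scored, the SCD percentage computed, and the sample
called SCD iff that percentage strictly exceeds 8%. The 8–25% range is
additionally reported as `severity_band_position` = (pct − 8)/(25 − 8),
clipped below at 0 and open above 1 (severely affected samples can exceed
the band).

## Synthetic data generator

The generator replaces unavailable patient data and defines the study
conditions the tests run under.

**Cell geometry.** A normal cell is a biconcave disc:
φ(r) = peak · max(0, 1 − (r/R)²)^½ · (1 − d·exp(−(2r/R)²)), stretched along
one axis by the elongation factor e (area-preserving semi-axes R√e, R/√e),
with d the central dimple depth. A critically sickled cell is the same
elongated profile with no dimple and the centreline bent by a quadratic
displacement proportional to `curvature`. Masks are pixels whose noiseless
phase exceeds 5% of the peak; Gaussian background noise (sd 0.01 rad) is
added everywhere.

**Population structure.** Three subtypes on a single deformation-severity
axis: `normal_like`, `mildly_deformed`, `critically_sickled`. SCD samples
default to a 0.50/0.35/0.15 mixture; normal samples contain no critically
sickled cells and a comparable benign mixture (0.55/0.45), so the two
populations' histograms overlap except in the tails. Within each subtype a
latent severity factor (loading 1.0 for the shared subtypes, 0.7 for the
sickled continuum) couples elongation, curvature, peak phase, dimple loss
and (negatively) radius: a cell unusually deformed in one descriptor is
deformed in all of them. This coupling is what makes the ~20 tail criteria
select consistent cell sets, and its weaker value on the sickled continuum
leaves genuinely ambiguous low-severity sickled cells whose elongation
overlaps normal support — the cells a confounded classifier misranks.

Three deliberate realism ingredients shape what the refinement and the
ALL-vs-SEL comparison can show:

1. **Bulk confound.** SCD samples' shared subtypes have peak phase shifted by
   −0.05 rad (mean only; the truncation bounds stay common to both donor
   groups, so neither population has a support region the other cannot
   reach). The shift is individually invisible against the ~0.15 rad spread
   but statistically obvious at population scale — exactly the "significant
   at the population level, useless at the cell level" structure that makes
   unrefined training misleading.
2. **Dry-mass neutrality.** Critically sickled cells keep the shared range of
   integrated OPL (radius and peak phase chosen so r²·peak matches; HbS
   polymerization deforms the cell but does not change its hemoglobin
   content). Without this the dry-mass tails leak noise-ordered cells into
   the refined set.
3. **Acquisition-run signature.** Each sample draws one residual background
   phase level (sd 0.04 rad) added to background pixels only; cell pixels
   are referenced to the local background annulus during reconstruction, so
   none of the 25 features sees it. Image-based models do see it: trained on
   donor labels with two donors per class, the unrefined CNN shortcuts on
   the background level and fails on unseen test samples, while the refined
   CNN's morphology signal dominates. Feature-based models are untouched.

**Default study.** Two SCD training samples (12k cells), two normal training
samples (8k + 10k), five test samples of 2k cells (three normal, one SCD with
the default 15% sickled fraction, one severe SCD with 26%); ~50k cells total,
per-sample counts in the 10⁴ range. A `scale` knob shrinks every count
proportionally for quick runs; tests and the acceptance script use scales
between 0.02 and 1.0 depending on what the check needs.

**What the generator does not model.** Holograms, speckle or coherent noise,
flow or motion blur, cell clumps and debris (the QC rules are exercised on
constructed fixtures instead), staging/focus errors, donor-to-donor
biological variability beyond the acquisition signature, and sickle cell
trait. Passing tests demonstrate that the chain — tail search, union/balance
logic, training protocol, decision rule — behaves correctly on data with the
assumed statistical structure; they say nothing about accuracy on real
patient images.

## Numerical choices and edge cases

* Candidate thresholds are data values only; the closed-tail convention makes
  the search exact on ties (verified against exhaustive enumeration).
* Degenerate masks: a one-pixel-wide mask reports elongation = pixel count;
  eccentricity is clipped strictly below 1. Constant-phase cells get
  skewness/kurtosis 0. An empty mask raises an unsegmentable-cell error.
* Shape-parameter distributions are mean/sd-parameterized normals clipped to
  [lo, hi]; clipping (rather than rejection) keeps draws a fixed number of
  RNG calls, which makes every sample bit-reproducible from its seed.
* The multinomial subtype counts and the per-cell parameter draws share one
  `numpy` Generator per sample, so a sample is fully determined by
  (population config, seed).
* Stratified splits use `train_test_split(stratify=...)` with per-repeat
  seeds `seed + i`; all derived seeds are reduced mod 2³¹−1.

## Problem sizes used by the test suite

Unit tests run on tens-to-hundreds of cells. The acceptance tests use the
full default study (five replicates, seeds 1–5) for refinement purity,
recovery and the LR refinement benefit, and a half-scale study with 2 × 2000
training images for the CNN benefit — sizes chosen so the whole suite
completes in well under half an hour on a single core while still exercising
the full-scale statistical behaviour of the tail search (whose contamination
properties are scale-dependent through the pseudo-count and threshold
overshoot).

## Known limitations

* The 21:1 ratio and the 8/25% decision bounds are fixed domain constants,
  not fitted quantities; no automatic tuning is provided by design.
* Only axis-aligned single-parameter criteria are searched; joint
  (multi-parameter) criteria are out of scope.
* The CNN is a minimal reference implementation: no augmentation, no
  early stopping, no GPU path. It is adequate for the refinement-benefit
  comparison, not a production classifier.
* Sample-level calls assume cells are exchangeable within a sample; no
  within-sample batch correction is attempted.
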