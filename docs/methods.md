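# Methods

## The surrogate model

gridlime explains a single prediction of a black-box classifier
f : image → class probabilities by a local linear surrogate over segment
occlusions. With the image partitioned into K segments, a perturbation
z ∈ {0,1}^K keeps segment j where z_j = 1 and replaces it with black
where z_j = 0. The surrogate is the ordinary least-squares fit

    f_c(x ⊙ z) ≈ b + Σ_j w_j z_j

over N sampled perturbations, fitted separately per class c. The
perturbation law is i.i.d. Bernoulli(½) per segment — the
maximum-information design for estimating main effects on the cube — with
row 0 reserved for the all-ones (unperturbed) instance so the original
prediction is always in the fitting set. Whether the nominal sample count
includes the unperturbed instance is a convention; here it does.

The default surrogate is deliberately plain: no proximity kernel, no
ridge penalty, no feature selection. A Bernoulli(½) design at N = 10,000
is well conditioned for K up to several hundred, so regularisation is
unnecessary, and all K weights are reported rather than a top-k subset.
An exponential proximity kernel exp(−d²/width²) on cosine distance from
the unperturbed row is available behind a flag (`use_kernel`) for parity
with other LIME implementations; the all-zeros row is assigned distance 1
by convention. The fit score is the coefficient of determination on the
fitting set itself (no holdout — the surrogate is a local description,
not a predictive model), defined as 1 when the residuals vanish
identically, e.g. for a constant target.

Degenerate designs raise rather than warn: fewer than K+1 samples, or
duplicated/constant mask columns, produce a singular-design error naming
the collinear columns (found by QR with column pivoting). Negative sample
weights are rejected.

## Segmentation

Felzenszwalb (FHA), SLIC and quickshift are delegated to scikit-image;
this package contributes the uniform contract around them: 8-bit RGB in,
labels renumbered to a contiguous 0..K−1 range in row-major
first-occurrence order (so output labelling is deterministic across
backends), and a shared Gaussian pre-smoothing width σ = 0.8 — the
library default for FHA, adopted for all three. Quickshift's mode-seeking
RNG is pinned so segmentation is reproducible.

The squaregrid decomposition divides the raster into an r×r grid of
squares. Block edges sit at round(i·dim/r): when r divides the dimension
all blocks are identical (on 96×96 the seven canonical levels 9, 16, 36,
64, 144, 256, 576 divide evenly, the finest giving 4×4-pixel squares);
otherwise sides differ by at most one pixel. The scheme is
content-independent by construction.

Count matching: quickshift offers no direct segment-count control, so it
is the baseline; FHA's `scale` (count decreasing) and SLIC's `n_segments`
(count increasing, though only roughly — SLIC's connectivity enforcement
makes the realised count non-monotone locally) are searched by bisection
under the monotonicity assumption, falling back to a coarse scan when the
bracket contradicts it or bisection misses. If no parameter in the range
reproduces the baseline count exactly, the closest count is returned with
an explicit mismatch flag rather than an error — a count-mismatched
comparison is degraded, not meaningless. Quickshift defaults
kernel_size = 4, max_dist = 6, ratio = 0.5 were fixed once so that
default segmentations of the synthetic patches land in the 20–40 segment
regime typical for this patch size, with the 200–600 FHA scale window
bracketing the quickshift count; all are exposed as parameters.

## Multi-scale squaregrid explanations

One independent surrogate run per grid level; the final heat map is the
elementwise sum of the per-level maps, so coarse levels contribute broad
context and fine levels detail, adding constructively where scales agree.
Per-level seeds are derived as base_seed + level index — levels are
independent yet the whole procedure is reproducible from one seed — and
masks are resampled fresh at each level (each level is a self-contained
surrogate run; nothing is shared but the image). Classifier calls are not
cached across levels. The per-level explanation objects are returned
alongside the sum, and the additivity of the final map is exact, not
approximate.

When no class is requested, the explained class defaults to the
classifier's argmax on the unperturbed image — the predicted class is the
one whose explanation is usually wanted.

## Rendering

The colour convention is symmetric and diverging: t = clip(value/vmax,
−1, 1), white (255,255,255) at zero, linear RGB interpolation to
saturated blue (0,0,255) for t > 0 and saturated red (255,0,0) for t < 0.
Asymmetric limits are rejected — pinning white at zero is what makes blue
and red areas comparable across panels. The anchors and linear-in-RGB
interpolation are fixed so renderings are bit-reproducible. Annotation
overlays blend annotated pixels toward green (0,200,0) at α = 0.35 by
default. The limit sweep re-renders one map at ascending symmetric limits
(default 0.001 … 0.8, roughly log-spaced): tight limits saturate and
reveal small-weight structure, loose limits show only the dominant
segments. Heat maps round-trip through CSV at full decimal precision
(`%.17g`), so a written and re-read map compares exactly equal.

## Synthetic data and mock classifiers

The generator emulates the contrasts a metastasis detector keys on, not
histology itself: a pink background (230,180,200) with smoothed Gaussian
texture (σ_texture = 10 grey levels, smoothed at 1.5 px), 25 small
near-circular dark-purple nuclei (radius ≈ 3 px ± 15%), and — in positive
patches — around 5 enlarged lighter-purple blobs (radius 8–14 px) whose
boundary radius is modulated by seeded low-order sinusoids of the polar
angle (the "irregular shape" cue). The blob union is the annotation; the
first blob is centred inside the central 32×32 window so the label rule
holds by construction, and generated images never contain pure black
pixels (black is reserved for masking). What passing tests on these
patches show is that the pipeline's mechanics — masking, regression,
localization — behave correctly; they say nothing about any real CNN's
biology, staining variation, scanner noise or tissue texture, none of
which is modelled.

The labelling rule is the patch convention: label 1 iff at least one
annotated pixel lies in the centred 32×32 window; annotated tissue
outside the window never influences the label. For non-96×96 inputs the
window stays 32×32, centred.

Three deterministic mock classifiers serve as oracles:

* **linear** — p₁ exactly affine in segment visibility, with visibility
  detected by exact pixel comparison against the reference image. Its
  affine range over the whole mask cube is validated to stay inside
  [0, 1], so the surrogate recovers the generating coefficients to
  machine precision (the package's strongest correctness oracle).
* **near-linear** — the affine mock plus a small smooth term
  ε·sin(2π·mean(z)), ε = 0.02 by default. The nonlinearity leaves the
  surrogate an irreducible residual, so repeated explanations carry
  genuine Monte-Carlo noise; this is the regime in which weight
  stability across reruns is a meaningful measurement rather than
  trivially zero.
* **tumor detector** — p₁ = logistic(s·(v/1024 − ½)) with v the count of
  visible (non-black) annotated pixels in the central window and
  steepness s = 4 by default: a smooth stand-in for a detector of tumor
  tissue in the patch centre, used for localization checks.

## Stability measurement

`stability_check` reruns the full explanation with consecutive seeds and
reports the mean of |w_j(a) − w_j(b)| over segments and run pairs. The
headline measurement (also recomputed by `scripts/acceptance.py`) uses a
fixed positive synthetic patch, the 36-square grid, the near-linear mock
and 3 runs × 10,000 samples; it comes out near 2×10⁻⁵, comfortably inside
the ≤ 10⁻³ reproducibility regime that motivates the 10,000-sample
default, and degrades by roughly an order of magnitude at 100 samples
(Monte-Carlo error scales as N^−1/2). The exact magnitude depends on the
residual the classifier leaves around the best affine fit — stiffer
nonlinearities give larger values — so the band, not the digit, is the
reproducible quantity.

## Problem sizes in the test suite

Tests that assert exact algebraic identities (additivity, masking,
recovery) run at a few hundred perturbation samples — exactness does not
improve with N, but any level with K segments needs N > K, so runs that
touch the 576-square level use N ≥ 700. The stability and localization
checks, whose claims are statistical, run at their stated sizes (3 ×
10,000 samples; 50 seeded trials at 2,000 samples — localization is
insensitive to N at K ≈ 30, well before the 10,000-sample default).

## Known limitations

* Black-out occlusion is the only perturbation; mean-colour or blurred
  in-painting (which probe a classifier differently) are out of scope.
* SLIC's realised segment count is non-monotone in its target count, so
  exact count matching occasionally fails within a given range; the
  mismatch flag must be checked.
* The architecture counter covers the layer vocabulary of the two encoded
  reference networks (conv / dense / pooling / dropout / flatten /
  global pooling); it is not a general graph-shape engine. For the VGG19
  variant, the published layer list jumps from the last pooling stage
  (a 3×3×512 activation) straight to a 1-neuron dense head; a global
  average pool is the only standard reduction consistent with the
  published total of 20,024,897 trainable weights (a flatten would give
  4,608 inputs and a different total), and is encoded as such. The
  custom model's total likewise pins its convolutions to valid padding.
* Explanation weights are surrogate regression coefficients; they
  quantify the local effect of occluding segments, not causal importance
  in the underlying tissue.
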