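# Methods

This note documents the models implemented in `viscomp`, the parameter
defaults and why they were chosen, what the synthetic data generator does
and does not emulate, and the numerical decisions that matter when reading
results.

## Rating model

Each item i carries a Gaussian belief N(μ_i, σ_i²) over its latent
perceived complexity.  A 2AFC trial in which the observer picks item w
over item l is treated as a two-player game with performance noise β per
player and no draws (the task forces a choice).  The exact posterior of
the winner's skill,

    p(s_w | win) ∝ N(s_w; μ_w, σ_w²) ∫ N(s_l; μ_l, σ_l²) Φ((s_w − s_l)/(√2 β)) ds_l,

has closed-form first and second moments expressed through
v(t) = φ(t)/Φ(t) and w(t) = v(t)(v(t)+t) with c² = 2β² + σ_w² + σ_l² and
t = (μ_w − μ_l)/c.  `update_pair` applies these moments directly; the unit
test suite verifies them against independent 2-D Gauss–Hermite quadrature
of the posterior to 1e-5 absolute.  v is evaluated through the log normal
CDF so the ratio stays accurate far into the left tail (t ≪ −8), where a
naive pdf/cdf quotient underflows.

Parameters (all in score units):

| parameter | default | meaning / rationale |
|---|---|---|
| μ₀ | 25 | prior mean; standard convention of the rating algorithm |
| σ₀ | 25/3 | prior sd |
| β | σ₀/2 | per-game performance noise; standard default |
| τ | σ₀/100 | dynamics variance added before each update so beliefs never freeze |
| epochs_max | 10 | maximum full passes over the comparison list |
| ε_converge | 0.01 | stop when the mean per-item \|Δμ\| of an epoch falls below this |

Updates are strictly sequential (online); each epoch replays the full
comparison list in a freshly shuffled order (seeded).  Multi-epoch
replay is an interpretation choice: it treats "iterations" of the rating
process as full passes over the data.  Repeated passes re-use each
comparison several times, which sharpens the ranking (helpful for rank
recovery) but inflates the spread of μ beyond what a single pass produces
and slightly overfits item-level win rates; the consistency statistic
computed on the training comparisons is therefore biased upward at low
comparisons-per-item counts and approaches its population value as that
count grows (the chance-level test uses 2000 comparisons/item for this
reason).  Items never compared keep the prior.  Ties in μ count 0.5 in
the consistency statistic, which is unbiased under exchangeability.

## Synthetic world

The simulator emulates the statistical structure of a crowdsourced 2AFC
complexity experiment:

- latent scores ~ Normal(25.0, 5.5) — the distribution the rated scores
  of a large balanced experiment are expected to form;
- balanced random pairing: pairs are drawn in rounds of random
  near-perfect matchings serving lowest-participation items first, so
  participation spread stays ≤ 2 even when the requested number of
  comparisons is far below the number of distinct pairs (uniform sampling
  of pairs would give a binomial participation spread much larger than
  the "approximately equal counts" a balanced experiment achieves); pairs
  repeat only when unavoidable; observers receive trials round-robin;
- Thurstone Case V observers: each item evokes an internal value plus
  independent Gaussian noise, so P(choose A) = Φ((s_A − s_B)/(√2·noise_sd)),
  optionally mixed with a uniform lapse.  noise_sd = 2 (score units) is
  the canonical test condition: a mostly-consistent but imperfect
  observer.  The human noise level cannot be pinned down separately from
  the latent spread, so both knobs are exposed rather than fixing a
  "human-equivalent" setting;
- procedural images: mid-gray background plus Gaussian texture noise,
  with random ellipses/polygons in palette colours; one bounding-box tag
  (from a 20-name VOC-style vocabulary) per shape.  Complexity drivers —
  shape count, palette size, texture noise — are known exactly.

What the generator does **not** emulate: natural-image statistics (1/f
spectra, object co-occurrence, semantics), photographic framing, and
observer-specific biases.  Passing tests demonstrate that the pipeline
machinery is correct and that the feature battery responds to known
complexity drivers in the right direction; they do not certify predictive
accuracy on real photographs or human judgements.

In the part-whole study the simulator is hierarchical: each image has a
complexity level ~ Normal(25.0, 5.5), its discs scatter around that level
with half that sd, and the whole-image latent is the disc mean plus the
same half-sd noise.  Without within-image correlation the mean of ~35
discs would carry almost no between-image variance and no part-whole
prediction would be possible at any rating quality.

## Feature battery

31 features are computed per image; all are deterministic functions of
the pixels and configuration (identical pixels through PNG or BMP give
bitwise-identical values).  Conventions:

- luminance is Rec.601 (0.299 R + 0.587 G + 0.114 B) on [0,1] floats;
  sRGB→CIELAB uses the D65 white point;
- GLCM: 8 grey levels, offset (0,1), symmetric, normalised.  "Energy" is
  the angular second moment (the MATLAB `graycoprops` convention: a
  two-level checkerboard scores 0.5, a constant image 1).  Correlation of
  a constant image is undefined and returned as 0 with a warning;
- entropies: Shannon entropy, base 2, of 256-bin histograms on [0,1],
  with 0·log 0 := 0;
- colourfulness: √(σ_a²+σ_b²) + 0.3·√(μ_a²+μ_b²) in CIELAB; values below
  0.01 (the grey-residue floor of the colour conversion) are clamped to 0.
  Colour count: occupied 10-unit CIELAB cubes holding ≥ 0.01% of pixels.
  Colour harmony: best chroma-weighted fit of the hue distribution to
  rotatable harmonic arc templates, in [0,1] — a stand-in whose absolute
  values are not comparable to other software;
- clutter (feature-congestion style): colour clutter pools √det of the
  local CIELAB (a,b) covariance over a 3-level Gaussian pyramid; contrast
  clutter is the local sd of a difference-of-Gaussians luminance response
  (mean and variance over pixels and scales); subband entropy is the mean
  fixed-bin-width entropy of the detail subbands of a 3-level db4 wavelet
  decomposition (fixed bin width so the entropy grows with coefficient
  spread rather than being scale-invariant).  The exact variant of the
  original clutter model (pooling, scales) is not standardised, so these
  are documented reimplementations, not pixel-exact ports;
- edge density: Canny on luminance, thresholds [0.11, 0.27], σ = 1;
- JPEG ratio: 3 bytes/pixel divided by the JPEG byte count at quality 75;
- frequency factor: the radial frequency (cycles/pixel, DC included)
  below which 99% of FFT power lies, divided by Nyquist (0.5) and clipped
  to [0,1];
- counts ("reference" backend, self-contained): multiscale SIFT-style
  keypoints and difference-of-Gaussian blobs for the two keypoint counts,
  a stable-threshold extremal-region counter (regions whose area changes
  ≤ 20% across a 16-step threshold ladder, both polarities, with small
  and near-full-frame components excluded), and mean-shift segmentation
  of a ≤48-px CIELAB raster (bandwidth 14 Lab units) whose connected
  components give the region count.  The "external" backend reads all
  four counts from a CSV instead.  Absolute counts are not comparable to
  other implementations; only directions and orderings are meaningful.

Features that require trained models (deep salience statistics, detector
object counts, visual-search RTs) are merged from external CSV columns;
missing values stay NaN, never silent zeros.

## Prediction models

Inputs are standardised to zero mean and unit variance **inside** the
estimator, so any cross-validation wrapped around it estimates the scaling
on training folds only; targets are never rescaled.  Lasso/ridge select α
by inner 5-fold CV over 10 log-spaced values from 1e-15 to 20 (the
near-zero end deliberately probes unregularised fits and can be
ill-conditioned; that warning is suppressed).  SVR defaults to an RBF
kernel with C = 1, ε = 0.1; the MLP is {128, 64, 32, 1} ReLU units,
200 epochs, early stopping on a 10% inner split, seeded initialisation —
all documented defaults where the protocol leaves them open.  Raw-pixel
regression resizes to a common raster (default 64×64) and uses
ridge-stabilised least squares since p typically exceeds n; note that a
dense linear functional of the pixels is only identifiable when the
training count exceeds the pixel dimension.  The headline metric is
Pearson's r on pooled validation predictions (ratings live on an interval
scale, so rank-only metrics discard information); for grouped CV, where
items can be validated in several splits, the mean per-fold r is reported
instead.

## Part-whole analysis

Discs of radius 50 px are placed on a square grid from r to dim − r at
stride round(1.2·r) = 60 px, so neighbouring discs overlap; a 375×500
frame yields 5×7 = 35 discs, and typical photo frames (shorter side
350–400, longer 450–500) yield 30–50.  A dimension not exceeding 2r
collapses to one centred disc at index (dim−1)//2.  Extracted disc
rasters mask pixels outside the disc to mid-gray (0.5) so feature
extraction on discs is well-defined; masking (rather than cropping or
blending) is a design choice.  Complexity maps interpolate disc μ values
with an exact bicubic spline (RectBivariateSpline, s = 0) when both axes
have ≥ 4 centres — the surface passes through every disc rating at its
centre to machine precision — and fall back to bilinear with a warning
otherwise; pixels beyond the outermost centres take the boundary value.
Summed disc ratings are flagged non-comparable when images have unequal
disc counts (the sum confounds complexity with image area).  Validation
splits hold out whole images, never individual discs, so nothing in
validation shares a source image with training.

## Object tags

The "central" object of an image is the tag with the largest bounding-box
area (ties break by file order).  For each class, images containing it
split disjointly into central (class is the largest object) and
background (present but not largest); the anywhere-mean is therefore
exactly the image-count-weighted mean of the two cells.  Tag-based
predictors use the anywhere cell by default (the alternative is exposed
via `class_cell`); classes unseen in the training table fall back to the
global mean rating so predictions stay total.  VOC XML (1-based,
inclusive) is converted to the package's 0-based half-open convention on
read.

## Problem sizes and numerical choices

The end-to-end replication runs the whole-image stage at full scale
(4000 items, 75,020 comparisons, 62 observers) — the balanced design and
online rating engine handle this in seconds — while the image-based
substudies run at desk scale: 48 procedural images (96×72) for the
feature study with a leave-one-out ridge fit (ridge rather than OLS
because the image count is close to the 31-feature dimension), and 20
latent-level part-images of 35 discs each for the part-whole study.
Degenerate inputs are handled explicitly: constant images get zero
entropies/variances/clutter and a flagged GLCM correlation; empty
comparison lists return prior beliefs; zero-keypoint images are an error
for descriptor sampling (a keypoint detector that returns nothing has no
character to sample).

## Known limitations

- The rating engine is a sequential two-player approximation, not full
  expectation propagation over the comparison graph; per-observer skill
  or bias is not modelled.
- Feature values involving reimplemented components (clutter, colour
  count/harmony, region counts) are internally consistent but not
  numerically interchangeable with the original MATLAB/EDISON tools.
- Multi-epoch rating inflates the μ spread relative to a single pass; μ
  is an interval-scale score whose spread depends on the epoch schedule,
  so compare μ values only within a single rating run.
- The synthetic generator's simplicity means absolute correlation levels
  reported by the replication say nothing about human data; only the
  pipeline's correctness and directional behaviour are validated.
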