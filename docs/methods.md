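# Methods

`dermoborder` quantifies the *B* (border irregularity) feature of the
clinical ABCD melanoma rule from a single grayscale lesion image.  This
note records the models behind each stage, the parameters that matter,
the numerical choices, what the synthetic data does and does not
emulate, and the known limitations.

## Segmentation: fuzzy clustering with a type-II ambiguity threshold

A lesion image is modelled as two intensity populations — pigmented
lesion and surrounding skin — with an ambiguous transition zone at the
border.  Fuzzy c-means (c = 2, fuzzifier m = 2) fits graded
memberships u_ij by minimizing

    J = Σ_j Σ_i u_ij^m ‖x_j − v_i‖²,

with the standard alternating updates of centroids and memberships.
Iteration stops when the largest centroid move falls below 1e−5
(identical centroids being the limiting case) or at 300 iterations.
Centroids initialize at the 25th/75th intensity percentiles, which
makes the fit deterministic; the seed only perturbs a collapsed
initialization.  Constant images are rejected as degenerate.

Rather than committing every pixel to its argmax cluster, pixels are
split into confident and ambiguous by an *ambiguity threshold*.  An
S-shaped membership function (piecewise quadratic, crossover at its
centre knot) is slid across the gray range; at each position the
*ultrafuzziness*

    γ̃(g) = (1/MN) Σ_g h(g) · [μ(g)^{1/α} − μ(g)^α],   α = 2

measures the histogram-weighted width of the type-II membership band
(the footprint of uncertainty).  The position maximizing γ̃ is the
threshold; ties break to the lowest gray level.  Because this is a
histogram computation, it runs on the lesion cluster's membership map
rescaled to [0, 255], so the maximizing position converts directly to
a membership threshold τ = g_pos/255 (a raw-image scan is available
via `threshold_on="image"`).

Parameters: α ∈ (1, 2] (default 2 — larger exponents wash out image
memberships); scan bandwidth, default (L−1)/4 = 63.75 gray levels.
The bandwidth sets the scale of the ambiguity analysis: a band
spanning half the gray range keeps both modes of a bimodal histogram
inside the S-ramp and places the maximum between them, while the
narrower default localizes on the transition zone of one population —
appropriate here because the scan runs on membership maps whose mass
concentrates at 0 and 255.  At the range ends the knots are clipped
with a half-level epsilon so they stay strictly ordered.

*Gradual focusing* then resolves the ambiguous pixels: confident
pixels (max membership ≥ τ) commit to their argmax cluster and form
the coarse image structure; the remaining weak pixels are swept in
raster order and join the majority cluster among the already-committed
pixels in their 3×3 window, with frequency ties reverting to the
pixel's own argmax cluster.  Sweeps repeat until the weak set is
empty; a sweep with no progress (e.g. τ = 1 making everything weak)
falls back to argmax seeding through the same tie rule, so termination
is unconditional.

Cleanup keeps the largest 8-connected component of the darker-centroid
cluster (pigmented lesions; invertible by flag), fills holes, and
applies edge-preserving smoothing.  The smoothing contract — remove
texture below a scale without moving step edges more than one pixel,
identity at scale 0 — is filled by a median filter with window
2·scale + 1 (default scale 2).  A median filter satisfies the contract
exactly on binary masks and keeps the implementation dependency-free;
any smoother honouring the same contract can be substituted.

On the synthetic fixtures (contrast ≥ 100, noise sd ≤ 10) the
segmentation overlaps ground truth at Jaccard > 95%.

## Border detection

The border stage is a four-step Canny detector: separable 1-D Gaussian
smoothing (σ = 1.4, kernel truncated at ±4σ and renormalized), a 2×2
gradient stencil

    R_x = (−S1 + S2 − S3 + S4)/2,   R_y = (S1 + S2 − S3 − S4)/2

over samples S1..S4 at (r,c), (r,c+1), (r+1,c), (r+1,c+1) (edge
replication keeps the field full-size; direction is a quadrant-aware
arctangent so R_x = 0 is well defined), non-maximum suppression with
directions quantized to 0°/45°/90°/135° sectors and a strict ">"
comparison (plateaus are suppressed), and two-level hysteresis linking
(edges above the high threshold; candidates above the low threshold
kept only when 8-connected to a strong pixel).  Thresholds default to
the 90th percentile of nonzero thinned magnitudes and 0.4× that value,
which adapts to binary-mask gradients where absolute magnitudes are
arbitrary.

The final border is an ordered, closed, 8-connected trace obtained by
Moore-neighbor boundary following on the region enclosed by the
largest closed edge contour.  Strict-inequality suppression can nick
one- to few-pixel gaps into an otherwise closed ring; a dilate–fill–
erode bridge with growing radius (1–3 px) recovers the enclosed region
before tracing, and an error with diagnostics is raised if no contour
encloses any area.  Perimeters are polygonal arc lengths with diagonal
steps counting √2; on a rasterized disc of radius r the trace length
sits within ~6% of 2πr.

## The 27-value irregularity descriptor

Order: [FD, C, ZM1..ZM25].

**Box-counting fractal dimension.**  N(ε) counts ε×ε grid cells
(anchored at the trace bounding-box origin, single offset) touched by
the border; D is the least-squares slope of log N against log(1/ε)
over a dyadic ladder ε = 1, 2, 4, … up to a quarter of the longer
bounding-box side, using only scales with N > 1.  Smooth closed
borders measure ≈ 0.9–1.0 (discretization biases small smooth loops
slightly below the ideal 1), rough borders climb toward 1.3+; the
Koch curve at five construction steps measures within 0.08 of its
analytic log 4/log 3.  Estimates outside [1, 2] trigger a warning but
are returned unclamped.  What matters downstream is the monotone
response to border roughness, which holds across the fixture range.

**Convexity.**  Convex-hull perimeter divided by lesion perimeter,
both as Moore-traced arc lengths; capped at 1 to absorb the ≤ 3%
discretization error on convex shapes.  Indentations shorten the hull
relative to the border and push C below 1.

**Zernike magnitudes.**  The filled mask is mapped to the unit disc at
its centroid (radius = largest centroid-to-pixel distance) and
normalized to unit mass; for every order n ≤ 8 and repetition m ≥ 0
with n − m even,

    Z_nm = (n+1)/π · Σ conj(V_nm(ρ, θ)) f(px),   V_nm = R_nm(ρ) e^{imθ},

with R_nm the exact finite factorial sum.  That yields 25 magnitudes;
|Z_00| = 1/π ≈ 0.3183 for every nonzero mask under unit-mass
normalization, a built-in sanity anchor.  Magnitudes (not complex
values) are used because they are rotation invariant (verified to
1e-2 under 90° rotations; translation invariance is exact by the
centroid mapping).

## Classification and fusion

**Gaussian naive Bayes** on the 27-value descriptor: per-class feature
means and variances (floored at 1e−9 × the largest feature variance so
the constant ZM1 channel stays usable) with frequency priors;
prediction multiplies the per-feature normal densities in the log
domain and normalizes the two posteriors.

**CNN**: five 3×3 convolution layers (16/32/64/128/256 filters, ReLU),
each followed by 2×2 max-pooling, then a 64-unit ReLU layer and a
single sigmoid output read as p(regular).  Input is the smoothed
segmented mask and the border map stacked as two 128×128 channels,
with the standardized 27-value descriptor concatenated onto the
flattened features.  Training is binary cross-entropy with Adam
(lr 0.001, batch 8), 1 epoch by default, all randomness from one seed.
The network is implemented directly in numpy (im2col convolutions,
hand-derived gradients), which keeps the package self-contained and
the arithmetic inspectable; an epoch over ~70 samples takes a few
seconds on one CPU core.

**Fusion.**  With subscript 1 = irregular and 2 = regular,

    P = (CNN_p1·GnB_p1 + CNN_p2·GnB_p2)/2 ∈ [0, 0.5],
    threshold = (max(P) + mean(P))/2  over the test batch,
    decision: regular if P_i < threshold, irregular if P_i > threshold,

with the P_i = threshold tie classified irregular: a false "regular"
call risks a missed melanoma, while a false "irregular" call only
triggers further investigation.  For single-image use, where a batch
maximum does not exist, the threshold frozen from the training batch
is substituted.

Note that P is invariant under flipping both probability pairs, so it
measures *joint confidence*, not class direction.  The scheme
classifies correctly exactly when the models are systematically more
confident on irregular borders than on regular ones.  That asymmetry
is a property of the intended training regime — a small set of unique
regular lesions replicated to class parity by flip/rotate
augmentation against a larger, diverse irregular pool — which leaves
the CNN's sigmoid less saturated on regulars.  A fully balanced and
fully learned training set removes the asymmetry and with it the
separation; training the CNN past the point of usefulness likewise
erodes accuracy, which is why the default is a single epoch.  The
end-to-end test measures this protocol: 6 unique regular lesions
augmented to parity with 36 irregulars for training, 60 fresh held-out
lesions (30 smooth, 30 rough) for testing.

**Metrics.**  Accuracy, sensitivity (regular-class recall),
specificity (irregular-class recall), and F-score with irregular as
the positive class, all in percent, plus the Jaccard index
|G∩S|/|G∪S|·100 for segmentation overlap.  This class-role mapping is
the unique one under which a 47-sample batch (40 irregular, 7 regular,
3 irregular misses, no regular misses) yields 93.6 / 100 / 92.5 /
96.1 simultaneously.

## Synthetic lesions

`fixtures` generates what dermoscopy inputs provide at the level this
pipeline consumes: a dark, roughly centred lesion (background gray
200, contrast 100–140) with additive Gaussian noise (sd 5–10) on a
256×256 canvas, a noise-free ground-truth mask, and a label.  Regular
lesions (label 1) are ellipses; irregular lesions (label 0) are
star-convex blobs r(θ) = R·(1 + roughness · p(θ)) with p a seeded sum
of sinusoidal harmonics (orders 2–24 by default) weighted 1/k and
scaled to peak amplitude 1, so `roughness` is the peak relative radial
deviation and any value < 1 keeps the radius positive.  Roughness 0
reproduces the disc of the same radius bit for bit.  The default
irregular range 0.35–0.5 gives median fractal dimension and convexity
distributions disjoint between classes over 30 samples per class.

Every generator is a pure function of parameters and seed.  The
augmentation set is fixed to identity, three rotations, and two flips
— the transforms that leave the descriptor's rotation-invariant parts
unchanged and labels trivially valid.

What the fixtures do *not* emulate: hair and ruler artifacts, color
texture, multi-lesion fields, vignetting, and the ambiguity of real
clinical labels.  Passing tests therefore demonstrate the correctness
of the algorithms and the learnability of shape-based irregularity,
not clinical performance on dermoscopy archives.

## Degenerate inputs and numerical conventions

Coordinates are 0-based, row-major, origin top-left; masks use
1 = lesion.  Constant images are rejected by clustering and
thresholding; empty masks are rejected by every feature; membership
argmax ties break to the lower cluster index and γ̃ argmax ties to the
lower gray level.  FCM distances are floored at 1e−12 so pixels
sitting exactly on a centroid get full membership without division by
zero.  All percentages are reported unrounded; display rounding is the
caller's choice.

## Problem sizes

Defaults are desk-scale: 256×256 synthetic canvases (the pipeline
accepts any size), 128×128 CNN inputs, training sets of tens of
lesions, and a 60-lesion held-out evaluation.  These sizes keep the
full test suite in the half-minute range on a single CPU core while
exercising every code path at realistic geometry.

## Known limitations

- The box-counting estimate on small smooth loops dips below the
  theoretical 1.0; comparisons are meaningful within the pipeline, not
  against absolute literature values.
- The fused score's direction-blindness (above) makes ensemble
  accuracy sensitive to the training composition and to CNN training
  length; the Gaussian naive Bayes alone is the more robust classifier
  on cleanly separated shape classes.
- Single-lesion images only; the largest-component rule silently
  discards secondary lesions.
- No hair removal or illumination correction is attempted.
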