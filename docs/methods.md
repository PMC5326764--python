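# Methods

## Problem setting

Scoring cereal development stages (e.g. the Zadoks decimal scale) is
traditionally done by eye in the field. The pipeline here automates the
binary decisions that matter for two stages — *are emerged ears present in
this canopy image?* (heading) and, given ears, *are they flowering?* — by
treating each as two-class image categorization. The package implements
the full classical BoVW stack rather than a learned end-to-end model: it
is transparent, trains from a few hundred small labelled patches, and
classifies images of any resolution with one pooled vector per image.

## Decorrelation stretch

Ears at emergence differ from leaves mainly along a low-variance direction
of RGB space; the three channels of vegetation images are strongly
correlated (typically ρ > 0.9). The enhancement whitens the channel
covariance — rotate by the eigenvectors, divide each principal component
by √(vᵢ+δ), rotate back — then multiplies by a single contrast parameter
`target_sd` and re-centers at 127.5.

Choices that were genuinely open:

* **Covariance vs. correlation matrix.** Both are classical; covariance is
  the default (`ds.matrix`), correlation available for images whose
  channels differ grossly in dynamic range.
* **`target_sd` = 50.** Puts ±2.5σ of the whitened distribution inside the
  8-bit range; larger values saturate more pixels into the clip. This is a
  display/contrast knob, not a statistical one; it cancels out of any
  classifier applied after per-image normalization.
* **Guard δ = 1e−12·max(v).** Small enough that the pre-clip output
  covariance equals `target_sd`²·I to better than 1e−6 relative error on
  any sanely conditioned image (the testable whitening contract), large
  enough that a perfectly flat channel does not divide by zero. An
  all-constant image returns the recenter level everywhere.
* The eigenvector sign convention (largest-magnitude entry positive) has no
  effect on the output — the transform is R f(Λ) Rᵀ, invariant to column
  signs — but makes `ChannelStats` deterministic for tests.

## SIFT

The detector/descriptor follows the standard construction: σ₀ = 1.6, 3
scales per octave (k = 2^{1/3}), initial 2× upsampling, octave count
⌊log₂ min(H, W)⌋ − 2, DoG by exact subtraction, strict 26-neighbor extrema,
≤5 iterations of quadratic sub-pixel refinement with a 0.5-pixel clamp,
contrast threshold 0.03 on [0, 1] intensities, edge-ratio limit 10,
36-bin orientation histograms (Gaussian-weighted at 1.5σ, six smoothing
passes, secondary peaks ≥ 80% emit duplicates), and 4×4×8 trilinearly
binned descriptors normalized–clipped (0.2)–renormalized.

Notes:

* Features are computed on the BT.601 luminance of the enhanced image;
  per-channel extraction would triple cost for little texture gain since
  the stretch already moved the discriminative signal into luminance
  contrast.
* Detected (sparse) keypoints are the default; a dense grid
  (`sift.dense`, `sift.dense_step`) exists for experimentation.
* Zero-gradient windows produce flagged keypoints whose (all-zero)
  descriptors are excluded from encoding, so every descriptor that reaches
  the coder has unit norm.
* The module is fully deterministic; orientation duplicate counts can vary
  by a few keypoints under exact 90° rotation because near-threshold
  secondary peaks sit on bin boundaries — detection itself is equivariant.
* Images above `sift.max_pixels` (8 Mpx) are decimated by powers of two
  before extraction and coordinates mapped back.

## Vocabulary and coding

K-means is Lloyd's algorithm with k-means++ seeding (seeded; plain random
available), assignment-fixpoint / relative-tolerance / max-iteration
stopping, farthest-point re-seeding of emptied clusters, and an in-loop
assertion that the inertia never increases. At most
`codebook.max_descriptors` (200,000) descriptors are used, subsampled with
the master seed. The vocabulary size is the main capacity knob: the
classical sweep saturates in the low thousands on field imagery; the
synthetic suite uses K = 200, which already saturates the fixture task.

LLC solves min ‖x − Bc‖² + λ·tr(ZZᵀ)‖c‖² s.t. Σc = 1 over the `encode.knn`
= 5 nearest words (Z = B − x), in closed form via the local Gram system;
λ = 1e−4. The trace-scaled ridge keeps the system finite when selected
words coincide. Weights may be negative (the constraint is affine);
pooling takes absolute values to preserve histogram semantics. Hard 1-NN
assignment (`encode.method = hard`) is the vector-quantization baseline of
the ablation grid.

## Spatial pyramid

Grids 1×1, 2×2, 4×4 (21 sub-regions, 21·K entries — 42,000 at K = 2000);
half-open cells with floor indexing, right/bottom edge points clamped to
the last cell; per-level weights (1/4, 1/4, 1/2), the standard pyramid
weighting, configurable; `spm.enabled = false` reduces to the plain
level-0 bag of words of length K. Sum pooling is the default ("histogram"
semantics); max pooling is exposed because LLC is often paired with it.
The final vector is L1-normalized, which is also what makes a model
trained on small patches applicable to full scenes: only the *relative*
word distribution enters the classifier.

## Classifier

The Hellinger kernel Σ√(hᵢh′ᵢ) is realized as an explicit feature map
(L1-normalize, elementwise square root — mapped vectors have unit L2 norm)
followed by linear one-vs-all SVMs (liblinear primal, squared hinge,
C = 1.0, deterministic). Prediction is the argmax of decision values,
lowest class index on ties. An image with no keypoints yields the zero
vector and is decided by the biases alone, with a low-confidence marker.
Precision and recall are reported retrieval-style — retrieved-relevant
over retrieved, and over total-relevant — with precision reported as null
(not zero) when nothing is retrieved.

## Synthetic fixtures: what they do and do not show

The generator emulates the *structure* of the field problem, not its
appearance: 64×64 patches; the ear class is a smooth green base with 4
elongated blobs (elongation 3, orientation jitter ±0.5 rad) carrying a
high-frequency spotted "spikelet" texture (wavelength 5 px) and optional
awn streaks; the background class is low-frequency oriented stripes
(wavelength 18 px) with smooth mottling. RGB channels share the texture
through a common component weighted for pairwise correlation 0.95, the
regime where decorrelation stretching is informative. Nuisances: per-image
illumination gain ~U(0.8, 1.2) (±5% per channel) and offsets ±10, and
occluding dark ellipses (probability 0.3, up to 25% area) on training
images. Composite "canopy" scenes are the same texture at 2× size with
proportionally more blobs. Everything derives bitwise from one seed with
per-image counters.

The study conditions for the end-to-end checks are 50 images per class
(40 train / 10 test after the 80/20 split), K = 200, learning-curve sizes
10/20/40 per class averaged over 5 seeds, and an illumination probe of
channel gains (0.40, 0.33, 0.50) with offsets (60, 60, 40) — a strong,
channel-asymmetric contrast compression. Under that probe the
decorrelation-stretched pipeline keeps its accuracy while the unenhanced
one collapses to chance, because whitening renormalizes per-channel
contrast before feature detection while the raw pipeline loses most
keypoints to the contrast threshold.

Passing these tests shows the machinery is correct and that the
enhancement does what it claims *in this controlled color model*. It does
not show field-level accuracy: real canopies have perspective, wind blur,
soil, mixed cultivars, and far richer texture; headline numbers on real
imagery require real imagery.

## Numerical and degenerate-input choices

* Population (denominator-n) covariance throughout the enhancement.
* K-means ties and assignment ties always resolve to the lowest index;
  LLC neighbor lists are sorted by (distance, index) for determinism.
* Sub-pixel refinement discards candidates that drift out of the interior
  or fail to settle in 5 iterations; border candidates are skipped.
* Empty feature sets propagate as zero pyramid vectors plus warnings
  rather than errors, so one blank frame cannot abort a batch run.
* Model serialization is a single `.npz` with a JSON metadata header
  (classes, seeds, config echo, codebook hash); loading reproduces
  predictions bitwise.

## Known limitations

* SURF is not implemented; the corresponding ablation cell reports
  "skipped" (no SURF detector is available to the package).
* The SIFT implementation is vectorized per keypoint but pure
  NumPy/SciPy; very large images rely on the `sift.max_pixels` decimation
  rather than raw speed.
* One pooled vector per test image: no sliding-window localization of
  ears within a scene.
* Flowering-stage discrimination (ears-with-anthers vs. ears-without) is
  the same machinery with a different training set; the synthetic
  generator does not model anther micro-texture.
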