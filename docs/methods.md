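# Methods

This note documents the model, the choices behind the implementation, what
the synthetic fixtures do and do not emulate, and known limitations.

## Model and procedure

The classifier is a part-prototype network trained on *pseudo-classes*.
The procedure, end to end:

1. **Preprocessing.** Images are resized to `side × side × 3` (bilinear,
   anti-aliased; a resize to the image's own size is skipped so it is
   exactly the identity), scaled to [0, 1], and standardized per channel
   with the fixed constants mean 0.5, std 0.25 (`imageset_io.NORM_MEAN/STD`).
   The upstream literature says only "normalized"; fixed constants keep the
   transform data-independent and invertible for display.
2. **Black-box embedding.** A small CNN classifier is trained on the
   original class labels (Adam, lr 0.001, default 5 epochs). The embedding
   of an image is the global average pool of its final conv block — the
   "last layer before the fully connected layer" — with no L2
   normalization or whitening: clustering sees the raw latent space the
   classifier learned.
3. **Per-class K-means.** K-means (k-means++, 10 restarts, fixed seed) runs
   separately on each class's embeddings. Cluster indices are canonicalized
   by descending cluster size (ties by centroid lexicographic order) so the
   partition is reproducible under row permutation. Pseudo-labels use the
   fixed encoding `ỹ = c·K + k`; the inverse `c = ⌊ỹ/K⌋` is the remap
   used at inference. K = 1 makes pseudo-classes coincide with classes and
   is the built-in baseline ablation.
4. **Balancing and augmentation.** Groups below the target count are
   oversampled with replacement (groups above it are left unchanged);
   duplicates get ids `{src}#dup{k}`. Geometric augmentation (rotation
   ±25°, shear ±10°, skew ±10%, small elastic distortion; all
   configurable) appends `{src}#aug{k}` copies that inherit labels and
   pseudo-labels. Embeddings for clustering are computed on preprocessed,
   *non-augmented* images; augmentation is applied after relabeling.
5. **Part-prototype network.** Backbone conv stack plus two 1×1 add-on
   convolutions, the first with ReLU, the second with a sigmoid so patch
   embeddings lie in (0, 1) — matching the uniform [0, 1) prototype
   initialization. Distances are squared Euclidean throughout (the
   similarity formula only ever uses d²; no square root is taken).
   Similarity `s = log((d²+1)/(d²+ε))` with ε = 1e-4 is strictly
   decreasing in d², equals ln(1/ε) ≈ 9.2103 at d² = 0 and tends to 0 as
   d² → ∞. Max pooling over the activation grid takes the first maximum in
   row-major order (deterministic tie-break).
6. **Three-stage optimization.** Joint stage: head frozen; conv and
   prototypes minimize mean CE + λ₁·(min own-class d²) − λ₂·(min
   other-class d²) with λ₁ = 0.8, λ₂ = 0.08, Adam at lr 0.001. Push stage:
   each prototype is replaced by the nearest same-pseudo-class patch
   embedding over the whole training set (including oversampled and
   augmented copies), with provenance (image id, row, col) recorded; ties
   resolve to the first candidate in dataset order, making the push
   deterministic and idempotent. Head stage: with conv and prototypes
   frozen the similarity scores are fixed, so they are computed once and
   the head is refit on the cached scores for 20 full-batch Adam steps of
   CE plus an L1 penalty (coefficient 1e-4 by default) on connections
   between a prototype and output units of *other* pseudo-classes. The head
   starts at +1 for own-class links and −0.5 otherwise. The schedule
   [joint ×10 → push → head ×20] repeats until 30 joint epochs are
   consumed; "total epochs" counts joint epochs only.

## Neural-network kernel

No deep-learning framework is used: `pcppn.nn` implements strided 2-D
convolution (im2col), ReLU, sigmoid, linear, global average pooling and
Adam in NumPy with hand-written backward passes, verified against
finite-difference gradients in the test suite. The gradient of the joint
objective through the prototype layer is routed analytically: the upstream
gradient reaches each (image, prototype) pair's minimal-distance patch cell
only, with ds/dd² = 1/(d²+1) − 1/(d²+ε), and the cluster/separation terms
add ±λ/B at their argmin prototypes.

Backbones are small registered conv stacks (`tiny`: 5×5/stride-4 then two
3×3/stride-2 blocks — total stride 16, so a 64×64 input yields a 4×4 patch
grid; `tiny_wide`, `tiny_deep` variants for reproducibility probes). The
backbone is a configuration choice, not a code fork; large pretrained
architectures are out of scope of this CPU-only implementation.

## Synthetic fixtures

`synthetic_fixtures.generate_imageset` plants, in each image, exactly one
square motif from a family determined by (class, sub-mode): an oriented
sinusoidal grating with family-specific orientation, spatial frequency,
color tint and mean luminance, at a uniformly random location over a noisy
gray background. Defaults: q = 2 classes × K_true = 2 sub-modes × 25
images, 64 px side, 28 px motif, pixel noise sd 0.06. Two generator design
points matter:

- families differ along several axes at once (orientation, frequency, hue,
  luminance) so sub-modes are well separated in generic pooled conv
  features, which is the premise of the clustering step;
- grating frequencies stay below ~0.15 cycles/px (period ≥ ~7 px) so that
  strided backbones do not alias the texture; with higher frequencies the
  pooled features become sensitive to the motif's position phase and the
  planted sub-modes smear into diffuse, sometimes bimodal clusters.

With the confound flag on, the *background* receives a class-correlated
hue tint (strength in [0, 1]); the channel sums of the class tints are
equal, so the confound is a hue shift, not a brightness shift. A sidecar
table records each image's (class, sub-mode, motif bounding box).

What the fixture does **not** emulate: stain variability and stain physics,
tissue morphology, label noise, scale/magnification effects, inter-image
correlation from shared patients. Passing tests therefore demonstrate the
*mechanics* of the method — clustering recovers planted structure,
prototypes land on discriminative patches, remapping preserves classes —
not clinical performance.

`generate_ratings` simulates the 0–3 rater scale: a chosen fraction of
prototypes draw scores from a high distribution (default P(0..3) =
.00/.05/.35/.60), the rest from a low one (.60/.30/.08/.02).

## Interpretability metrics

Relevancy is the mean of the M×P score table scaled to a 0–100 percentage;
it is linear in each score, invariant to prototype/rater permutation and to
duplicating the whole rater panel, and equals the prototype-count-weighted
mean of the per-class relevancies. Disagreement is the per-prototype std
across raters — sample std (ddof = 1) by default, with a switch, since
either convention is defensible — averaged within class and overall, and
is 0 exactly when every prototype is rated unanimously.

Prototype explanations upsample the prototype's activation grid on its
provenance image to input resolution (bilinear) and draw the tight
bounding box around the region at or above the 95th percentile of the
upsampled map. The confounding probe scores each pushed prototype by the
IoU of this box against the planted motif box of its provenance image and
reports the fraction with IoU > 0.1 ("touches the relevant region");
prototypes whose provenance is a geometrically augmented copy are excluded
because the motif's coordinates no longer match the ground-truth table
(oversampling duplicates are pixel-identical and resolve to their source).
Probe experiments therefore run with augmentation disabled.

## Evaluation conventions

Confusion matrices use rows = true class; per-class accuracy is the row
diagonal rate in percent, with empty classes reported as missing rather
than 0. Both the sample-weighted overall accuracy and the unweighted macro
mean are emitted, since "average accuracy" is ambiguous. Cross-fold
summaries report mean ± sample std (ddof = 1) and both count- and
rate-averaged confusion matrices. Pseudo-class argmax ties resolve to the
lowest pseudo id.

## Problem sizes and determinism

Default experiment sizes (100 images at 64 px, 3-block stride-16 backbone,
D = 32, 10 prototypes per pseudo-class, 30 joint epochs) were chosen so a
full pipeline runs in seconds on one CPU core while leaving the planted
structure non-trivial to recover. One master seed fans out to named
sub-seeds (synthesis, embedding, K-means, balancing, augmentation, fit) via
SHA-256, so components can be re-randomized independently; every operation
is bitwise reproducible for a fixed seed within a fixed environment.

## Known limitations

- Backbones are small and trained from scratch; no pretrained weights, so
  absolute accuracies on real histopathology data are not represented.
- The joint-stage gradient ignores the (measure-zero) non-differentiability
  at argmin/argmax ties, as is standard.
- K is fixed per run; there is no automatic cluster-count selection.
- The elastic-distortion augmentation is a small-amplitude displacement
  field, not a diffeomorphic warp.
- Relevancy requires complete rating tables; missing cells are rejected
  rather than imputed.
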