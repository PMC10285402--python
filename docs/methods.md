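# Methods

## The problem

Serial scanning electron microscopy (SEM) of brain tissue produces large
anisotropic grayscale stacks — thousands of aligned sections with in-plane
resolution several times finer than the section spacing — in which neurites
and organelles appear as bright, textured interiors bounded by thin dark
membranes.  Dense instance segmentation of these stacks is the bottleneck of
connectome reconstruction, and annotated ground truth is scarce because it
must be produced voxel-by-voxel by experts.  This package implements a
self-supervised route around that bottleneck: masked-autoencoder (MAE)
pre-training of a 3D vision transformer on raw, unlabeled volumes, followed
by supervised fine-tuning of the pre-trained encoder inside a UNETR-style
segmentation network, watershed decoding of the predicted maps, and the
standard evaluation metrics of the field.

## Tokenization

A volume crop of shape (Z, Y, X) = (6, 96, 96) voxels (axes ordered z, y, x
throughout; z is the section axis) is divided into non-overlapping blocks of
(1, 16, 16) voxels.  The z-extent of a block is 1 because the stacks are
anisotropic: a 16×16 in-plane patch already spans roughly the same physical
distance as several sections, so further z-pooling would discard resolution
the data does not have to spare.  The standard crop therefore yields a
6×6×6 token grid — 216 tokens of 256 voxels each — flattened in z-major,
then y, then x order.  Mask plans index into exactly this order.

Each token receives a fixed 3D sin-cos positional embedding: three 1D
sin-cos tables (one per grid axis, over the token's absolute index on that
axis) concatenated along the feature dimension.  The per-axis widths are the
three nearest even integers summing to the embedding dimension, so any even
embedding width ≥ 6 is admissible; this keeps both the 768-dim and the
1024-dim encoder presets, and the 64-dim desk preset, on one code path.
Rows for distinct grid coordinates are pairwise distinct.

## Mask sampling

Three strategies, all without replacement:

* **random** — tokens are drawn uniformly; the visible count is
  floor((1 − r)·N).  At r = 0.90 on 216 tokens this leaves 21 visible.
* **space-only** — a set of xy-columns is kept; kept columns are visible in
  every section.  Keeping 4 of 36 columns leaves 24 visible tokens, an
  effective ratio of 192/216 ≈ 88.9%.
* **section-only** — whole z-sections are kept or masked.  Keeping one of
  six sections gives a 5/6 ≈ 83.3% ratio.

Structured strategies take integer keep-counts because their feasible
ratios are quantized; a requested ratio is converted to the nearest feasible
count with ties broken toward more masking.

## The masked autoencoder

The encoder (a vanilla pre-norm ViT) runs on visible tokens only, so the
masking ratio directly scales its sequence length — at 90% masking the
encoder processes one tenth of the tokens.  The decoder is smaller than the
encoder (default depth 4, width 512): encoded tokens are projected to the
decoder width, scattered back into canonical grid order, every masked slot
is filled with one shared learned mask token (zero-initialized, optional
small-noise init), and decoder positional embeddings — the same fixed
sin-cos table passed through a learned linear projection to the decoder
width — are added before the decoder blocks.  A linear head predicts all
256 voxels of every patch.

The loss is the mean squared error between predictions and per-patch
normalized targets — each patch centered by its mean and divided by its
biased standard deviation plus 1e−6 — averaged over masked patches only.
Visible patches are never gathered into the loss, so their gradient is
identically zero (checked by autodiff in the acceptance suite).  For
visualization, masked voxels of the input rendering are set to 0.

Pre-training defaults follow the published schedule: AdamW with
β = (0.9, 0.95), weight decay 0.005, base learning rate 1e−4, linear warmup
then cosine decay to zero, batch 128, input 6×96×96, 400k iterations with
50k warmup.  Every value is overridable; desk-scale runs use the vit-micro
preset (depth 2, width 64, 4 heads; decoder depth 2, width 32) and hundreds
of iterations.  Pre-training applies no dropout.  Checkpoints store
weights, optimizer moments, the RNG state, the config and seed, and the
loss history, so a resumed run reproduces the exact next-step loss.

## Segmentation fine-tuning

For segmentation the MAE decoder is discarded and the encoder becomes the
backbone of a UNETR-style network.  Skip connections tap encoder blocks at
depths proportional to {1/4, 1/2, 3/4, 1} of the stack ({3, 6, 9, 12} for
depth 12; {1, 2} for the desk preset).  Because tokenization never
downsampled z, the convolutional decoder upsamples only in-plane: four
learned 2× sub-pixel (pixel-shuffle) stages take the token grid back to
voxel resolution, each followed by a 3×3×3 convolution, with tap features
projected and nearest-upsampled into the matching stage.  A convolutional
stem on the raw input feeds the final full-resolution stage.  The head
emits 3 channels for either target family.

Targets are generated on the fly from the augmented label crop:

* **Affinity maps** — channel c at voxel v is 1 iff v and its neighbor
  v − e_c carry the same nonzero label (nearest-neighbor offsets only;
  volume-boundary entries 0).
* **BCD maps** — foreground binary map; instance contour map (label changes
  over the 6-neighborhood, widened in-plane only; out-of-volume voxels are
  not treated as background, so instances cut by the crop face grow no
  contour there); per-instance Euclidean distance-to-boundary normalized to
  [0, 1] by each instance's maximum, so large and small instances
  contribute comparably.

Both BCE losses are class-rebalanced — positives and negatives each receive
half the total weight — following the reference affinity-training
configurations this design adopts; thin boundary classes are otherwise
drowned out.  The BCD loss adds an MSE term on the logistic-squashed
distance channel, all three terms equally weighted.  Augmentation: random
xy-flips, xy-transpose (square crops), z-flip, brightness/contrast jitter
and per-section intensity perturbation, each toggleable.  The published
fine-tuning schedules are the defaults (AdamW, lr 1e−4, weight decay 0.05,
5k warmup, 200k iterations, dropout 0.3, drop-path 0.1, batch 8; or the
SGD variant with lr 4e−3, weight decay 1e−4, 10k warmup, 300k iterations
and scales [1, 0.5, 0.5], which downsamples training volumes 2× in y and x
before cropping).

Inference is sliding-window: tiles of the training input size, blended by
weighted averaging with a raised-sine window; volumes smaller than a tile
are reflect-padded and cropped back.  All channels pass through a logistic
squashing, so outputs lie in [0, 1].

## Instance decoding

**Affinity → instances (zwatershed-style).**  Seeds are connected
components of the affinity graph restricted to edges ≥ t_high (computed by
sparse connected components).  Growth processes edges in decreasing
affinity down to t_low, never merging two distinct seeds; ties break by
edge raster index.  Voxels touching no edge ≥ t_low remain background.
Fragments smaller than min_size merge into their strongest-affinity
neighbor (falling to background if isolated), and fragment pairs whose
boundary mean affinity clears merge_threshold are merged greedily —
always the currently strongest pair, with boundary statistics recomputed
after every merge.  The fragment machinery runs on a region-adjacency
graph with O(degree) merges and a lazy priority queue, so decoding stays
around a second even on noisy soft predictions with thousands of
fragments.  Defaults: t_high 0.9, t_low 0.1, min_size 128,
merge_threshold 0.3 — community-typical values; on ground-truth (0/1)
affinities the result is threshold-insensitive.  Each affinity edge is
stored once (channel c at v encodes the edge to v − e_c); no reciprocal
averaging.

**BCD → instances (marker-based watershed).**  Markers are 6-connected
components of confidently-interior voxels (binary > θ_binary and
contour < θ_contour); flooding runs on 1 − distance (falling back to the
contour channel if the distance channel is empty) within the binary mask;
a size filter is applied last.  26-connected markers were rejected: they
leak diagonally across 2-voxel contour walls between touching instances.

Both decoders are deterministic, and output labels are canonicalized to
1..k by first-voxel raster order.

A structural note on BCD: at the wall between two *touching* instances the
binary/contour/distance representation is symmetric about the interface, so
wall voxels cannot be attributed to a side even from ground-truth maps.
BCD round-trips are therefore exact only for instances separated by
background (the organelle-style regime the representation was designed
for); on densely packed touching instances a small irreducible error
remains.  Affinity maps encode the interface explicitly and round-trip
exactly in both regimes.

## Evaluation

All pairwise metrics are computed from the voxel-count contingency table
between prediction S and truth T, restricted to truth-foreground voxels
(T ≠ 0, the SNEMI3D convention; configurable off).

* **Variation of information** VI = H(S|T) + H(T|S), entropies in natural
  log.  H(S|T) measures over-segmentation (split, Voi-S), H(T|S)
  under-segmentation (merge, Voi-M).
* **Adapted Rand error** = 1 − F, where F is the harmonic mean of pair
  precision (Σn_ij² − n)/(Σs_i² − n) and recall over (Σt_j² − n) — the
  distinct-pair counting convention of the SNEMI3D contest evaluation.
  Lower is better; 0 iff the partitions agree up to relabeling.
* **AP-50 / AP-75** — predicted instances ranked by voxel count (no
  per-instance confidence survives watershed decoding), matched greedily
  one-to-one to truth instances at IoU ≥ 0.5 / 0.75; AP is the area under
  the resulting precision-recall curve.  Undefined (NaN) when the truth
  has no instances.

## Synthetic volumes

The generator emulates the two structure classes of the downstream tasks:
neurite-like tubes (random-walk trajectories stamped with an anisotropic
brush, mostly in-plane motion with slow z-drift) and organelle-like
ellipsoids, both flattened in z (z semi-axis 0.4× the in-plane radius) so
objects span several sections but fewer voxels in z than in xy — the
geometric expression of the stack anisotropy.  Objects are packed without
overlap; stamps that earlier objects carve below 60% of their volume are
rejected (heavily carved remnants have thin necks that no longer resemble
cell bodies); each kept instance is a single 6-connected component spanning
≥ 2 sections, labeled consecutively from 1.  An optional `gap` keeps
background between instances (organelle-style isolation); by default
instances may touch (neurite-style packing).

Rendering is purely geometric: interface voxels (in-volume 6-neighbor label
changes, dilated in-plane to the membrane width, default 2 voxels) are
drawn dark (mean 0.15), interiors bright (mean 0.75) modulated by a smooth
low-frequency texture field, unclaimed background stays dark; Gaussian
noise (σ 0.05) is added and the image clipped to [0, 1].  The texture and
noise fields are drawn over the whole volume, so the image depends only on
label geometry — permuting instance ids changes nothing.  For default
parameters the foreground fraction lands in [0.2, 0.9].

What the generator does **not** emulate: real EM texture (organelle
ultrastructure, vesicles, synaptic densities), imaging artifacts (charging,
folds, section loss, misalignment), intensity drift between sections beyond
the jitter augmentation, and membranes of varying thickness or contrast.
Passing tests on this data therefore demonstrate that the pipeline's
machinery is correct and that pre-training transfers under controlled
conditions — not that any particular accuracy carries over to real tissue.

## The desk-scale transfer experiment

The headline property — pre-training beats training from scratch — is
checked at desk scale in the limited-annotation regime the paradigm
targets.  Per seed pair: two unlabeled 20×128×128 training volumes are
generated, of which only one 8×64×64 crop carries labels; validation uses
two held-out 12×96×96 volumes.  Geometry is coarse and separated
(radii 8–16, membrane width 2, gap 2): at a 300-iteration budget the
network learns foreground/background structure and coarse shape, not the
one-voxel boundary precision between touching processes that full-scale
training buys, so coarse geometry is what makes the decoded segmentations
informative at all.  A vit-micro MAE is pre-trained for 300 iterations
(random masking 0.9, batch 8) on the raw volumes; two segmentation models
are fine-tuned for 300 iterations (batch 2, affinity targets, no dropout —
a tiny model at a tiny budget needs no stochastic regularization) with the
identical seed, data order and decoder initialization, one from the
pre-trained encoder and one from scratch.  Both are scored by the mean
adapted Rand error of their zwatershed-decoded predictions over the
validation volumes.  Input crops are 6×64×64 and the base learning rate is
1e−3 with 30-iteration warmup and cosine decay — the published schedule's
shape with sizes a model this small can use in minutes on one CPU.

## Numerical choices and implementation notes

* The models and training loops run on a compact reverse-mode autodiff
  engine over numpy arrays written for this package (`stackmae.nn`):
  broadcasting arithmetic, batched matmul, softmax, row gather/scatter for
  token masking, a direct 3D "same" convolution, sub-pixel upsampling, and
  AdamW/SGD with the warmup + cosine schedule.  Gradients of every
  primitive and of composite blocks are tested against central finite
  differences.
* Per-patch normalization uses the biased standard deviation (ddof 0) with
  ε = 1e−6.
* LayerNorm ε 1e−6; GELU is the exact erf form; BCE on logits uses the
  softplus identity for stability.
* Watershed and union-find tie-breaks follow raster order; all decoders and
  training loops are deterministic given the seed (single worker).
* Checkpoints are single-file `.npz` archives (weights + optimizer moments
  + JSON metadata including RNG state).
* HDF5 and TIFF writes disable timestamps, so regenerating a dataset with
  the same seed is byte-identical.

## Known limitations

* The engine is CPU-bound and unvectorized across batch beyond BLAS; the
  full published schedules (400k iterations, batch 128, ViT-L) are out of
  desk-scale reach by design.
* Only nearest-neighbor affinities are produced; long-range affinities are
  out of scope.
* The BCD wall ambiguity above bounds achievable round-trip accuracy on
  touching instances.
* AP scores predicted instances by voxel count; a probability-aware score
  would require a decoder that propagates confidences.
* The desk-scale transfer comparison is stochastic; its margin is modest
  and individual seed pairs can tie or invert, which is why it is assessed
  over four seed pairs.
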