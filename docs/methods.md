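# Methods

## Problem and approach

Small lesions (long diameter below ~10 mm) are the hardest targets in
volumetric lesion segmentation: they occupy few voxels, offer few features,
and are easily lost by a single whole-volume network. `csrseg` implements a
coarse-to-fine fusion strategy for anisotropic 3D volumes (thin in-plane
voxels, thick slices, e.g. 0.6 x 0.6 x 5 mm liver MRI):

1. **Liver stage** — a 2.5D CSR-UNet segments the organ; everything outside
   is discarded so later stages see only hepatic tissue.
2. **Coarse stage** — a 3D CSR-UNet, run as overlapping sliding-window
   patches over the liver-masked, normalised volume, produces a foreground
   probability map. This stage is reliable for large lesions.
3. **Detection stage** — connected components of the (deliberately low)
   thresholded coarse probability map that measure **strictly under 30 mm**
   in-plane long diameter become candidate boxes, each snapped to a uniform
   64 x 64 x 5 crop about the component centroid. An adapter accepts boxes
   from any external detector in the same JSON schema, and a ground-truth
   oracle detector supports training and testing.
4. **Fine stage** — a 2.5D CSR-UNet re-segments each crop at full in-plane
   resolution, consuming a 5-slice slab per output slice.
5. **Fusion** — inside the union of detection boxes the fine result
   *replaces* the coarse result (so the fine stage can both recover missed
   lesions and delete coarse false positives); outside, coarse components
   are kept; the result is intersected with the liver mask. A `union` mode
   that only adds foreground is available, as is an option to drop sub-gate
   coarse components before fusion (`drop_small_coarse`, off by default:
   keeping them is the safer default when the detector misses a lesion the
   coarse stage found).

## CSR-UNet

The segmentation backbone is a U-Net whose convolution stages are **CSR
blocks**: two 3x3(x3) convolutions each followed by batch normalisation and
ReLU, then squeeze-and-excitation (SE) channel attention, plus a residual
shortcut (identity when channel counts match, otherwise a 1x1 projection):

    y = SE(relu(BN(conv(relu(BN(conv(x))))))) + shortcut(x)

SE pools each channel globally, passes the pooled vector through a
bottleneck MLP (hidden width `C / se_reduction`, minimum 1) and rescales
channels by the sigmoid gate. Encoder stages double channels from
`base_channels` with 2x max pooling; the decoder mirrors them with
kernel-equals-stride transposed convolutions and skip concatenations; a
final 1x1 convolution yields class logits. Operator ordering inside the
block (BN before activation, SE after the second convolution, residual add
after SE, no activation after the add) follows standard SE-ResNet practice.

Design notes:

* **2.5D variant** — slices as input channels (default 5), predicting the
  centre slice. Preferred whenever slice spacing is several times the
  in-plane spacing; used for the liver and fine stages. The coarse stage
  uses the 3D variant.
* **Anisotropy** — for 3D inputs with few slices, z pooling is disabled per
  stage once the remaining z extent would fall below 4 voxels
  (`plan_z_pooling`), so the slice axis never collapses before the
  bottleneck.
* **Arbitrary shapes** — inputs not divisible by the cumulative pooling
  factor are zero-padded internally and the logits cropped back; the output
  spatial shape always equals the input shape.
* Convolution layers feeding batch norm carry no bias (it would be
  cancelled by the normalisation and receive a zero gradient).

The tensor engine is a compact numpy implementation with explicit
forward/backward passes (shift-and-accumulate GEMM convolutions, exact
max-pool argmax routing, batch-norm train/eval modes with running
statistics), an Adam optimiser and cosine learning-rate annealing. Backward
passes are verified against central finite differences layer-by-layer, and
end-to-end by overfitting single samples to near-zero loss.

## Loss

Training minimises the focal Tversky loss on the softmax foreground
probability:

    TI = (sum p g + s) / (sum p g + alpha sum p (1-g) + beta sum (1-p) g + s)
    L  = (1 - TI)^gamma

with defaults `alpha = 0.7` (false-positive weight), `beta = 0.3`
(false-negative weight), `gamma = 0.75`, `smooth s = 1e-6`. With
`alpha = beta = 0.5, gamma = 1` the loss reduces exactly to soft-Dice loss;
`gamma < 1` steepens the loss near `TI -> 1`, which keeps gradient pressure
on the last hard voxels of small lesions. The loss is computed per sample
and averaged over the batch; its gradient clamps `1 - TI` at `1e-12` so the
focal exponent stays finite at perfection. An additive
focal-cross-entropy + Tversky combination is available
(`TverskyConfig(mode="focal_plus_tversky")`) but off by default.

## Preprocessing, patching and augmentation

* In-plane resampling to a fixed matrix (bilinear for images, nearest for
  labels; nearest provably introduces no new label values). Through-plane
  resampling to isotropic voxels is deliberately out of scope: lesions are
  handled at native slice spacing.
* Intensity: clip to the 0.5-99.5 percentile range (computed within the
  liver mask when available) and normalise affinely to [0, 1]. A constant
  region yields zeros with a logged warning rather than an exception, so an
  empty ROI cannot abort a batch pipeline.
* Patch planning: per-axis stride `floor(patch * (1 - overlap))` with the
  last start snapped to end exactly at the volume edge; the union of
  patches always covers every voxel (property-tested over random
  geometries). The overlap fraction (not fixed by the architecture) defaults
  to 0.5. Assembly is a weighted average; Gaussian weighting
  (sigma = patch/8, peak-normalised) is the default, uniform available.
* Training patches are foreground-biased: with probability `fg_patch_prob`
  (default 0.5) a patch is centred on a random lesion voxel — this is the
  "weight the positions the network must focus on" idea realised as
  oversampling, since no closed-form weighting is prescribed.
* Online augmentation: per-axis mirror flips with probability 0.5, in-plane
  rotations uniform in +-20 degrees (about the slice axis only, given 5 mm
  slices), and global intensity scaling uniform in (0.9, 1.1). The same
  spatial transform is applied to image (linear) and label (nearest).
* All indices are 0-based; patches and boxes are half-open
  `[start, start + size)`.

## Synthetic phantom

No public dataset accompanies the task the package addresses, so the
package ships a generator that emulates the *statistical structure* of a
delayed-phase liver MRI cohort: an ellipsoidal organ (default semiaxes
46 x 42 x 45 mm) of intensity 0.5 on a 0.1 background, containing
axis-aligned ellipsoidal lesions whose **in-plane long axis equals the
specified diameter** (centres snapped to voxel centres, so the diameter is
recoverable from the voxelised component to within one in-plane voxel
diagonal), additive Gaussian noise (default sigma 0.03), and anisotropic
spacing (default 1 x 1 x 5 mm; the generator accepts any spacing, e.g.
0.5938 x 0.5938 x 5.0 mm). Lesion through-plane semiaxes are capped at
12.5 mm — at 5 mm slices large lesions present as flat stacks — which also
keeps disjoint placement of several large lesions feasible. Intensities
live in [0, 1], matching the pipeline's normalised working range.

Cohort sampling draws exact per-bin lesion counts per case (default one
each of 5-10, 10-30, >30 mm) plus 0-2 extras in random bins, diameters
uniform within bins, contrast magnitudes uniform in [0.2, 0.35], and
benign/malignant tags at 45/55 (tags are provenance only; no per-type
intensity statistics are available to emulate, so contrast distributions
are free parameters). Placement rejection-samples centres from the
analytically eroded organ with a 200-retry cap and enforces at least one
background voxel between lesions (26-connectivity).

What the phantom does **not** model: MRI physics (coil bias, partial
volume, pharmacokinetics), multi-phase acquisition, lesion texture and
irregular margins, anatomy around the liver. Passing tests on phantoms
demonstrate that the machinery — geometry, bookkeeping, optimisation,
fusion logic — is correct and that refinement behaves as designed under
controlled contrast; they do not certify clinical-grade accuracy on real
images.

## Evaluation

Voxel metrics from exact confusion counts: Dice `2TP/(2TP+FP+FN)`, IoU
`TP/(TP+FP+FN)`, volumetric similarity `1 - |FP-FN|/(2TP+FP+FN)`;
empty-vs-empty is defined as 1. Lesion-wise evaluation stratifies ground
truth lesions by in-plane long diameter (per-slice Feret maximised over
slices, convex-hull accelerated, verified against brute-force pairwise
distances; a 3D Feret option exists) into bins [0,10) -> "5-10" (sub-5 mm
lesions cannot be quantified at 5 mm slices and fold into the smallest
bin), [10,30) -> "10-30", [30,inf) -> ">30".

Detection uses any-voxel overlap with greedy one-to-one assignment of
predicted components to GT lesions by descending overlap (an IoU floor is
configurable via `match_min_iou`); unmatched predictions are false-positive
detections. Recall and F1 are lesion-level (voxel-level F1 would duplicate
Dice). Per-lesion Dice/IoU are computed inside the lesion's bounding box
dilated by 5 voxels — localising the comparison so distant false positives
do not contaminate a small lesion's score — with voxels of other GT lesions
excluded from the window; bin rows average per-lesion scores
(lesion-averaged, not case-averaged) and pool detection counts.

## The scaled refinement study

`pipeline.refinement_experiment` (also run by `scripts/acceptance.py`)
trains the tumour stages at desk scale, sized to finish in minutes on one
CPU core: 30 phantoms of 96 x 96 x 20 voxels at 1 x 1 x 5 mm, 3-5 lesions
each; coarse 3D and fine 2.5D CSR-UNets with 8 base channels and depth 2;
20 epochs of Adam at lr 1e-3 with cosine annealing, batch 2, 10 steps per
epoch, training patches 48 x 48 x 16; 22 training / 8 held-out cases, the
liver stage bypassed with the ground-truth organ mask (organ segmentation
is independent of the refinement question). Reported: first/final-epoch
training loss, and size-stratified lesion recall/Dice/F1 of the coarse-only
versus fused predictions on the held-out cases. The study's claims are
inequalities (training converges; fusion does not hurt — and typically
helps — sub-10 mm recall and Dice; >30 mm recall is 1), not absolute
values: absolute performance at this scale is not comparable to a full-size
GPU training run (batch 16, 300 epochs, 192 x 192 x 80 patches, 5-fold
cross-validation), whose configuration remains available through
`TrainConfig`.

## Numerical and design choices

* Checkpoints store the model config JSON plus all weights and batch-norm
  running statistics in a single `.npz`; k-fold training keeps each fold's
  best-validation-loss weights; inference uses a single fold by default.
* The proposal detector consumes the coarse *probability* map (threshold
  0.1), not the binarised mask, so faint small lesions missed by the 0.5
  argmax still generate candidates; duplicate candidates (centroids within
  half a crop per axis) merge, keeping the higher score.
* Deterministic by construction: all randomness flows from explicit integer
  seeds through `numpy.random.default_rng`; identical seeds give
  bit-identical phantoms, splits, initial weights and training runs.
* Degenerate inputs: constant-intensity normalisation returns zeros;
  empty liver mask short-circuits to an empty prediction with no boxes;
  a box fully outside the grid is an error, a partially outside box is
  zero-padded.

## Known limitations

* The numpy training engine is single-threaded and desk-scale; it is not a
  performance substitute for GPU frameworks and larger `base_channels` /
  `depth` settings train slowly.
* The phantom's piecewise-constant lesions with clean ellipsoidal margins
  make segmentation easier than clinical data; held-out recalls near 1 on
  phantoms say nothing quantitative about clinical recall.
* The proposal detector is intentionally simple (threshold + connected
  components); it has no learned objectness and no FROC analysis. The
  external-box adapter exists precisely so a stronger detector can be
  plugged in.
* Tumour-type classification is out of scope; class tags in the phantom are
  provenance only.
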