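# Methods

## Problem and scope

Stomata — the guard-cell pore complexes on wheat leaf surfaces — are
phenotyped from 1600 × 1200 px micrographs by (i) semantic segmentation
into background (0), stoma (1) and pore (2), and (ii) mask-to-trait
morphometry: per-stoma length, width, area and per-field count. The
package implements the full pipeline: a synthetic micrograph generator
with exact ground truth, the Wheat Stoma Former (WSF) segmentation
network, its training regime, segmentation/agreement metrics and the
trait extractor, plus dataset bookkeeping and a CLI.

## Model

WSF follows the SegFormer template. An overlapping patch embedding
(7 × 7 convolution, stride 4, padding 3) feeds four transformer stages
with spatial-reduction self-attention (reduction ratios 8/4/2/1),
Mix-FFN blocks (an MLP with a 3 × 3 depthwise convolution) and 3 × 3
stride-2 overlapping merges between stages, producing a pyramid at
1/4, 1/8, 1/16 and 1/32 resolution with 64/128/320/512 channels in the
full preset. Inputs are intensity images in [0, 255], scaled to [-1, 1];
height and width must be divisible by 32 (the CLI `predict` command
reflect-pads and crops automatically; the library rejects non-divisible
inputs rather than padding silently).

Between encoder and decoder sits the cross-layer feature pyramid
transformer (CFPT). Published descriptions of this block are prose-level,
so its parameterization is this package's own design under the stated
contracts (shape preservation, pure-residual identity when output
projections are zero):

* lateral 1 × 1 convolutions align all levels to a common width, fused
  top-down FPN-style with bilinear upsampling;
* channel reconstruction (CR) pools/unpools every fused level onto the
  1/16 grid (average-pool down, nearest-neighbour up), where the maps
  are concatenated;
* cross-layer channel attention (CCA): channel tokens attend to each
  other using resolution-independent (mean, std) global descriptors as
  token features, with the full spatial maps as values;
* cross-layer spatial attention (CSA): multi-head self-attention over
  the grid positions of the merged stack;
* the four channel groups are redistributed to their native grids
  through zero-initialized 1 × 1 output convolutions and added to the
  input pyramid. A fresh CFPT is therefore exactly the identity and
  learns a refinement on top of it.

The all-MLP decoder projects each level to a common width (256 full /
64 tiny) with 1 × 1 convolutions, bilinearly upsamples everything to the
1/4 grid, concatenates, passes the stack through parallel MLP branches,
fuses with a 1 × 1 convolution, classifies, and upsamples the class
scores to input resolution, yielding an (H, W, K) logit map. Mask
readout is per-pixel argmax with ties broken toward the lowest class
index. All resampling is bilinear with `align_corners=False` semantics;
masks are always resampled nearest-neighbour.

The `tiny` preset (channels 16/32/64/128, depth 1 per stage, 64-channel
decoder, ~0.5 M parameters) exists for CPU-scale training and testing;
the `paper` preset (~15.7 M parameters) is the full architecture.

### Numerical backend

The network, backprop and AdamW run on an in-repo reverse-mode autodiff
engine over NumPy float32 arrays (`wsf.autodiff`, `wsf.nn`): broadcasted
arithmetic, batched matmul, grouped im2col convolution, bilinear/nearest
resampling, reductions and the pointwise nonlinearities. Gradients of
every operator are tested against central differences. Weights are
truncated-normal (σ = 0.02); biases zero; all randomness flows from
explicit integer seeds — there is no global RNG state anywhere in the
package.

## Training

The loss is `w_ce · CE + w_dice · (1 − mean soft Dice)` with default
weights (1, 1) and optional per-class CE weights; Dice uses smoothing
constant 1. Optimization is AdamW (β = 0.9/0.999, weight decay 0.01,
both configurable). The configured defaults mirror the reference regime:
initial learning rate 6 × 10⁻⁵, decay factor 0.8, batch size 8, 200
epochs. Two schedules are implemented: `epoch_decay` (lr × 0.8 after
every epoch) and `plateau` (× 0.8 when the smoothed validation loss has
not improved for 5 epochs), the default, since a strict per-epoch 0.8
decay shrinks the rate by ~10⁻¹⁹ over 200 epochs and cannot be the
operative schedule of a converged long run.

Bookkeeping records raw and exponentially smoothed (α = 0.1) train and
validation losses per batch and learning rate, pixel precision and MIoU
on the validation partition per epoch. k-fold splitting (default k = 5)
is available as an alternative to the 7:2:1 holdout; the holdout is the
default pipeline and k-fold operates over train+validation with the
test partition untouched.

The desk-scale runs used by the test suite and the acceptance script
train the tiny preset from scratch for 30 epochs on 64 synthetic
128 × 128 fields (16 held out) at learning rate 1 × 10⁻³ — the
conventional AdamW from-scratch rate; the 6 × 10⁻⁵ default is a
fine-tuning rate that presumes pretrained weights, which this package
deliberately does not ship.

## Synthetic data

`StomaFieldSpec` defaults emulate the study conditions: 1600 × 1200
fields with 19–23 stomata, long axes 100–140 px, short axes 55–80 px,
interior pores at 0.4 of the stoma axes, near-parallel row orientation
(±12° jitter), textured background (smoothed Gaussian noise), a linear
illumination ramp and pixel noise. Stomata are placed by rejection
sampling with an exact gap-dilated occupancy test, so objects are
pairwise disjoint and fully in frame; over-dense specifications raise.
Each stoma is rendered as two tangent guard-cell lobes flanking a
bright pore; the mask labels the full guard-cell-complex ellipse as
class 1 and the pore ellipse as class 2, so every pore pixel is interior
to its stoma ellipse and trait recovery against the generating
parameters is well defined. The `desk` preset (128 × 128, 2–3 stomata,
36–48/20–28 px axes, higher contrast) is the CPU-training fixture.

Augmentation applies rotation, scaling, flips, coarse-grid elastic
deformation and noise injection with identical geometric parameters to
image and mask; masks are resampled nearest-neighbour (labels stay in
{0, 1, 2} by construction and are re-validated), exposed regions fill
with background/median intensity, and multiples of 90° on square frames
take a lattice-exact path. The default expansion factor is 10
(1 source + 9 variants), matching a 1,260 → 12,600 dataset expansion.

What the generator does *not* model: epidermal cell walls, trichomes,
vein texture, focus gradients, specular highlights or optical blur of a
real microscope. Passing tests on this data demonstrate the correctness
of the pipeline's computations (shapes, losses, metrics, geometry,
recovery of known parameters), not field-condition segmentation
accuracy; headline accuracy on real micrographs is out of scope here.

## Traits

The mask is binarized (default stoma region = classes {1, 2}; pore-only
and stoma-only policies available), split into 8-connected components,
and components under `min_size` (default 50 px²) are dropped. Each
component's outer boundary is traced as the component minus its
4-connected erosion; on a binary image this coincides with a Canny edge
to within one pixel (asserted in tests). Length and width are the sides
of the minimum-area enclosing rotated rectangle, computed by rotating
calipers over the convex hull of the boundary pixels' corner points
(±0.5 px), so sides measure the rasterized extent rather than the
center-to-center span. Area is the component pixel count times
`pixel_area` (default 1, i.e. px² — no pixel↔µm calibration is assumed;
physical calibration is a user-supplied scalar). Count is the number of
retained components. Border-touching components are measured but
flagged. Touching stomata merge into one component — a documented
limitation of instance separation from a semantic mask; generated
fields are non-overlapping by construction.

## Metrics

Precision is micro accuracy-style: correctly classified pixels over all
evaluated pixels, all classes jointly. MIoU averages per-class IoU over
classes with non-empty union (avoiding 0/0 for absent classes). Dataset
evaluation pools pixel counts over all mask pairs at full resolution.
Agreement statistics are R² — identity-agreement convention by default
(residuals about y = x), with the regression convention also exposed —
and RMSE. Trait association is the Pearson correlation matrix with
two-sided p-values from the t transform on n − 2 degrees of freedom,
requiring complete, non-constant columns.

## Splitting

7:2:1 train/test/val with largest-remainder apportionment (ties toward
the earlier partition) and a seeded permutation. Grouped splitting
(default) assigns by source stem so augmented variants never straddle
partitions; ungrouped splitting reproduces splitting of an
already-expanded pool, where 12,600 samples yield exactly
8820/2520/1260.

## Problem sizes in tests and the acceptance script

Oracle suites use 16 × 16 mask pairs (200), 90 × 90 rasterized shapes
(100) against a 0.1° exhaustive rectangle search, and 20 clean 800 × 600
five-stoma fields with fixed 120/66 px axes for parameter recovery. The
training check is the tiny preset on 128 × 128 desk fields as described
above. Architecture shape contracts are exercised at 512 × 512 with the
full preset.

## Known limitations

* No GPU path; the NumPy backend is single-threaded per op and intended
  for desk-scale models, not 200-epoch full-resolution training.
* CCA/CSA follow this package's parameterization of the prose-level
  contracts; no claim is made of equation-level equivalence to any
  external implementation.
* The generator's intensity model is three-level with noise; models
  trained on it will not transfer to real micrographs.
* Elastic deformation uses a coarse displacement grid with linear
  interpolation; extreme σ values can fold space.
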