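# Methods

`treecensus` implements a multi-task deep-learning pipeline for
individual-tree inventory from high-resolution multiband aerial imagery:
counting by density-map regression, crown delineation by semantic
segmentation, and per-tree height estimation from optical bands, together
with the post-processing, bias-correction and field-plot evaluation steps
that turn raw network outputs into inventory-style numbers. Because such
imagery (and its LiDAR height references and field tables) cannot ship
with a software package, a synthetic-scene generator with exact ground
truth stands in for the data; everything downstream of the generator is
the real method.

## Counting by density maps

Each tree is represented by a truncated, unit-normalised Gaussian kernel
centred on its crown centroid. On the (2M+1)×(2M+1) support,

    G_{sigma,m}(p) = exp(-||p - m||^2 / (2 sigma^2)) / Z,

with Z the sum of the unnormalised kernel entries, so every tree carries
exactly one unit of mass; the density map D(p) is the sum of the kernels
of all C trees and its integral equals the count. Defaults sigma = 4 and
M = 7 (a 15×15 kernel). Kernels are evaluated only at in-image pixels:
a kernel crossing the border loses the off-image mass (training patches
are crops of larger scenes, so this loss is inherent), and the
count-conservation identity is exact only for centroids at least M pixels
from every border — which the scene generator guarantees by placement
margin. Crown centroids are polygon area centroids rounded to the nearest
pixel (round half up), keeping the kernel on the integer grid.

Counting by integrating the predicted density map is compared throughout
against the baseline of enumerating segmented crowns, which merges
adjoining trees into single components and systematically undercounts.

## Segmentation targets, gap maps and the weighted Tversky loss

Binary masks mark pixels whose centre falls inside any crown polygon.
Because adjacent crowns tend to merge in a semantic segmentation, the
narrow background corridors between crowns ("gaps") are up-weighted in
the loss. Gap construction: a background pixel is a gap pixel iff it lies
in the disc dilation (default radius 3 px, configurable) of at least two
distinct crowns — a symmetric rule, invariant to crown relabelling. Gap
pixels receive weight 5 by default, all other pixels weight 1.

The segmentation branch minimises the pixel-weighted Tversky loss

    l_seg = 1 - sum(w p0 g0) / (sum(w p0 g0) + alpha sum(w p0 g1) + beta sum(w p1 g0)),

a generalisation of 1 − Dice with separate false-positive (alpha) and
false-negative (beta) penalties; with uniform weights and
alpha = beta = 0.5 it reduces exactly to 1 − Dice. Defaults
alpha = 0.4, beta = 0.6 (false negatives slightly dearer); both are
config-exposed, as is the gap weight. The degenerate all-background /
all-background case is defined as loss 0. Raising the gap weight strictly
raises the loss whenever a gap pixel is misclassified and has no effect
when all gap pixels are correct — the mechanism by which a gap-penalty
sweep trades crown-area fidelity against crown separability.

The counting branch minimises the pixel-wise MSE between predicted and
target density maps. The total loss is l_seg + lambda_t * l_count with
lambda_0 = 100 by default and a nondecreasing linear ramp to a ceiling
(default 10^4) chosen so the two terms reach similar magnitude
mid-training. Validation losses are always evaluated at the final
epoch's lambda: comparing epochs under a moving lambda would
systematically favour early (small-lambda) epochs during model
selection.

One numerical choice matters for the counting branch. Raw density
targets peak around 5e-3 trees/pixel — three orders of magnitude below
the segmentation probabilities the trunk also serves — and regressing
them directly proved unstable in float32 (held-out count bias swung
between −26% and +60% across otherwise reasonable lambda schedules).
Training therefore supports a density target scale
(`ModelConfig.density_scale`; the desk-scale recipe uses 64, bringing
density peaks to ~0.3): targets are multiplied by the scale during
optimisation and predictions divided back to trees/pixel at inference,
so the counting identity is untouched. On scaled targets the count MSE
starts near the Tversky loss's magnitude, and the desk-scale lambda
ramp is correspondingly small (1 → 25).

The height network minimises a weighted MAE in which pixels whose
reference height is at least 10 m get weight 5 (tall trees are rare and
otherwise underpredicted); below the threshold the weight is 1.

## Architectures

Both networks are U-Nets with batch normalisation after every
convolution and additive attention gates on the skip connections
(gate = sigmoid(psi(relu(Wg·g + Wx·x))), applied at every decoder level;
`attention=false` gives the plain U-Net ablation). The dual-branch model
shares the whole trunk between tasks; only the final 1×1 projection heads
are task-specific — a sigmoid head for crown probabilities, a linear head
for the density map (its output is deliberately not clamped at zero:
negative ripples belong in the integral, and clamping would bias counts).
The height model is the same trunk with the final decoding block removed,
so its single linear head predicts at half the input resolution, matching
height references that are 2× coarser than the imagery. A
multi-resolution variant accepts extra coarse bands injected after the
first down-sampling step where the grids match.

Head projections are zero-initialised so that at the start of training
the density/height branches output exactly zero and the segmentation
branch probability 0.5; without this the randomly-initialised density
branch dominates the shared trunk's gradients under lambda_0 = 100.

The networks run on a small reverse-mode automatic-differentiation engine
written on numpy (`treecensus.nn`): vectorised elementwise ops,
stride-1 convolutions (im2col forward, per-tap einsum weight gradients),
2×2 max pooling, nearest-neighbour upsampling, batch norm and Adam.
Float32 is the working precision. Every structured op's analytic gradient
is tested against central-difference numerical differentiation. Training
is fully deterministic on CPU for fixed seeds.

## Training procedure

Random patches (default 256 px in the full-scale configuration; the
desk-scale runs use 64 px) are extracted at even offsets (so
half-resolution grids crop to co-located windows), standardised per
instance and per channel to zero mean and unit SD for the
counting/segmentation model, or globally with frozen training-set
statistics for the height model (constant channels map to zeros; a
zero-SD band in global statistics is an error). Augmentation applies
random horizontal/vertical flips to image and targets identically
(preserving the density integral exactly), and Gaussian blur and
brightness changes to the image only; random cropping is realised by the
patch sampling itself. Optimisation is Adam; the learning rate is not a
published quantity, so it is config-exposed (library default 1e-4; the
desk-scale recipe uses 3e-3, appropriate for its much smaller model).
Validation patches are drawn once before training and kept fixed; the
returned weights are those of the epoch with the lowest validation loss.
For the counting/segmentation model the validation criterion matters: the
pixel-wise density MSE is nearly blind to a systematic miscalibration of
the map's integral, which made the selected epoch's count bias essentially
random (measured swings of ±15% between adjacent late epochs). Model
selection for counting therefore uses full-scene validation patches (no
kernel mass clipped at patch borders) and adds a per-patch squared
count-error term to the validation loss (`make_count_seg_val_loss`); the
training loss itself is unchanged. The learning rate can decay linearly
to a final value (`final_learning_rate`), which damps the late-epoch
oscillation of the count calibration.
Scene-level train/validation splits are stratified by landscape regime
(4:1 by default). Fine-tuning support consists of checkpoint loading,
dataset mixing with integer oversampling of the smaller set (default
×5), and bilinear 2× up-sampling of coarser imagery — nothing more.

## Post-processing chain

Fixed order: threshold crown probabilities at 0.5 → connected components
(8-connectivity by default; the model solves semantic, not instance,
segmentation, so components are the instance notion) → polish away
segments under 2 px → expand each crown by d = alpha*sqrt(s/pi) with
alpha = 0.2 (raster dilation by round(d/pixel) with a disc element) →
per-tree height = 95th percentile (linear interpolation between order
statistics) of the height grid over the expanded crown, the height grid
having been upsampled to base resolution by nearest neighbour → drop
anomalies with max NIR > 80 yet height < 1 m (high NIR means vegetation;
a sub-metre "tree" with vegetation reflectance indicates a corrupt height
reference), and, in evaluation contexts, trees whose reference height is
below 1 m. Swapping polish and expand would let sub-threshold fragments
survive by inflation; the order is asserted in tests.

Tiled inference blends overlapping window predictions with a
raised-cosine edge taper; any positive taper satisfies the invariant that
a constant-input raster yields tiling-independent output. Tiles are
standardised per instance exactly as training patches were.

Two post-hoc linear corrections share one mechanism: fit prediction =
a·reference + b by OLS on validation data, then report
(prediction − b)/a. Applied to canopy heights (minibatch learning leaves
a systematic distortion) and to aggregate crown areas (gap up-weighting
intentionally shrinks predicted crowns, deflating large-area totals).

## Field-plot evaluation

Concentric-circle designs: Danish (3.5 m: all trees taller than 1.3 m;
10 m: dbh > 10 cm; 15 m: dbh > 40 cm) and Finnish (single 12.62-m
circle). Counts transfer between circles by the ratio of areas assuming
evenly distributed stems — 10 m to 15 m multiplies by (15/10)² = 2.25.
The two Danish reconstructions (extrapolate mid-size trees out to 15 m,
or scale large trees back into 10 m) are both provided. Tree-in-plot
membership is centroid inclusion with strict inequality at the boundary
(no published rule exists; the choice is config-visible). Plot-level
agreement is the relative bias, mean((pred − ref)/ref), positive for
overprediction.

## Evaluation metrics

R² = 1 − SS_res/SS_tot; MAE and rMAE = MAE / mean reference; relative
bias as above; overall bias = |Σ(pred − ref)| / |Σ ref| (aggregate-level,
lets per-sample errors cancel); MSE decomposition into squared bias
(mean(ref) − mean(pred))² plus mean squared variation, two nonnegative
terms summing exactly to the MSE; and pixel-level precision/recall/F1
with F1 equal to Dice. Segmentation quality is reported pixel-level (an
object-level IoU-matched PRF exists as a clearly separate helper but is
not used by the standard evaluations).

## The synthetic-scene generator

Scenes emulate 20-cm four-band orthoimagery: elliptical crowns (random
axis ratio 0.7–1.0, random orientation) with hemi-ellipsoid dome height
profiles, gradient shading, a cast shadow at a configurable sun offset,
background/crown colour palettes per regime, Gaussian sensor noise, and a
canopy-height band formed by exact 2×2 block averaging of the rendered
height surface. Placement patterns: deciduous = parent–offspring
clustering (clumped canopies), coniferous = jittered planting grid,
nonforest = sparse hedgerow-like rows. `overlap_fraction` controls the
share of crowns allowed to touch or overlap; at 0 a 2-px clearance is
enforced so rasterised crowns stay 8-disconnected. Crown NIR is kept
above 80 and background below 80 (clipped after noise) so the anomaly
filter's threshold is meaningful. Placement, texture and noise use
independent RNG streams: changing the noise level never moves a tree.
Placement margins keep every centroid at least M = 7 px inside the
border, so density-map count conservation is exact on generated scenes.

What the generator does **not** emulate: radiometric sensor physics,
view-angle and orthorectification displacement between image and height
data, species mixtures within a scene, understory vegetation, and
labelling ambiguity. Tests passing on these scenes therefore demonstrate
the correctness of the mechanisms (losses, targets, counting identity,
post-processing, evaluation), and that the architecture can learn the
task end-to-end — not performance on real forests.

## Desk-scale study conditions

The end-to-end check trains the dual-branch model (depth 3, base width 8,
~136k parameters) on 20 synthetic 128-px scenes (mixed regimes, 6–24
trees each, crown radii 0.8–2 m, 30% overlap allowed) with 64-px patches,
batch 8, 40 patches/epoch, 100 epochs, Adam at 3e-3, density scale 64 and
lambda ramping 1 → 25, and evaluates counting R², counting relative bias
and pixel F1 on 5 held-out scenes. These sizes are the package's desk-scale configuration;
the architecture scales to the full-size setting (256-px patches, deeper
and wider trunk, 1,500-epoch schedules) through the same configs.

## Known limitations

* The CPU engine is adequate for desk-scale models but orders of
  magnitude slower than a GPU framework; full-scale national mosaics are
  out of reach by design.
* alpha/beta of the Tversky loss and the exact lambda trajectory are not
  published quantities; the defaults here are documented choices, exposed
  in configuration.
* The gap-map construction rule (dilation-overlap, radius 3) is one
  reading of "morphological operations"; the rule and radius are
  config-exposed.
* Crown polygons exported from detections are unions of pixel squares,
  not smoothed outlines.
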