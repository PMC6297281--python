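# Methods

`sliceatlas` maps an ordered stack of 2D histological brain slices onto
a 3D reference atlas without ever reconstructing a volume from the
slices. The pipeline has three stages — plane localization, nonrigid 2D
registration, and structure-specific correction — plus a synthetic
phantom generator that supplies every input with exact ground truth.
This note records the model, the parameter choices and their reasons,
the numerical decisions, and what the synthetic experiments do and do
not demonstrate.

## Coordinate conventions

Volumes are stored `(z, y, x)` with `z` anterior→posterior (the slicing
axis), `y` superior→inferior, `x` left→right; a coronal plane is a
fixed-`z` section. The sectioning-angle difference is parameterized by
`alpha` (rotation about `y`) and `beta` (rotation about `x`), composed
alpha-first about the geometric center of the volume. Both angles are
small in practice, so composition order is a second-order effect, but
the same order is used in estimation and in the final reslice. 2D
geometry is carried in homogeneous `(row, col)` coordinates throughout.

## Similarity metric

The difference score `rho(a, b)` between two images is the summed
squared difference of block-normalized histogram-of-oriented-gradient
features at the same block coordinates: 9 unsigned orientation bins,
2×2-cell blocks, L2 block normalization with an `eps = 1e-4`
regularizer, and an intensity threshold (default 0.02 of a [0, 1]
scale) below which pixels contribute no gradient mass — this suppresses
the faint non-tissue halo around atlas planes. Block normalization is
what buys tolerance to uneven staining: multiplying one image by a
factor in [0.5, 2] changes `rho` by under 10% on phantom slices.

Cell size sets the tolerance/precision trade-off: a large cell (15 px
at the reference resolution of real atlas-scale data) makes the score
insensitive to small uncorrected distortions and is used for plane
matching; a small cell (4 px) is used inside the registration stage
where the point is to correct those distortions. The synthetic phantom
is generated at roughly half the linear scale of a real adult mouse
brain at 25 µm (its brain spans ~100–130 px rather than ~320–456 px),
so phantom studies use a proportionate 8 px localization cell; the
physical size of the descriptor relative to anatomy is what matters,
not the pixel count.

Half-slice scores restrict the feature sum to blocks fully inside the
half mask rather than multiplying the images by the mask, which would
inject identical artificial step edges into both images at the midline.

## Global pre-alignment

Before `rho` is computed, the moving slice is brought into the fixed
plane's frame with a similarity transform fitted in closed form
(Umeyama) on contour correspondences. Contours are extracted from
tissue masks, low-passed by keeping the lowest 16 Fourier descriptors,
resampled uniformly by arc length (100 points; 64 in the fast search
path), and described with Shape Context histograms (5 log-radial × 12
angular bins). Each point's descriptor concatenates an absolute-frame
histogram and a tangent-relative one: the absolute half anchors the
orientation on near-symmetric outlines (where tangent-relative views
repeat along the curve and matching would otherwise pick an arbitrary
cyclic shift), while the tangent half is rotation-invariant and lets a
genuinely rotated shape be followed. Because the absolute half still
biases the first match toward zero apparent rotation, the
correspondence is re-estimated on the transformed contour for up to
three rounds (one round in the search path, where slices are assumed
near-upright); the residual rotation shrinks geometrically.

An optional grid search over anisotropic horizontal/vertical rescaling
(`sx, sy ∈ {0.90, 0.95, 1.00, 1.05, 1.10}`, applied about the fixed
contour centroid, ties broken toward unity) absorbs directional
compression from sectioning; it is enabled for the final cost matrix
and the registration stage and skipped during the iterative angle
search for speed.

## Plane localization

For the selected slice subset `A`, a cost matrix scores every slice
against every coronal plane of the (rotated) atlas. Two physical
admissibility gates precede scoring: the similarity scale must lie
within [0.7, 1.4] of the known pixel-size ratio, and the plane's tissue
area within 3× of the slice's expected area. Without these gates the
score degenerates on nearly empty border planes (shrinking a slice onto
a small blob leaves both images with almost no gradient mass and a
spuriously low score).

A dynamic program then finds the monotone assignment minimizing the
summed score subject to a spacing constraint: the atlas index step
between consecutive selected slices must match the known physical
spacing within a relative tolerance `theta` (default 0.5, tolerating
2× local compression or stretch). The first selected slice may match
any plane. Predecessor ties break toward the spacing-ideal plane,
final-plane ties toward the smallest index. The DP is exact; tests
check it against exhaustive enumeration of all admissible monotone
mappings. Slices outside `A` get real-valued plane indices by
piecewise-linear interpolation over `A`, extrapolating the end
segments.

Two alignment modes trade speed for per-pair fidelity. The final cost
matrix aligns per pair, but only within a ±8-plane band around a
bootstrap location obtained with the cheap mode; outside the band the
bootstrap scores stand. The cheap (search) mode aligns each slice once
per reslice into the shared atlas frame — all planes live in one
coordinate system, so a single transform per slice suffices — against
a reference plane. The reference is found in two passes: first the
admissible plane of most similar tissue area, then, after a full-mask
DP pass, the plane the slice actually mapped to. The second pass
matters: a reference alignment error is shared across all planes of a
row, and an off-target reference masquerades as a tilt in the
half-slice statistics below.

### Sectioning-angle estimation

The angle about each axis is estimated from the half-slice index
difference `D`: map the two halves of every selected slice (upper/lower
for the rotation about `x`, left/right for the rotation about `y`)
separately and average the difference of matched indices. When the
atlas is under-rotated, structures in one half systematically match
more anterior planes than the other, so `D` crosses zero at the true
angle and its sign says which way to rotate. Under this package's axis
conventions the update direction is `-sign(D)` (the first-listed half
maps to smaller indices while under-rotated). The search steps in
1-degree increments, re-reslicing each time, until `D` flips sign, and
returns the flip-adjacent angle of smaller `|D|`. Rows where either
half holds less than 5% of the slice's foreground are excluded from
the average.

Because `D` for one axis is measured with the other axis held fixed, a
wrong first guess of one angle biases the other. The two 1D searches
are therefore alternated, warm-started from the previous estimates,
until neither changes (at most three rounds; later rounds typically
need two to four evaluations). The angle search runs on images
downsampled isotropically by `search_downsample` (all three volume
axes together — in-plane-only reduction would silently change the
rotation geometry); phantom studies use factor 1 since the phantom is
already generated at reduced scale.

## Foreground segmentation

Atlas planes and experimental slices are segmented into tissue and
background by exact minimization of a two-class energy: background
pixels pay their intensity, foreground pixels their distance to the
mean nonzero intensity, and neighboring pixels in different classes pay
`exp(-(i_p - i_q)^2)`, so cuts prefer high-contrast boundaries. The
pairwise term as printed does not carry an explicit different-class
indicator; it is read here as a submodular boundary penalty charged on
cut edges, which makes the energy exactly solvable by s-t min-cut
(capacities are scaled to integers with a scale adapted to image size;
agreement with exhaustive enumeration is asserted on tiny images).
Pixels inside the atlas annotation are clamped to foreground.

Cleanup follows the two published recipes: for atlas planes, discarded
tissue-intensity regions are restored when they survive a disk-20
morphological opening; for experimental slices the mask is smoothed by
a disk-3 opening and discarded regions above 50 px are restored. Holes
are filled and the largest connected piece kept.

## Coherency-aware multilevel MRF registration

Each slice, globally aligned into its matched plane's frame, is
registered to the plane by labeling a uniform control grid (16 px
spacing) with integer displacements. The annotation plane divides the
domain into coherent tissue and free space (ventricles + background).
Coherent nodes joined by a segment that crosses tissue only carry
tension edges with a spring cost — the squared norm of the difference
of their *cumulative* displacements. Free nodes (in hollow space but
moving tissue through their bilinear influence) have no tension and
are minimized independently; nodes influencing no tissue are fixed.

Three levels run at 4×, 2× and 1× downsampling. Displacement sets are
*carried*: at each level a node's candidates are its inherited motion
(bilinearly interpolated from the previous level and doubled with the
resolution, rounded to integers) plus a fresh offset from the integer
grid `[-8, 8]^2` — 289 labels, half the grid spacing. Evaluating the
spring on cumulative displacements means a stretch introduced at a
coarse level keeps costing energy at finer levels; a two-node
construction in the tests shows that resetting the carried motion (the
conventional multilevel scheme) changes the argmin.

Unaries use the translation approximation: the target patch (the
node's 32×32 influence support) is compared by HOG (cell 4) with the
source patch translated by the candidate cumulative displacement. The
full local-warp unary is not used in production — the approximation is
what makes 289 labels per node affordable — and its cost is that the
recovered per-node motion approximates the patch-averaged field, so
recovery error grows with within-patch field variation. Nodes whose
influence touches the experimental tissue outline switch to a
symmetric-difference unary in which the source tissue mask patch is
truly warped (bilinear, 0.5 threshold) rather than translated, since
translation cannot reduce a shape mismatch; such nodes are treated as
free (no tension edges), following the published reading. Structure
landmark pairs, when available, add a Euclidean point-distance term.
A slice-consistency term compares against the previous slice's
registered image (the previous slice resampled through the inverse of
its own final field; inversion by damped fixed-point iteration). For
the first slice the term is dropped and its weight folded into the
atlas term.

All terms are min-max normalized to [0, 1] per level; the pairwise
normalization is a joint min-max over all edge/label pairs computed in
closed form from the offset-grid extremes. Weights are
`(c_a, c_b, c_d, c_p) = (3, 1, 1, 5)`: the atlas term three times the
consistency and structure terms, the spring equal to the unary total.
The spring's own `lambda` is absorbed into `c_p` after normalization —
keeping both would double-parameterize one knob.

Coherent nodes are solved by sequential tree-reweighted message
passing. Messages for the quadratic pairwise are computed exactly in
`O(L)` per edge with a two-pass 1D lower-envelope distance transform
over the offset grid (a dense `L×L` path covers arbitrary label
subsets used by the tests). The implementation stops when the decoded
labeling's energy plateaus rather than tracking the TRW lower bound —
same cap of 50 sweeps, simpler bookkeeping, and the decoded energy is
the quantity the acceptance property constrains. ICM polishing then
runs from the better of the decoded and the zero-displacement
labeling, which guarantees the returned energy never exceeds the
zero labeling's. Displacements are integers at each level's
resolution; no sub-pixel refinement.

The recovered field is backward: `g(x) ≈ f(x + D(x))` maps the aligned
slice's frame into the plane. Registered slice images are produced by
resampling through the numerically inverted field.

## Structure correction

A squeezed hollow structure (aqueduct) can be smaller than a grid cell
and invisible to the MRF. Its outline is therefore corrected directly:
both contours (experimental, atlas) are split at their highest and
lowest points (ties resolved toward the contour centroid
horizontally), each half is sampled at 8 interior points uniformly by
arc length with a shared counter-clockwise traversal, and points are
paired by order. An exact thin-plate spline (r² log r kernel, affine
part, zero regularization — landmark counts stay below ~60) maps the
post-MRF structure positions onto the atlas contour, with grid nodes
in a 3-cell ring outside both structures added as identity anchors.
A 2-cell ring leaves ~1.1 px of far-field drift under a strong
squeeze; 3 cells bounds it at ~0.13 px. The TPS composes after the
MRF field (`T_total = TPS ∘ T_mrf`). Structure masks are an input —
the segmentation network that produced them in the original study is
out of scope, and the phantom generates them exactly.

## Phantom generator

The generator emulates a sectioning experiment with known truth. The
reference volume (default 64×144×120 voxels at 25 µm) contains a
brain-shaped ellipsoid, a bright boundary shell, 14 high-contrast
ellipsoidal "nuclei" whose short anterior-posterior extents make
neighboring coronal planes discriminable, band-limited texture, and a
dark ventricle tube with z-varying elliptical cross-section recorded
in a paired annotation (free labels: background 0 and the ventricle).

Stacks are manufactured by reslicing at the requested angles, dropping
planes whose preimage leaves the volume along z (partial end slices),
keeping every `step`-th plane to reach the slice thickness (default
twice the voxel size), and corrupting each slice with a random
rotation below 2.5°, translation below 10 px per axis, a smooth random
backward warp (coarse displacement grid, default spacing 48 px ≈
1.2 mm — slice-preparation distortion is smooth at the millimetre
scale and this bounds strain near 1/3 — with max displacement 8 px),
and a contrast factor in [0.7, 1.3]. Every transform is recorded;
`slice(x) = contrast · plane(A(x + U(x)))` reproduces each slice
exactly from its clean plane. The selected subset defaults to every
second slice, giving |A| ≈ 14 on a default stack, matching the subset
size the method is designed around (≈12 for sectional stacks).

What the phantom does *not* emulate: Nissl granularity and staining
texture, missing tissue, folds, tears, bubbles, inter-subject
anatomical variation, or the appearance gap between experimental
stains and the reference. Passing phantom studies therefore
demonstrates the geometry and optimization machinery — angle and plane
recovery, warp recovery, structure correction — under the stated
corruption model, not robustness to real histological artifacts.

## Problem sizes and evaluation

Synthetic studies run at the phantom's default sizes: ~27-slice
stacks, 144×120 planes, 10-slice-to-64-plane cost matrices during the
angle search. Angle recovery is evaluated over 20 random stacks with
angles uniform in [-8°, 8°]²; warp recovery over 10 random smooth
fields on a textured plane; both discrete optimizers are checked
against exhaustive oracles (the DP by pruned depth-first enumeration
of admissible mappings, the segmentation energy by vectorized
enumeration of all labelings of ≤ 4×4 images). Landmark errors are
reported in atlas pixels (1 px = atlas voxel size) with the boxplot
statistics (min, quartiles, median, max, mean). In-plane landmark
truth comes from the recorded per-slice transforms; the plane-index
error is reported separately in planes (= atlas voxels along z),
comparing rotated-grid z indices, which are shared between nearby
rotations about the common center up to sub-plane offsets.

## Known limitations

* Contour-based pre-alignment cannot recover in-plane rotation of a
  near-symmetric outline (the information is simply absent from the
  contour); slices are assumed near-upright, as in the sectioning
  protocol the method targets.
* The translation-approximation unary limits warp recovery when the
  true field varies substantially within a 32 px patch; recovery
  degrades gracefully (patch-averaged motion) rather than failing.
* Fixed background nodes pin the recovered field to zero outside
  tissue, so dense-field comparisons are only meaningful on tissue.
* The half-index angle statistic needs enough discriminable structure
  in each half; stacks of very few usable slices (|A| well below ~10)
  make `D` noisy and the 1-degree search may stop one step early.
* Field inversion is iterative and approximate; compositions with
  strong local TPS corrections are evaluated through the forward map
  where exactness matters.
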