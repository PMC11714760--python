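# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `grainmri`. It is the package's account of *why* each stage
works the way it does; the README covers *how* to run it.

## Problem setting

A seed-MRI scan is a 3D grayscale volume (nominally 0.04 mm isotropic
voxels after zero-filling; canonical grid 500x180x180 with axis 0 along the
grain). Cereal grains comprise four tissues that MRI contrasts reasonably
well: the embryo, the bulk starchy endosperm (bright), the thin
lipid-rich aleurone layer wrapping the endosperm, and the outer pericarp
(dim). The pipeline turns one scan of one or many grains into a table of
23 morphometric traits per grain: per-tissue volumes, convex volumes,
surface areas, aligned length/width/depth, crease depth, shape indices
(sphericity, solidity), tissue fractions, and — when bulk composition
percentages are supplied from external instruments — starch/lipid
enrichment factors (SEF = Gs x Ven, LEF = Gl x (Ve + Va), in percent x
mm^3; the percentages are deliberately not normalized).

## Grain phantoms (synthetic data)

Real annotated seed MRI is scarce, so every stage is validated against a
phantom family with exact ground truth: a superellipsoid body
(|x/a|^p + |y/b|^p + |z/c|^p <= 1, p in [2, 3]) carrying a pericarp shell
(2 voxels), an aleurone shell (3 voxels), an ellipsoidal embryo cap at the
low-length end (~18-30% of the length), and a parabolic ventral groove
(the crease, 4-8 voxels deep, 9-14 wide) carved upward from the analytic
lower surface along the full length. Default semi-axes (38, 22, 16)
voxels on a 112x72x72 grid — a grain scaled to roughly half the canonical
resolution so that a full pipeline run takes seconds, not minutes. The
canonical 500x180x180 / 200x180x180 shapes remain the defaults of
`PipelineConfig` for real data.

Two decisions matter for accuracy:

- **Posed rasterization.** A rotated phantom is produced by rotating the
  *coordinate grid* into the body frame and evaluating the implicit
  geometry there — no interpolation ever touches generated labels. Truth
  (class voxel counts, principal-axis extents, crease depth) is measured
  on a companion rasterization at the canonical pose.
- **On-grid truth.** Truth is counted on the voxel grid, not taken from
  continuous formulas; analytic values (sphere volume 4/3 pi R^3, area
  4 pi R^2) are used only as tolerance checks of the voxelization.

Intensity rendering assigns class means (background 10, embryo 150,
endosperm 220, aleurone 180, pericarp 60 — bright endosperm/aleurone, dim
pericarp, minimum class gap 30), adds Gaussian noise (default SD 3, i.e.
10% of the smallest gap), and corrupts whole cross-sections with
high-amplitude "faulty frame" noise (default probability 0.02 per slice,
amplitude 100), emulating the spurious frames real scans occasionally
contain. The generator does **not** emulate MR physics: no bias fields,
partial-volume ramps, relaxation contrast or resolution anisotropy.
Passing phantom tests therefore demonstrates correctness of the geometry
and learning machinery, not segmentation accuracy on scanner data.

## Semantic segmentation

Volumes are standardized (whole-volume z-score) before prediction.

**Compact U-Net (2D / 2.5D).** An encoder-decoder with three resolution
levels, a constant channel width per level, two 3x3 conv + ReLU blocks per
stage, 2x2 max pooling, nearest-neighbour upsampling followed by
convolution, skip connections by concatenation, and a 1x1 convolution to
five class scores. The 2.5D regime feeds 2k+1 consecutive cross-sections
(k = 10 by default, a sliding window along the length axis) as input
channels to predict the central slice, which couples adjacent slices and
yields visibly smoother reassembled surfaces than slice-independent 2D
processing. Training uses Adam (default learning rate 1e-3 at full scale;
the desk-scale experiments use 2e-3 with 16 channels), unweighted
categorical cross-entropy, batch size 64 by default, up to 100 epochs, and
returns the parameter state with the least validation loss. On-the-fly
augmentations (flips, small rotations, scaling, shifts,
brightness/contrast, Gaussian noise, faulty-frame corruption of stack
planes) are individually switchable; geometric transforms are applied
identically to input and target (nearest-neighbour on the target),
photometric ones to the input only.

The network and its backpropagation are implemented directly in numpy
(im2col convolutions, analytic gradients verified against finite
differences in the test suite). This keeps the package free of a deep
learning framework dependency and is entirely adequate at the problem
sizes the package targets for its built-in experiments: 64x64
cross-sections, 16 channels, a few hundred slices — about four minutes per
25-epoch 2D session on one CPU core. Edge slices replicate the
first/last plane so every stack has full depth. Argmax ties resolve to
the lowest class index; a constant input volume short-circuits to
all-background. Cross-sections must be divisible by 4 (two poolings).

**Fallback segmenter.** A deterministic, training-free oracle route:
nearest-class-mean intensity classification given a class intensity table,
followed by removal of per-class connected components below 20 voxels.
Preconditions demand class means separated by more than twice the
tolerance. On a zero-noise rendering it reproduces the source labels
exactly, which closes the loop phantom -> rendering -> segmentation ->
truth and isolates downstream stages from segmentation error.

**External 3D backend.** Self-configuring 3D frameworks are out of scope;
the `external3d` backend is an interface that consumes NIfTI label files
produced by such a tool (one `<sample>_seg.nii.gz` per input) and feeds
them into the same downstream stages.

**Dice.** Per class c, D_c = 2|P_c ∩ T_c| / (|P_c| + |T_c|); the summary
is the mean over the four tissue classes, ignoring background. A class
empty in both volumes scores 1 (correct absence) and is flagged.

## Instance separation

Each grain contains exactly one embryo, so embryo connected components
(26-connectivity, minimum 50 voxels to suppress speckle) provide one
marker per grain at the component centroid snapped to the nearest embryo
voxel. Instances grow outward by watershed on the negated Euclidean
distance-to-background transform restricted to foreground, so the
boundary between touching grains falls on the distance ridge. Foreground
components with no embryo are excluded as orphans (logged, never merged).
Each instance is centered in a fixed-size crop (200x180x180 at full scale,
96x64x64 in the built-in experiments) with the intensity carved under the
same mask.

## Canonical alignment

1. **Principal axes.** Foreground voxel coordinates are the data points;
   eigenvectors of their covariance, ordered by decreasing eigenvalue, map
   to (length, width, depth). The sign of the length axis is fixed by
   sending the embryo centroid to the low end. Near-spherical instances
   (top two eigenvalues within 1%) keep their input axes with a warning.
2. **Roll.** PCA leaves the roll about the length axis two-fold ambiguous
   (crease up or down). The default geometric estimator finds the crease
   profile of the central cross-section — the convex-hull deficiency,
   opened with a 3x3 square and restricted to its largest connected
   component — and returns the angle that rotates the profile centroid to
   the bottom (-axis 2, the chosen numeric meaning of "bottom"). A
   convex section yields 0 with a warning. A learned regressor with the
   output contract (cos θ, sin θ) — the encoding that avoids the
   -180/+180 discontinuity — can be plugged in instead; no trained
   weights ship with the package.

**Label resampling.** Rotating labels with nearest-neighbour
interpolation produced up to 2-voxel errors in recovered extents
(boundary jitter plus digitization phase mismatch). Labels are instead
resampled by linearly interpolating the five one-hot class indicators and
taking the per-voxel argmax — the class boundary stays at the
interpolated 0.5 level, and no invalid label values can appear — and the
foreground centroid is mapped onto an exact voxel center so the output
digitization has the same sampling phase as a body rasterized about a
voxel center. A 1e-3-voxel offset nudge breaks exact vote ties. With
this scheme, 19 of 20 random-pose phantoms recover all three dimensions
within 1 voxel and all recover tissue volumes within 2%.

## Traits: numerical choices

- **Volumes**: voxel count x r^3, exact by definition.
- **Convex volumes**: filled 3D convex hull with *voxel-center* vertices
  (`offset_coordinates=False`); with corner offsets the hull of a digital
  sphere is ~4.5% too large and solidity of convex bodies lands at 0.96
  instead of 1.
- **Surface areas**: marching cubes at level 0.5 on the zero-padded
  monolith (merged tissue classes — internal boundaries never contribute)
  or embryo mask, after Gaussian smoothing with sigma 0.8 voxels.
  Marching cubes on a raw binary mask overestimates curved surfaces by
  ~9% (staircase); with the smoothing, a digitized radius-20 sphere's
  area is within 0.5% of 4 pi R^2 and sphericity within 2% of 1. The
  trade-off is deliberate and documented: sharp polyhedral edges are
  rounded, so a 10-voxel cube measures ~14% below 6a^2. No single
  estimator is exact for both regimes (face counting is exact for the
  cube but 1.5x high for spheres); the smooth regime is the one grains
  occupy, so the estimator is anchored on the sphere limit.
- **Dimensions**: inclusive index span (max - min + 1) x r, matching the
  voxel-count volume convention for 1-voxel-thick objects.
- **Crease depth**: on the central cross-section (mid foreground index
  along the length, ties to the lower index), the axis-parallel distance
  from the section's lowest foreground row to the highest point of the
  crease profile. The 3x3 opening of the hull deficiency exists because
  digitized convex sections have 1-2 px boundary slivers that would
  otherwise masquerade as a crease.
- **Degenerate inputs**: an empty monolith is an error; an empty embryo
  yields NaN embryo traits with a warning; missing composition leaves
  SEF/LEF empty.

## Statistics layer

- **Correlations**: pairwise-complete Pearson r with two-sided P from the
  t transform with N-2 degrees of freedom (checked against
  `scipy.stats.pearsonr`); N is reported per pair because SEF/LEF may be
  missing where composition is absent.
- **Bland-Altman agreement**: bias = mean difference, limits of agreement
  = bias +/- 1.96 x sample SD (N-1), t-based 95% CI of the bias, relative
  differences d/b.
- **Normality**: D'Agostino-Pearson omnibus test with the rejection
  threshold fixed at P < 0.01, plus QQ pairs against fitted normal
  quantiles.
- **Sample size**: two-sample normal-approximation formula
  n = ((z_{1-alpha/2} + z_{power}) / (delta/sigma))^2 per group, rounded
  up (benchmark: effect 1.0, alpha 0.05, power 0.8 -> n = 8).
- **Clustering**: complete-linkage agglomeration on Euclidean distances
  between z-scored group-mean trait vectors; missing values are refused,
  never imputed.
- **PCA**: on z-scored columns; all components retained so explained
  variance ratios sum to 1.

## Problem sizes of the built-in experiments

The package's own experiments (test suite and `scripts/acceptance.py`)
run on 112x72x72 single-grain grids (96x64x64 instance crops), 3- and
16-grain packings on up to 112x288x288 grids, and U-Net sessions of 25
epochs with 16 channels on 4 training volumes of 96 slices at 64x64 — a
deliberate desk-scale configuration chosen so a complete validation run
finishes in minutes on one CPU core while exercising every code path at
realistic geometry ratios (shell thicknesses, crease proportions and
class contrasts match the full-scale setting; only the grid is scaled by
roughly half).

## Known limitations

- The phantom family is smooth and four-tissue; it does not model husks,
  awns, internal cavities, per-tissue texture, or contact deformation of
  tightly packed grains.
- Segmentation quality numbers on phantoms do not transfer to scanner
  data; the learned models shipped in experiments are for machinery
  validation, not production segmentation.
- Grains whose embryos merge into a single connected component are not
  split (no shape priors).
- Surface areas of sharp-edged (non-smooth) objects are systematically
  underestimated by the anti-staircase smoothing, as quantified above.
- The roll regressor route is an interface plus training contract; no
  pretrained weights are included.
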