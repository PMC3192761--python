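# Methods

## The reconstruction problem

Immunohistochemistry shows where a protein is expressed, but only on one
5-μm section at a time.  Whether a strand of CK19⁺ cells seen on a slide is
part of the intrahepatic bile-duct system or an isolated aggregation cannot
be decided in 2D: the connection may run obliquely through neighboring
sections.  `histo3d` reconstructs a stack of serially cut, stained and
photographed sections into a 3D volume and answers such questions two ways:

- **volumetric rendering** shows the raw stained colors in depth, with the
  slide background made transparent, and
- **segmentation-based surface rendering** turns labeled structures (vessel
  lumina, stained proteins) into explicit triangle meshes and component
  censuses, on which "connected to the ducts" becomes a well-defined
  adjacency query.

## Stack model and geometry

A stack is an ordered series of 24-bit RGB section images plus a manifest
with the physical metadata images cannot carry: pixel size (μm), section
thickness (μm), the cut index of every section, and the marker stained on
it.  Cut indices are 0-based and section *i* sits at depth *i* ×
thickness, so a stack of 50 sections at 5 μm spans 250 μm of tissue.
Sections lost during staining keep their index; the depth they occupied is
preserved (`z_extent` uses `(max_index − min_index + 1) × thickness`).  When
voxelizing, missing planes are skipped by default; a `nearest` gap policy
duplicates the nearest neighbor instead, trading duplicated data for exact
z geometry.  Nothing in the source protocol indicates lost sections were
duplicated, so skipping is the conservative default.

Marker interleaving — staining every *k*-th section with a given antibody —
is modeled by `marker_schedule(n, k, offset)`; with 50 sections and k = 10
each marker appears 5 times.

## Alignment

Each photograph lands in its own frame, so consecutive sections are related
by an unknown rotation + translation.  The model is strictly rigid: scaling
would corrupt the physical pixel size, and section-distortion correction is
out of scope.  The reference path is landmark-based: paired points on
consecutive sections fitted by 2D orthogonal Procrustes (centroids removed,
rotation from the SVD of the cross-covariance with reflections excluded),
reporting the residual RMS.  Pairwise transforms are chained into absolute
transforms with the first included section as the reference frame.
Resampling uses inverse mapping (bilinear for display images, nearest for
label masks) with pure-white fill, consistent with the background-whitening
convention downstream.  Rotation is parameterized about the image center,
which decouples the fitted angle from the translation the way manual
alignment behaves.

`auto_align_pair` is a convenience heuristic — phase correlation for the
shift plus a coarse angular search — and is documented as such; it does not
replace landmarks.

## Image editing

The interactive editing of the original protocol is replaced by
deterministic, logged operators so that runs are reproducible:

- `adjust_brightness_contrast`: `v′ = clip(slope·(v − 128) + 128 + offset)`.
- `whiten_background`: pixels within a per-channel tolerance (default 12) of
  the background color (supplied or estimated as the border-pixel mode) are
  set to pure white.  A homogeneous white background is what later maps to
  zero opacity.
- `remove_color_range_noise`: a color-range selection around a dark target,
  refined by morphological closing/opening, then small selected components
  (< `min_noise_size` px) whitened; larger same-colored regions — genuine
  stain — are kept bit-exactly.
- `invert_channels`: `v → 255 − v`; the same involution serves inversion
  before channel combination and re-inversion after.
- `resize`: the protocol's downsizing (1392×1040 camera frames → 696×520)
  is exact 2×2 block averaging, which halves dimensions, antialiases, and
  preserves the image mean to within half a gray level (block means rounded
  to nearest — resampling through PIL's BOX filter was rejected because its
  rounding biases the mean by ~0.5 gray level).  The "pixels per inch" of
  the original protocol is display metadata and never enters geometry.
- `to_grayscale`: ITU-R BT.601 luma (0.299/0.587/0.114).
- `enhance_lumina` darkens tissue so vessel lumina stand out, then whitens
  the lumina.  Darkening is a *ceiling clamp* — tissue pixels are limited to
  `round(contrast_slope·255)` per channel — rather than a multiplicative
  scale: the clamp is exactly idempotent (a second application is a no-op),
  never darkens a pixel already at 255, and its strength is still controlled
  by the slope parameter.  Keep the ceiling below the white threshold
  (default 245) or repeated application could reclassify bright tissue.

Defaults were chosen on phantom fixtures; the original protocol records no
numeric settings.  Whether weakly stained markers are darkened is a
per-marker config decision with no built-in heuristic.

## Volumetric rendering

The color-inverted stack becomes an RGBA grid: the opacity channel is
computed from the inverted colors, colors are re-inverted (alpha passes
through), and the grid is rendered orthographically.

The alpha rule is `A = max(R, G, B)` of the inverted colors.  The original
combination step computes alpha "automatically" with an unpublished formula,
so the rule here is an explicit convention: max-of-channels sends a
formerly pure-white pixel to exactly A = 0 and keeps any stain visible.
`luminance` and `mean` rules are selectable alternatives; none can be
validated against the original figures, and this is a documented limitation.

Voxel spacing defaults to (1, 1, 10) — the display convention that stretches
the thin stack tenfold in z; physical spacing (pixel size, pixel size,
thickness × sampling interval) can be attached instead, and is what mesh
measures use.  Compositing is standard front-to-back
(`C += (1−α_acc)·α_i·C_i`) in normalized [0, 1], re-quantized to 8 bits,
with early exit at accumulated opacity 0.999 and residual transmittance
filled with the background color.  MIP mode takes the per-ray maximum of
α-weighted color, with the background attenuated by the ray's maximum
opacity.  Oblique views ray-cast in physical coordinates with trilinear
sampling at steps of min(spacing)/2.  Orthographic only; no perspective,
no GPU path.

## Segmentation and connectivity

Thresholding assigns each voxel of a grayscale stack to the first matching
label spec ("dark" selects ≤ threshold, "bright" ≥ threshold); labeling is
exclusive per voxel, as in an interactive segmentation editor, with list
order as priority.  Manual per-section masks can add or erase a label.

Connected components use 6/18/26 adjacency, default **26**: with z voxels
ten times coarser than the plane — and a marker present only on every 10th
section — face-only adjacency would artifactually sever ducts crossing
sections obliquely.  When a marker is present only on a subsample of
sections, its connectivity is computed on that subsampled stack with
z-adjacency between consecutive sampled sections.

A stain component is **connected** to a reference region (e.g. the portal
vein/duct lumen) iff it overlaps the region or touches it under the chosen
adjacency — this is the package's formalization of "connected to the bile
ducts" vs. "aggregation without connection", which the source material never
defines quantitatively.  `filter_small` despeckles a label before surfacing.

## Surfaces

Each label's binary mask is meshed by marching cubes at iso-level 0.5
(zero-padded so boundary-touching components close), vertex coordinates
scaled by the spacing — micrometres when physical spacing is attached.
**No smoothing and no decimation, ever**: on a binary field every marching
cubes vertex lies exactly on a voxel-edge midpoint, and the tests assert
this half-grid property, so any smoothing step would be detected.  Mesh
measures report triangle count, area, enclosed volume (signed-tetrahedron
sum, only for closed meshes — `None` otherwise), closedness (every edge
bordering exactly two faces) and component count.  Marching cubes bevels
corners, so a 10³ cube measures a few percent under 1000 voxel-volumes;
tolerances in the tests (5% cube, 10% sphere) were measured on those
fixtures.  Export: PLY (binary or ASCII, with the label color as per-vertex
color), OBJ, STL.

## The phantom generator

The human tissue behind the original reconstructions is unavailable, so the
test substrate is synthetic: a recursive branching tube tree (trunk ≈ portal
vein, branches ≈ ducts; optionally an annular "ductal-plate" sleeve around
the trunk) rasterized into an isotropic 1-μm grid, with classes background /
tissue / lumen / stained wall / sleeve / detached body.  `detached_bodies`
places stained spheres away from the tree and inside the tissue envelope —
ground-truth isolated aggregations.  The grid is virtually sectioned: each
5-μm section takes, per pixel, the most salient class in its slab (stain >
lumen > tissue > background) and renders DAB-like brown stain (120, 70, 40)
over a pale hematoxylin-like counterstain (190, 175, 210) on a near-white
slide (248, 247, 245), plus per-channel Gaussian noise (default σ = 3 gray
levels) and Poisson-placed dark specks (default 20/mm²).  These colors and
noise levels are plausibility choices stated here, not measurements.
Per-section random rigid misalignment (centered Gaussians in shift and
angle) is applied on request, returning the exact correcting transforms.

All randomness flows from the seed; equal specs give bit-identical output.
Ground truth retained at every stage: the voxel class grid, the segment
topology with the stained-component/trunk incidence, per-section noise-free
class masks, and the misalignment transforms.

What the phantom does **not** emulate: real histology texture, staining
gradients and section-to-section intensity drift, tissue folds and tears,
section stretching, and out-of-plane deformation.  Passing tests therefore
demonstrate correctness of the computational protocol, not robustness to
every artifact of real material.

## Problem sizes and numerical choices

The test phantom is a 120 × 120 × 80 μm grid (1-μm voxels, 16 sections of
5 μm) with a depth-1 tree and one detached sphere — small enough that the
full suite runs in well under a minute while still exercising branching,
connectivity and meshing end to end.  Acceptance checks that need the
protocol's own numbers (50 sections, 1392 × 1040 frames) use those sizes
directly, as they cost milliseconds.  Tie-breaks and tolerances: component
ids are assigned largest-first; affine resampling parameters are rounded at
1e-12 to keep exact index remaps on-grid; compositing early-exits at
accumulated opacity 0.999; JPEG output uses quality 95 and is excluded from
bit-exactness promises (measured worst-case deviation ~45 gray levels on
sharp stain edges).

## Known limitations

- The alpha-combination formula of the original software is unpublished;
  the max-rule is a stated convention, not a validated reproduction.
- Rigid alignment only; no distortion correction.
- The auto-aligner's angular search is coarse (±5° by 0.5° default) and can
  fail on feature-poor sections; landmarks are the reference path.
- Connectivity verdicts depend on the chosen adjacency; 26-connectivity on
  anisotropic, subsampled stacks is permissive by design.
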