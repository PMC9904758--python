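# Methods

This note documents the models, conventions, and numerical choices
behind `histoatlas`, and what the synthetic-data tests do and do not
demonstrate about real histology.

## Coordinate conventions

Atlas volumes are stored on a fixed axis order: axis 0 medio-lateral
(increasing left→right), axis 1 anterior–posterior (increasing
posterior→anterior), axis 2 dorso-ventral (increasing ventral→dorsal).
Stereotaxic coordinates are millimetre offsets from a user-supplied
bregma voxel: AP positive anterior, ML positive toward the right
hemisphere, DV negative below bregma (so a typical injection target
reads like `+2.0 AP, ±0.5 ML, −2.0 DV`). NIfTI inputs are reoriented
into this convention from their header affine; oblique or unrecognised
orientations raise rather than guess. Atlas files do not store a bregma
reference, so the loader requires it explicitly;
`data/atlas_presets.yaml` ships configuration templates to fill in per
lab and atlas version.

Voxel indices are 0-based and fractional coordinates are allowed
everywhere. Two index conventions coexist deliberately:

* **label sampling** is nearest-neighbour, `rint(v)` — labels are
  categorical, and this matches how slices, trajectories, channels, and
  cells are localised;
* **point-in-voxel containment** (binning ROI points into voxels) uses
  the half-open extent `[i, i+1)`, i.e. `floor(v)`, with a 1e-7-voxel
  guard so points computed to land exactly on a voxel boundary do not
  floor into the neighbour through float error.

The synthetic-atlas generator follows the containment convention:
primitives are evaluated at extent centres `i + 0.5`. This keeps
analytic volumes honest — a (5, 4, 3)-semi-axis ellipsoid voxelises to
within 2% of `(4/3)πabc`, where node sampling is ~9% off at that size.

## Slicing

A slice plane is posed by an origin plus orthonormal in-plane unit
vectors `u`, `v` and normal `n` in the bregma-relative mm frame. Tilts
rotate the canonical pose about bregma-centred axes in a fixed,
documented order: first `tilt_a` about `u`, then `tilt_b` about the
rotated `v`, each limited to ±30° (the range supported for out-of-plane
sections). We tilt the *plane*, not the volume; the alternative view
differs only in sign convention. Pixel `(s, t)` of a slice sits at
`origin + s·px·u + t·px·v`; the default pixel size is the smallest voxel
dimension. `plane_covering_volume` shifts a plane in-plane so its
positive pixel quadrant covers the whole volume, keeping the per-pixel
contract intact on the shifted copy. Labels are sampled
nearest-neighbour, templates trilinearly; out-of-volume pixels carry
label 0 and a mask bit.

## Planning and channel counting

The insertion angle is reported as two projected tilts (lateral: ML over
DV; AP: AP over DV), both in degrees from vertical; a perfectly
horizontal path has no defined tilt and is rejected with guidance.
Region traversal samples labels at half the smallest voxel size by
default (a refinement test bounds the discretisation error), places
segment boundaries at midpoints between samples of differing label, and
trims leading/trailing background as outside-brain. Channels are points
at their centres — no site area model — at `tip + offset + i·pitch`
micrometres from the physical tip; channels sampling background are
excluded, which encodes the channel-less distal tip: an insertion
shallower than the tip length records nothing. Multi-shank rows
translate the base trajectory along an azimuth in the plane
perpendicular to the insertion; azimuth 0 is the projection of +ML onto
that plane (+AP when the insertion is parallel to ML), right-handed
about the insertion direction. Per-shank read-outs are computed
independently and also pooled, since both presentations are useful.

## Piecewise-affine registration

The warp is triangulated on the *source* (histology) anchors;
destination triangles inherit that connectivity, which keeps the forward
map single-valued even when the destination cloud would triangulate
differently. Each triangle's affine is the exact solve of its three
vertex correspondences, so the map interpolates the anchors to machine
precision and is continuous across shared edges by construction.
Containment is resolved by barycentric coordinates with a 1e-12 slack;
points on shared edges or vertices deterministically take the lowest
triangle index. Points outside the convex hull are returned unmapped
with a cleared mask bit — extrapolating an affine beyond its triangle
produces uncontrolled artifacts, and matched anatomy only exists inside
the anchored region. Crossed anchors ("fold-over", a destination
triangle with reversed orientation) warn at fit time; forward mapping
still works, but inverse queries through a fold are ambiguous and raise.
Image warping is inverse-mapping with bilinear sampling; coordinates
within 1e-6 px of the image border are snapped onto it because the
resampler treats even infinitesimal undershoot as out-of-bounds.

## Reconstruction

**Track fitting.** The fitted line is the first principal axis of the
centred click points (total least squares via SVD), oriented
dorsal→ventral; the tip is the deepest click projected onto the line;
the entry is the first background→brain label transition walking the
line into the volume at half-voxel steps. Clicks from multiple slices
are fitted jointly and the rms perpendicular residual is reported so
users can detect inter-slice misalignment. Post-hoc read-outs build a
trajectory from (entry, tip) and reuse the planner's traversal and
channel-count code path, so planning and reconstruction cannot drift
apart.

**Magic wand.** The selection is the connected component (4- or
8-connectivity) of pixels within `tolerance` of the *seed pixel's*
luminance — always the original seed value, never a running region
statistic, so granularity is controlled purely by the tolerance. RGB
images are reduced to Rec. 709 luminance first.

**ROI accumulation.** Selected pixels map through the slice's
registration (when present) and plane pose to 3D points; each point's
containing voxel joins the ROI, and a positive slab thickness claims
voxels within ±thickness/2 along the plane normal, stepped at one voxel.
The default thickness is 0 (no inter-slice interpolation): reconstruction
resolution is then set by how many sections the user includes.
Duplicates collapse in a set union, so overlapping slices never double
count and `volume = count × voxel volume` exactly. Per-region read-outs
report both the percentage of the region's total atlas volume covered
and the percentage of the ROI falling in the region — the two readings
of a "percent expressing" figure — ordered by overlap, background last.

**Meshes.** Binary volumes are meshed by marching cubes at level 0.5
with vertices scaled to mm; enclosed volume is computed by the
divergence theorem over signed tetrahedra and the Euler characteristic
as V − E + F.

## Synthetic data and what the tests show

The generator builds annotated volumes from axis-aligned boxes and
ellipsoids (last primitive wins, one-voxel background margin on every
face, deterministic per seed; the template is the brain mask plus 1%
seeded noise). Test atlases use 0.05 mm isotropic voxels. Probe-fit
recovery simulations use 10 clicks spread over a 5 mm insertion — a
typical silicon-probe track length — with isotropic Gaussian click noise
of 1 voxel; under those conditions the median direction error is well
under 1° and grows monotonically with noise.

These fixtures exercise every geometric and numerical contract exactly,
but they idealise real histology: sections are perfect planes (no
mounting distortion beyond what anchors model), anchor correspondence
noise is absent unless injected, tissue shrinkage from fixation is not
modelled (in practice it is absorbed by using multiple anchors per
slice), region boundaries are analytic rather than anatomical, and
fluorescence is a binary plateau rather than a graded halo. Passing
tests therefore certify the computations, not the biological error
budget of a given preparation.

## Degenerate inputs and tie-breaks

Fewer than 3 anchors, collinear or duplicate source anchors, fewer than
4 track clicks, coincident clicks, horizontal trajectories, empty mesh
masks, seeds outside the image, tilts beyond ±30°, and out-of-bounds
bregma voxels all raise a validation error naming the problem. Label ids
missing from the label table are reported as `unknown(<id>)` in
read-outs and as loader warnings, never errors. All CLI randomness flows
from a single `--seed`; project files serialise as sorted-key UTF-8
JSON, making the pipeline byte-reproducible.
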