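# histoatlas

Headless probe planning, histology-to-atlas registration, and 3D
reconstruction for rodent brains.

Systems-neuroscience experiments need two anatomical bookends: before
surgery, stereotaxic coordinates and insertion angles that put an
electrode or injection pipette into the intended structures; after the
experiment, an objective record of where the probe, viral expression, or
labelled cells actually ended up, registered to a reference atlas.
`histoatlas` is a scriptable library + CLI covering that workflow against
annotated volumetric atlases (Waxholm rat, Allen mouse CCF, or any
NIfTI annotation volume with a label table), with a synthetic-atlas
generator so everything runs and tests without downloading an atlas.

## What it computes

**Probe planning.** Given entry and target points in bregma-relative
stereotaxic coordinates (AP, ML, DV in mm), a trajectory's insertion
length is the Euclidean distance `‖tip − entry‖` and its insertion angle
is decomposed into two projected tilts from vertical,

    lateral tilt = arctan(|ΔML| / |ΔDV|),   AP tilt = arctan(|ΔAP| / |ΔDV|).

Region traversal samples atlas labels along the path and merges runs
into ordered segments. Channel counts honour the channel-less shank tip
of silicon probes: channel *i* of a probe with tip length *L*, first
channel offset *o*, and pitch *p* sits at distance `L + o + i·p` from the
physical tip (175 µm tip and 20 µm pitch for a Neuropixels-style layout),
and only channels whose sampled label is non-background count. Multi-shank
probes replicate the trajectory across a user-defined shank row.

**Slicing.** Coronal/sagittal/horizontal planes, optionally tilted up to
±30° about the two in-plane axes, are extracted with an exact pixel↔voxel
coordinate contract (`point(s,t) = origin + s·px·u + t·px·v`); labels are
sampled nearest-neighbour, the intensity template trilinearly.

**Registration.** Clicked anchor pairs between a histology image and an
atlas slice define a triangulation-based piecewise-affine warp: the
source points are Delaunay-triangulated and each triangle carries the
unique affine sending its vertices exactly onto their partners —
continuous across edges, exact at the anchors, invertible per triangle.
Whole images are warped by inverse mapping with bilinear sampling.

**Reconstruction.** Probe tracks are total-least-squares line fits
through ≥4 clicked points (first principal axis of the centred points),
with the brain entry located by walking the line through the annotation
volume. Viral expression is delineated per slice with a tolerance
flood-fill ("magic wand"), accumulated across slices into an atlas-voxel
set, and quantified per region (voxel counts, % of region volume, % of
ROI). Cell points import from CSV and are assigned to regions; binary
volumes export as marching-cubes triangle meshes.

## Worked example

Plan a 384-channel probe through a three-region synthetic atlas:

```python
from histoatlas import (StereotaxicCoord, ProbeGeometry, make_synthetic_atlas,
                        plan_trajectory, traverse_regions, trajectory_readout)
from histoatlas.planner import count_channels
from histoatlas.reports import render_text

spec = {
    "shape": (60, 60, 60),
    "voxel_size_mm": (0.05, 0.05, 0.05),
    "bregma_voxel": (30, 30, 55),
    "primitives": [
        {"kind": "box", "label": 1, "lo": (5, 5, 5), "hi": (55, 55, 46), "name": "deep nucleus"},
        {"kind": "box", "label": 2, "lo": (5, 5, 30), "hi": (55, 55, 40), "name": "intermediate layer"},
        {"kind": "box", "label": 3, "lo": (5, 5, 40), "hi": (55, 55, 46), "name": "surface cortex"},
    ],
}
atlas, labels = make_synthetic_atlas(spec, seed=0)
traj = plan_trajectory(StereotaxicCoord(ap_mm=0.0, ml_mm=0.3, dv_mm=0.0),
                       StereotaxicCoord(ap_mm=0.0, ml_mm=-0.3, dv_mm=-2.0), atlas)
geom = ProbeGeometry(n_channels=384, channel_pitch_um=20.0, tip_length_um=175.0)
report = trajectory_readout(traj, traverse_regions(traj, atlas),
                            count_channels(traj, geom, atlas), labels)
print(render_text(report))
```

prints

```
Probe plan read-out
===================
entry (AP, ML, DV) mm : (+0.000, +0.300, +0.000)
tip   (AP, ML, DV) mm : (+0.000, -0.300, -2.000)
lateral tilt          : 16.7 deg
AP tilt               : 0.0 deg
insertion length      : 2.088 mm
channels in brain     : 71

  region  name                          length_mm  channels
       3  surface cortex                    0.312        15
       2  intermediate layer                0.525        26
       1  deep nucleus                      0.751        30
```

The trajectory slants 16.7° laterally (0.6 mm of ML travel over 2 mm of
depth); of 384 channels, 71 sit below the brain surface — none in the
distal 175 µm tip, which is channel-less — split across the three regions
in traversal order.

The same stages run from a shell (see `histoatlas --help`):
`synth-atlas`, `atlas-info`, `slice`, `plan`, `register`, `warp`,
`reconstruct-probe`, `wand`, `roi`, `cells`, `mesh`, `report`.

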