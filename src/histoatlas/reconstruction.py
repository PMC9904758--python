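"""Post-hoc 3D reconstruction from registered 2D selections.

After histology sections are registered to atlas slices, this module
turns 2D user input into atlas-space objects:

* probe tracks — a total-least-squares line through >= 4 clicked points,
  with the brain entry point located by walking the line into the brain;
* labelled volumes (e.g. viral expression) — tolerance flood-fill
  ("magic wand") selections accumulated slice by slice into a voxel set,
  quantified per region;
* imported cell points assigned to regions;
* triangle meshes of binary masks via marching cubes.

Reconstruction read-outs reuse the planner's traversal/channel-count
code path, so a track reconstructed from noiseless clicks along a
planned trajectory reproduces the plan's report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .atlas_core import (
    AtlasVolume,
    LabelTable,
    StereotaxicCoord,
    containing_voxel,
    sample_labels,
    stereotaxic_to_voxel,
    voxel_to_stereotaxic,
)
from .errors import ValidationError
from .planner import PlanReport, ProbeGeometry, Trajectory, count_channels, trajectory_readout, traverse_regions
from .registration import PiecewiseAffineMap, map_points
from .slicer import SlicePlane

__all__ = [
    "ClickedPointSet",
    "ProbeFit",
    "ROIVolume",
    "CellPointSet",
    "fit_probe_track",
    "probe_readout",
    "magic_wand",
    "accumulate_roi",
    "region_overlap",
    "assign_cells",
    "extract_mesh",
    "mesh_volume",
    "mesh_surface_area",
    "mesh_euler_characteristic",
]

MIN_TRACK_POINTS = 4  # clicked points required for a track fit


@dataclass
class ClickedPointSet:
    """User clicks on registered slices: (slice_id, s, t) plane coordinates."""

    points: list[tuple[str, float, float]]
    planes: dict[str, SlicePlane]

    def positions_mm(self) -> np.ndarray:
        """Resolve every click to a 3D (ML, AP, DV) mm position."""
        out = []
        for slice_id, s, t in self.points:
            if slice_id not in self.planes:
                raise ValidationError(f"slice id {slice_id!r} has no stored plane")
            out.append(self.planes[slice_id].point_at(np.float64(s), np.float64(t)))
        return np.asarray(out, dtype=float)


@dataclass
class ProbeFit:
    """Total-least-squares line through clicked probe-track points."""

    point: np.ndarray  # a point on the line (centroid), mm
    direction: np.ndarray  # unit, oriented dorsal -> ventral
    rms_mm: float
    entry: StereotaxicCoord
    tip: StereotaxicCoord
    n_points_used: int


def fit_probe_track(points: ClickedPointSet | np.ndarray, atlas: AtlasVolume,
                    planes: dict[str, SlicePlane] | None = None) -> ProbeFit:
    """Fit a 3D line to clicked probe-track points and locate entry and tip.

    The line is the first principal axis of the centred points (total
    least squares), oriented dorsal -> ventral.  The tip is the
    projection of the deepest click onto the line; the entry is the first
    background -> brain label transition walking the line from outside
    the volume toward the tip, sampled at half-voxel steps.
    """
    if isinstance(points, ClickedPointSet):
        xyz = points.positions_mm()
    else:
        xyz = np.atleast_2d(np.asarray(points, dtype=float))
    if len(xyz) < MIN_TRACK_POINTS:
        raise ValidationError(
            f"probe track fitting requires a minimum of {MIN_TRACK_POINTS} clicked points, got {len(xyz)}"
        )
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    if np.allclose(centered, 0):
        raise ValidationError("clicked points are all coincident")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction[2] > 0:  # orient dorsal -> ventral (decreasing DV)
        direction = -direction
    proj = centered @ direction
    rms = float(np.sqrt(np.mean(np.sum((centered - proj[:, None] * direction) ** 2, axis=1))))

    tip_pt = centroid + proj.max() * direction  # deepest click, projected

    # walk from outside the volume toward the tip at half-voxel steps
    step = min(atlas.voxel_size_mm) / 2
    extent = float(np.linalg.norm(np.asarray(atlas.shape) * np.asarray(atlas.voxel_size_mm)))
    depths = np.arange(-extent, proj.max() + step, step)
    walk = centroid + depths[:, None] * direction
    vox, _ = stereotaxic_to_voxel(walk, atlas)
    labels = sample_labels(atlas, vox)
    nonzero = np.nonzero(labels)[0]
    if len(nonzero) == 0:
        raise ValidationError("fitted line never enters the brain")
    entry_pt = walk[nonzero[0]]
    return ProbeFit(
        point=centroid,
        direction=direction,
        rms_mm=rms,
        entry=StereotaxicCoord.from_xyz(entry_pt),
        tip=StereotaxicCoord.from_xyz(tip_pt),
        n_points_used=len(xyz),
    )


def probe_readout(fit: ProbeFit, geometry: ProbeGeometry | None,
                  atlas: AtlasVolume, labels: LabelTable | None = None,
                  step_mm: float | None = None) -> PlanReport:
    """Region/channel read-out for a reconstructed track.

    Builds a trajectory from the fitted entry and tip and delegates to
    the planner, so planning and post-hoc reconstruction share one code
    path.
    """
    traj = Trajectory(entry=fit.entry, tip=fit.tip)
    traversal = traverse_regions(traj, atlas, step_mm=step_mm)
    channels = count_channels(traj, geometry, atlas) if geometry is not None else None
    return trajectory_readout(traj, traversal, channels, labels)


# ---------------------------------------------------------------------------
# Magic wand and ROI accumulation

def _luminance(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        return rgb @ np.array([0.2126, 0.7152, 0.0722])
    raise ValidationError(f"expected a 2D gray or RGB image, got shape {image.shape}")


def magic_wand(image: np.ndarray, seed_xy, tolerance: float,
               connectivity: int = 4) -> np.ndarray:
    """Tolerance flood-fill from a clicked seed pixel.

    Selects the connected component (4- or 8-connectivity) of pixels
    whose luminance differs from the *seed pixel's* value by at most
    ``tolerance`` — the comparison is always against the original seed
    value, never a running region statistic, so the selection granularity
    is controlled purely by the tolerance.  ``seed_xy`` is (x, y) =
    (column, row).
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    lum = _luminance(np.asarray(image))
    x, y = (int(c) for c in seed_xy)
    h, w = lum.shape
    if not (0 <= y < h and 0 <= x < w):
        raise ValidationError(f"seed {seed_xy} outside image of shape {(h, w)}")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    within = np.abs(lum - lum[y, x]) <= tolerance
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labeled, _ = ndimage.label(within, structure=structure)
    return labeled == labeled[y, x]


@dataclass
class ROIVolume:
    """Atlas voxels accumulated from per-slice delineations."""

    voxels: np.ndarray  # (n, 3) unique integer voxel indices
    voxel_size_mm: tuple[float, float, float]
    slice_ids: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.voxels)

    @property
    def volume_mm3(self) -> float:
        return self.count * float(np.prod(self.voxel_size_mm))


def _unique_rows(a: np.ndarray) -> np.ndarray:
    if len(a) == 0:
        return a.reshape(0, 3)
    return np.unique(a, axis=0)


def accumulate_roi(masks, atlas: AtlasVolume, slab_thickness_mm: float = 0.0,
                   registrations=None) -> ROIVolume:
    """Project per-slice binary masks into a single 3D voxel set.

    ``masks`` is a list of ``(mask, plane)`` or ``(mask, plane, pw_map)``
    tuples.  Without a registration map, ``mask`` lives on the slice's
    own pixel grid, indexed ``[s, t]`` like a ``Slice2D.label_image``.
    With a registration map, ``mask`` lives over histology image pixels
    (indexed ``[row, col]``); each selected pixel ``(x, y) = (col, row)``
    is mapped forward into the atlas-slice image frame, where image rows
    correspond to ``s`` and columns to ``t`` (so slice coordinates are
    ``(s, t) = (y', x')``).  Each mapped point's containing voxel joins
    the ROI; a positive ``slab_thickness_mm`` additionally claims voxels
    within +/- thickness/2 along the plane normal.  Duplicates across
    slices collapse (no double counting).
    """
    if slab_thickness_mm < 0:
        raise ValidationError("slab_thickness_mm must be >= 0")
    shape = np.asarray(atlas.shape)
    all_vox = []
    slice_ids = []
    for item_idx, item in enumerate(masks):
        if len(item) == 2:
            mask, plane = item
            pw_map = None
        else:
            mask, plane, pw_map = item
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            continue
        if pw_map is not None:
            pix = np.column_stack([cols, rows]).astype(float)  # (x, y) clicks
            mapped, in_hull = map_points(pw_map, pix, direction="forward")
            mapped = mapped[in_hull]
            if len(mapped) == 0:
                continue
            st = np.column_stack([mapped[:, 1], mapped[:, 0]])  # (s, t) = (y', x')
        else:
            st = np.column_stack([rows, cols]).astype(float)  # already [s, t]
        pts = plane.point_at(st[:, 0], st[:, 1])
        if slab_thickness_mm > 0:
            step = min(atlas.voxel_size_mm)
            half = slab_thickness_mm / 2
            offsets = np.arange(-half, half + step / 2, step)
            pts = (pts[None, :, :] + offsets[:, None, None] * plane.n).reshape(-1, 3)
        vox_f, _ = stereotaxic_to_voxel(pts, atlas)
        vox = containing_voxel(vox_f)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        all_vox.append(vox[ok])
        slice_ids.append(str(item_idx))
    voxels = _unique_rows(np.concatenate(all_vox) if all_vox else np.empty((0, 3), dtype=np.int64))
    return ROIVolume(voxels=voxels, voxel_size_mm=atlas.voxel_size_mm, slice_ids=slice_ids)


def region_overlap(roi: ROIVolume, atlas: AtlasVolume,
                   labels: LabelTable | None = None) -> list[dict]:
    """Per-region overlap read-out for an ROI, ordered by overlap descending.

    For each region label present in the ROI, reports the overlapping
    voxel count, the percentage of that region's total atlas volume
    covered, and (to remove ambiguity) the percentage of the ROI falling
    in that region.  ROI voxels on background (label 0) are reported as a
    separate ``background`` row at the end.
    """
    if roi.count == 0:
        return []
    vox = roi.voxels
    roi_labels = atlas.annotation[vox[:, 0], vox[:, 1], vox[:, 2]]
    region_sizes = np.bincount(atlas.annotation.ravel())
    rows = []
    background_row = None
    for lab in np.unique(roi_labels):
        overlap = int(np.sum(roi_labels == lab))
        row = {
            "label_id": int(lab),
            "name": labels.name(int(lab)) if labels else f"unknown({int(lab)})",
            "color": list(labels.color(int(lab))) if labels else [128, 128, 128],
            "overlap_voxels": overlap,
            "percent_of_region": 100.0 * overlap / region_sizes[lab] if lab != 0 else None,
            "percent_of_roi": 100.0 * overlap / roi.count,
        }
        if lab == 0:
            row["name"] = labels.name(0) if labels else "background"
            background_row = row
        else:
            rows.append(row)
    rows.sort(key=lambda r: (-r["overlap_voxels"], r["label_id"]))
    if background_row is not None:
        rows.append(background_row)
    return rows


@dataclass
class CellPointSet:
    """3D cell positions (mm, bregma-relative) with optional group tags."""

    positions_mm: np.ndarray  # (n, 3) as (ML, AP, DV)
    groups: list[str] | None = None

    def __post_init__(self):
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if not np.all(np.isfinite(self.positions_mm)):
            raise ValidationError("cell positions must be finite")
        if self.groups is not None and len(self.groups) != len(self.positions_mm):
            raise ValidationError("one group tag per cell required")

    @staticmethod
    def from_csv(path) -> "CellPointSet":
        """Read cells from CSV with header ``x_mm,y_mm,z_mm[,group]`` or
        ``x_voxel,y_voxel,z_voxel[,group]`` (voxel input needs an atlas to
        convert — use :meth:`from_csv_voxels`)."""
        import csv

        with open(path) as fh:
            reader = csv.DictReader(fh)
            pos, groups = [], []
            for row in reader:
                pos.append([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
                groups.append(row.get("group", ""))
        tags = groups if any(groups) else None
        return CellPointSet(positions_mm=np.asarray(pos), groups=tags)


def assign_cells(cells: CellPointSet, atlas: AtlasVolume,
                 labels: LabelTable | None = None) -> dict:
    """Count cells per region (and per group tag when tags are present).

    Each point is labelled by nearest-neighbour voxel sampling;
    out-of-brain points are counted under label 0.
    """
    vox, _ = stereotaxic_to_voxel(cells.positions_mm, atlas)
    labs = sample_labels(atlas, vox)
    groups = cells.groups if cells.groups is not None else [""] * len(labs)
    counts: dict[tuple[int, str], int] = {}
    for lab, grp in zip(labs, groups):
        key = (int(lab), grp)
        counts[key] = counts.get(key, 0) + 1
    per_region: dict[int, int] = {}
    for (lab, _), c in counts.items():
        per_region[lab] = per_region.get(lab, 0) + c
    return {
        "per_region": {
            int(lab): {
                "name": labels.name(lab) if labels else f"unknown({lab})",
                "count": per_region[lab],
            }
            for lab in sorted(per_region)
        },
        "per_region_group": {
            f"{lab}|{grp}": c for (lab, grp), c in sorted(counts.items())
        },
        "total": int(len(labs)),
    }


# ---------------------------------------------------------------------------
# Meshes

def extract_mesh(mask_volume: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes isosurface (level 0.5) of a binary volume.

    Returns ``(vertices_mm, faces)`` with consistently oriented faces.
    The mask needs at least one interior voxel and an empty one-voxel
    margin so the surface closes.
    """
    mask = np.asarray(mask_volume).astype(bool)
    if not mask.any():
        raise ValidationError("mask volume is empty")
    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(float(v) for v in voxel_size)
    )
    return verts, faces


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume via the divergence theorem (sum of signed tetrahedra)."""
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def mesh_surface_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum())


def mesh_euler_characteristic(vertices: np.ndarray, faces: np.ndarray) -> int:
    """V - E + F of the triangle mesh (2 for a closed genus-0 surface)."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    return int(len(vertices) - len(edges) + len(faces))


def save_mesh_obj(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    """Write a Wavefront OBJ file (1-based face indices)."""
    with open(path, "w") as fh:
        for v in vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
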