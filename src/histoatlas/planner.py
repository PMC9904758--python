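"""Pre-surgical planning of linear probe trajectories.

Given entry/target stereotaxic coordinates, compute the insertion angle
(decomposed into a lateral tilt within the coronal projection and an AP
tilt within the sagittal projection), the insertion length, the ordered
brain regions a probe traverses, and the number of recording channels
landing in each region.

Channel counting honours the channel-less shank tip of silicon probes:
the distal tip carries no recording sites (175 um on Neuropixels), so
channel ``i`` sits at ``tip_length + first_channel_offset + i * pitch``
from the physical tip, and any channel sampling background (label 0) is
excluded from the read-out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .atlas_core import (
    AtlasVolume,
    LabelTable,
    StereotaxicCoord,
    sample_labels,
    stereotaxic_to_voxel,
)
from .errors import ValidationError

__all__ = [
    "ProbeGeometry",
    "Trajectory",
    "RegionTraversal",
    "ChannelReadout",
    "PlanReport",
    "plan_trajectory",
    "traverse_regions",
    "count_channels",
    "plan_multishank",
    "trajectory_readout",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Physical channel layout of a linear silicon probe shank.

    Lengths in micrometres.  ``tip_length_um`` is the channel-less distal
    tip (175 for Neuropixels); ``first_channel_offset_um`` the distance
    from the top of the tip to the first channel centre.
    """

    n_channels: int
    channel_pitch_um: float
    tip_length_um: float = 175.0
    first_channel_offset_um: float = 0.0
    n_shanks: int = 1
    shank_spacing_um: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.n_channels > 1 and self.channel_pitch_um <= 0:
            raise ValidationError("channel_pitch_um must be > 0 for multi-channel probes")
        if min(self.tip_length_um, self.first_channel_offset_um, self.channel_pitch_um) < 0:
            raise ValidationError("probe lengths must be non-negative")
        if self.n_shanks < 1:
            raise ValidationError("n_shanks must be >= 1")

    def channel_distances_um(self) -> np.ndarray:
        """Distance of each channel centre from the physical tip, along the shank."""
        i = np.arange(self.n_channels, dtype=float)
        return self.tip_length_um + self.first_channel_offset_um + i * self.channel_pitch_um

    @property
    def total_span_um(self) -> float:
        return float(self.channel_distances_um()[-1])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_channels": self.n_channels,
            "channel_pitch_um": self.channel_pitch_um,
            "tip_length_um": self.tip_length_um,
            "first_channel_offset_um": self.first_channel_offset_um,
            "n_shanks": self.n_shanks,
            "shank_spacing_um": self.shank_spacing_um,
        }

    @staticmethod
    def from_dict(d: dict) -> "ProbeGeometry":
        return ProbeGeometry(**d)

    @staticmethod
    def from_json(path) -> "ProbeGeometry":
        with open(path) as fh:
            return ProbeGeometry.from_dict(json.load(fh))


@dataclass(frozen=True)
class Trajectory:
    """A linear insertion path: entry at the brain surface, tip at depth."""

    entry: StereotaxicCoord
    tip: StereotaxicCoord

    def __post_init__(self):
        if self.insertion_length_mm <= 0:
            raise ValidationError("entry and tip coincide")

    @property
    def _delta(self) -> np.ndarray:
        return self.tip.as_xyz() - self.entry.as_xyz()

    @property
    def direction(self) -> np.ndarray:
        """Unit vector entry -> tip in (ML, AP, DV) mm axes."""
        d = self._delta
        return d / np.linalg.norm(d)

    @property
    def insertion_length_mm(self) -> float:
        return float(np.linalg.norm(self.tip.as_xyz() - self.entry.as_xyz()))

    @property
    def lateral_tilt_deg(self) -> float:
        """Tilt from vertical within the coronal (ML-DV) projection."""
        d = self._delta
        if d[2] == 0:
            raise ValidationError("horizontal path: tilt from vertical is undefined")
        return float(np.degrees(np.arctan(abs(d[0]) / abs(d[2]))))

    @property
    def ap_tilt_deg(self) -> float:
        """Tilt from vertical within the sagittal (AP-DV) projection."""
        d = self._delta
        if d[2] == 0:
            raise ValidationError("horizontal path: tilt from vertical is undefined")
        return float(np.degrees(np.arctan(abs(d[1]) / abs(d[2]))))

    def point_at_depth(self, depth_mm) -> np.ndarray:
        """(ML, AP, DV) mm point(s) at the given depth(s) below the entry."""
        depth = np.asarray(depth_mm, dtype=float)
        return self.entry.as_xyz() + depth[..., None] * self.direction

    def to_dict(self) -> dict:
        return {
            "entry": {"ap_mm": self.entry.ap_mm, "ml_mm": self.entry.ml_mm, "dv_mm": self.entry.dv_mm},
            "tip": {"ap_mm": self.tip.ap_mm, "ml_mm": self.tip.ml_mm, "dv_mm": self.tip.dv_mm},
        }

    @staticmethod
    def from_dict(d: dict) -> "Trajectory":
        return Trajectory(
            entry=StereotaxicCoord(**d["entry"]), tip=StereotaxicCoord(**d["tip"])
        )


@dataclass(frozen=True)
class TraversalSegment:
    label_id: int
    entry_depth_mm: float
    exit_depth_mm: float

    @property
    def length_mm(self) -> float:
        return self.exit_depth_mm - self.entry_depth_mm


@dataclass
class RegionTraversal:
    """Ordered in-brain segments along a trajectory, depths from brain entry."""

    segments: list[TraversalSegment]
    step_mm: float

    @property
    def total_length_mm(self) -> float:
        return float(sum(s.length_mm for s in self.segments))


@dataclass
class ChannelReadout:
    """Per-region recording-channel counts plus per-channel localisation."""

    counts: dict[int, int]
    channel_labels: np.ndarray  # label id per channel (0 = outside brain)
    channel_positions_mm: np.ndarray  # (n_channels, 3) in (ML, AP, DV)

    @property
    def total_in_brain(self) -> int:
        return int(sum(self.counts.values()))


def plan_trajectory(p_start: StereotaxicCoord, p_end: StereotaxicCoord,
                    atlas: AtlasVolume | None = None) -> Trajectory:
    """Order two stereotaxic points into a trajectory (tip = deeper point)."""
    a, b = p_start.as_xyz(), p_end.as_xyz()
    if np.allclose(a, b):
        raise ValidationError("start and end points coincide")
    if a[2] == b[2]:
        raise ValidationError(
            "horizontal path: insertion tilt from vertical is undefined; "
            "offset the DV coordinate of one endpoint"
        )
    entry, tip = (p_start, p_end) if a[2] > b[2] else (p_end, p_start)
    return Trajectory(entry=entry, tip=tip)


def traverse_regions(traj: Trajectory, atlas: AtlasVolume,
                     step_mm: float | None = None) -> RegionTraversal:
    """Sample labels along the trajectory and merge runs into region segments.

    Samples are spaced ``step_mm`` apart from entry to tip (default half
    the smallest voxel size); boundaries between segments sit at the
    midpoint between adjacent samples of differing label, and leading or
    trailing background runs are trimmed as outside-brain.
    """
    if step_mm is None:
        step_mm = min(atlas.voxel_size_mm) / 2
    if step_mm <= 0:
        raise ValidationError("step_mm must be positive")
    length = traj.insertion_length_mm
    n = int(np.floor(length / step_mm)) + 1
    depths = np.arange(n) * step_mm
    if depths[-1] < length - 1e-12:
        depths = np.append(depths, length)
    pts = traj.point_at_depth(depths)
    vox, _ = stereotaxic_to_voxel(pts, atlas)
    labels = sample_labels(atlas, vox)
    nonzero = np.nonzero(labels)[0]
    if len(nonzero) == 0:
        raise ValidationError("trajectory lies entirely outside the brain")
    first, last = nonzero[0], nonzero[-1]
    labels = labels[first : last + 1]
    depths = depths[first : last + 1]

    # merge runs of identical label; boundaries at midpoints between samples
    change = np.nonzero(np.diff(labels))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(labels) - 1]])
    brain_entry = depths[0]
    segments = []
    for s_idx, e_idx in zip(starts, ends):
        lo = brain_entry if s_idx == 0 else (depths[s_idx - 1] + depths[s_idx]) / 2
        hi = depths[-1] if e_idx == len(labels) - 1 else (depths[e_idx] + depths[e_idx + 1]) / 2
        segments.append(
            TraversalSegment(
                label_id=int(labels[s_idx]),
                entry_depth_mm=float(lo - brain_entry),
                exit_depth_mm=float(hi - brain_entry),
            )
        )
    return RegionTraversal(segments=segments, step_mm=float(step_mm))


def count_channels(traj: Trajectory, geometry: ProbeGeometry,
                   atlas: AtlasVolume) -> ChannelReadout:
    """Localise every recording channel and count channels per region.

    Channel ``i`` sits at ``tip_length + first_channel_offset + i * pitch``
    micrometres from the physical tip toward the entry; channels sampling
    label 0 (outside the brain, or above the entry point) are excluded.
    """
    d_um = geometry.channel_distances_um()
    positions = traj.tip.as_xyz() - (d_um[:, None] / 1000.0) * traj.direction
    vox, _ = stereotaxic_to_voxel(positions, atlas)
    labels = sample_labels(atlas, vox)
    counts: dict[int, int] = {}
    for lab in labels[labels != 0]:
        counts[int(lab)] = counts.get(int(lab), 0) + 1
    return ChannelReadout(
        counts=counts, channel_labels=labels, channel_positions_mm=positions
    )


def plan_multishank(base_traj: Trajectory, geometry: ProbeGeometry,
                    azimuth_deg: float = 0.0) -> list[Trajectory]:
    """Replicate a trajectory across the shanks of a multi-shank probe.

    Shank ``k`` is the base trajectory translated by ``k * shank_spacing``
    along the in-plane direction at ``azimuth_deg`` within the plane
    perpendicular to the insertion.  Azimuth 0 points along the projection
    of +ML onto that plane (+AP reference if the insertion is parallel to
    ML), rotating right-handed about the insertion direction.
    """
    if geometry.n_shanks == 1:
        return [base_traj]
    d = base_traj.direction
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 1 - 1e-9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    th = np.deg2rad(azimuth_deg)
    offset_dir = np.cos(th) * e1 + np.sin(th) * e2
    out = []
    for k in range(geometry.n_shanks):
        shift = k * geometry.shank_spacing_um / 1000.0 * offset_dir
        out.append(
            Trajectory(
                entry=StereotaxicCoord.from_xyz(base_traj.entry.as_xyz() + shift),
                tip=StereotaxicCoord.from_xyz(base_traj.tip.as_xyz() + shift),
            )
        )
    return out


@dataclass
class PlanReport:
    """Structured plan read-out: coordinates, angles, regions, channel counts."""

    entry: StereotaxicCoord
    tip: StereotaxicCoord
    lateral_tilt_deg: float
    ap_tilt_deg: float
    insertion_length_mm: float
    regions: list[dict] = field(default_factory=list)
    total_channels_in_brain: int = 0

    def to_dict(self) -> dict:
        return {
            "entry_mm": {"ap": self.entry.ap_mm, "ml": self.entry.ml_mm, "dv": self.entry.dv_mm},
            "tip_mm": {"ap": self.tip.ap_mm, "ml": self.tip.ml_mm, "dv": self.tip.dv_mm},
            "lateral_tilt_deg": self.lateral_tilt_deg,
            "ap_tilt_deg": self.ap_tilt_deg,
            "insertion_length_mm": self.insertion_length_mm,
            "regions": self.regions,
            "total_channels_in_brain": self.total_channels_in_brain,
        }

    @staticmethod
    def from_dict(d: dict) -> "PlanReport":
        return PlanReport(
            entry=StereotaxicCoord(ap_mm=d["entry_mm"]["ap"], ml_mm=d["entry_mm"]["ml"], dv_mm=d["entry_mm"]["dv"]),
            tip=StereotaxicCoord(ap_mm=d["tip_mm"]["ap"], ml_mm=d["tip_mm"]["ml"], dv_mm=d["tip_mm"]["dv"]),
            lateral_tilt_deg=d["lateral_tilt_deg"],
            ap_tilt_deg=d["ap_tilt_deg"],
            insertion_length_mm=d["insertion_length_mm"],
            regions=d["regions"],
            total_channels_in_brain=d["total_channels_in_brain"],
        )


def trajectory_readout(traj: Trajectory, traversal: RegionTraversal,
                       channels: ChannelReadout | None,
                       labels: LabelTable | None = None) -> PlanReport:
    """Assemble the printable plan report from trajectory, traversal, channels.

    Regions are listed in traversal order with name, color, path length
    and channel count; label ids missing from the table are reported as
    ``unknown(<id>)`` rather than raising.
    """
    regions = []
    for seg in traversal.segments:
        row = {
            "label_id": seg.label_id,
            "name": labels.name(seg.label_id) if labels else f"unknown({seg.label_id})",
            "color": list(labels.color(seg.label_id)) if labels else [128, 128, 128],
            "entry_depth_mm": seg.entry_depth_mm,
            "exit_depth_mm": seg.exit_depth_mm,
            "path_length_mm": seg.length_mm,
            "n_channels": 0,
        }
        regions.append(row)
    if channels is not None:
        per_label: dict[int, int] = dict(channels.counts)
        for row in regions:
            # channels assigned to the first traversal row carrying that label
            lab = row["label_id"]
            if lab in per_label:
                row["n_channels"] = per_label.pop(lab)
    return PlanReport(
        entry=traj.entry,
        tip=traj.tip,
        lateral_tilt_deg=traj.lateral_tilt_deg,
        ap_tilt_deg=traj.ap_tilt_deg,
        insertion_length_mm=traj.insertion_length_mm,
        regions=regions,
        total_channels_in_brain=channels.total_in_brain if channels else 0,
    )
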