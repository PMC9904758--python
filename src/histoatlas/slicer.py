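"""Oblique slicing of atlas volumes with an exact 2D<->3D coordinate contract.

A :class:`SlicePlane` is an oriented cutting plane through the atlas.  Its
pose lives in the bregma-relative mm frame with axes (ML, AP, DV): an
origin point plus orthonormal in-plane unit vectors ``u``, ``v`` and the
normal ``n``.  Pixel ``(s, t)`` of any slice sampled on the plane sits at
the 3D point ``origin + s * pixel_size * u + t * pixel_size * v``.

Tilts emulate cutting out-of-plane sections: the canonical plane is
rotated about bregma-centred in-plane axes, first by ``tilt_a`` about
``u`` then by ``tilt_b`` about the rotated ``v``, each limited to +/-30
degrees (the range the registration workflow supports).  We tilt the
plane, not the volume; the two views differ only by a sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .atlas_core import AtlasVolume, sample_labels, stereotaxic_to_voxel, voxel_to_stereotaxic
from .errors import ValidationError

__all__ = [
    "SlicePlane",
    "Slice2D",
    "compute_plane",
    "extract_slice",
    "plane_point_to_voxel",
    "voxel_to_plane",
    "plane_covering_volume",
]

MAX_TILT_DEG = 30.0

# canonical (u, v, n) triples per orientation, as (ML, AP, DV) unit vectors
_CANONICAL = {
    "coronal": (np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), np.array([0, 1.0, 0])),
    "sagittal": (np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), np.array([1.0, 0, 0])),
    "horizontal": (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
}


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    th = np.deg2rad(angle_deg)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


@dataclass(frozen=True)
class SlicePlane:
    """Oriented (optionally tilted) cutting plane through the atlas."""

    orientation: str
    position_mm: float
    tilt_a_deg: float
    tilt_b_deg: float
    pixel_size_mm: float
    origin: np.ndarray  # mm, bregma-relative (ML, AP, DV)
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("u", "v", "n"):
            vec = getattr(self, name)
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise ValidationError(f"plane axis {name} is not unit length")
        gram = np.abs([self.u @ self.v, self.u @ self.n, self.v @ self.n])
        if gram.max() > 1e-9:
            raise ValidationError("plane axes are not mutually orthogonal")

    def point_at(self, s, t) -> np.ndarray:
        """3D mm position of in-plane pixel coordinates (s, t); vectorized."""
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        return (
            self.origin
            + s[..., None] * self.pixel_size_mm * self.u
            + t[..., None] * self.pixel_size_mm * self.v
        )

    def shifted(self, ds: float, dt: float) -> "SlicePlane":
        """Copy with the origin translated in-plane by (ds, dt) pixels."""
        new_origin = self.point_at(np.float64(ds), np.float64(dt))
        return replace(self, origin=new_origin)

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "position_mm": self.position_mm,
            "tilt_a_deg": self.tilt_a_deg,
            "tilt_b_deg": self.tilt_b_deg,
            "pixel_size_mm": self.pixel_size_mm,
            "origin": self.origin.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "n": self.n.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "SlicePlane":
        return SlicePlane(
            orientation=d["orientation"],
            position_mm=float(d["position_mm"]),
            tilt_a_deg=float(d["tilt_a_deg"]),
            tilt_b_deg=float(d["tilt_b_deg"]),
            pixel_size_mm=float(d["pixel_size_mm"]),
            origin=np.asarray(d["origin"], dtype=float),
            u=np.asarray(d["u"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            n=np.asarray(d["n"], dtype=float),
        )


@dataclass
class Slice2D:
    """A sampled 2D slice: integer labels, optional template, provenance pose."""

    label_image: np.ndarray
    plane: SlicePlane
    template_image: np.ndarray | None = None
    oob_mask: np.ndarray | None = None  # True where the pre-image left the volume

    @property
    def extent(self) -> tuple[int, int]:
        return self.label_image.shape


def compute_plane(
    orientation: str,
    position_mm: float,
    tilt_a_deg: float = 0.0,
    tilt_b_deg: float = 0.0,
    pixel_size_mm: float | None = None,
    atlas: AtlasVolume | None = None,
) -> SlicePlane:
    """Construct a slice plane at ``position_mm`` along the canonical normal.

    The canonical pose is rotated about bregma-centred axes: ``tilt_a``
    about ``u``, then ``tilt_b`` about the rotated ``v``.  The origin is
    placed so the plane passes through bregma + position_mm * canonical
    normal.  Default pixel size is the smallest voxel dimension.
    """
    if orientation not in _CANONICAL:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if abs(tilt_a_deg) > MAX_TILT_DEG or abs(tilt_b_deg) > MAX_TILT_DEG:
        raise ValidationError(
            f"tilt angles ({tilt_a_deg}, {tilt_b_deg}) exceed the +/-{MAX_TILT_DEG:g} deg limit"
        )
    if pixel_size_mm is None:
        if atlas is None:
            raise ValidationError("pixel_size_mm required when no atlas is given")
        pixel_size_mm = float(min(atlas.voxel_size_mm))
    if pixel_size_mm <= 0:
        raise ValidationError("pixel_size_mm must be positive")

    u0, v0, n0 = _CANONICAL[orientation]
    Ra = _rotation_about(u0, tilt_a_deg)
    v1 = Ra @ v0
    Rb = _rotation_about(v1, tilt_b_deg)
    R = Rb @ Ra
    origin = position_mm * n0  # bregma-relative mm; bregma is the frame origin
    return SlicePlane(
        orientation=orientation,
        position_mm=float(position_mm),
        tilt_a_deg=float(tilt_a_deg),
        tilt_b_deg=float(tilt_b_deg),
        pixel_size_mm=float(pixel_size_mm),
        origin=origin,
        u=R @ u0,
        v=R @ v0,
        n=R @ n0,
    )


def plane_point_to_voxel(plane: SlicePlane, s, t, atlas: AtlasVolume):
    """Fractional voxel coordinates of in-plane pixel coordinates (s, t)."""
    pts = plane.point_at(np.asarray(s, dtype=float), np.asarray(t, dtype=float))
    flat = pts.reshape(-1, 3)
    vox, _ = stereotaxic_to_voxel(flat, atlas)
    return vox.reshape(pts.shape)


def voxel_to_plane(plane: SlicePlane, voxel, atlas: AtlasVolume):
    """In-plane (s, t) of a 3D voxel coordinate, plus an off-plane flag.

    The flag is set when the point lies more than half a pixel off the
    plane along its normal.
    """
    vox = np.atleast_2d(np.asarray(voxel, dtype=float))
    mm = voxel_to_stereotaxic(vox, atlas)
    rel = mm - plane.origin
    s = rel @ plane.u / plane.pixel_size_mm
    t = rel @ plane.v / plane.pixel_size_mm
    off = rel @ plane.n
    off_plane = np.abs(off) > plane.pixel_size_mm / 2
    if np.asarray(voxel).ndim == 1:
        return float(s[0]), float(t[0]), bool(off_plane[0])
    return s, t, off_plane


def extract_slice(atlas: AtlasVolume, plane: SlicePlane, out_shape) -> Slice2D:
    """Sample the atlas on the plane's pixel grid.

    Labels are sampled nearest-neighbour (they are categorical); the
    template, when present, is sampled by trilinear interpolation.
    Pixels whose 3D pre-image falls outside the volume carry label 0,
    template 0, and a set out-of-bounds mask bit.
    """
    ns, nt = (int(x) for x in out_shape)
    if ns <= 0 or nt <= 0:
        raise ValidationError("out_shape must be positive")
    ss, tt = np.meshgrid(np.arange(ns), np.arange(nt), indexing="ij")
    vox = plane_point_to_voxel(plane, ss.ravel(), tt.ravel(), atlas)
    shape = np.asarray(atlas.shape)
    in_bounds = np.all((vox >= -0.5) & (vox <= shape - 0.5), axis=1)
    labels = sample_labels(atlas, vox).reshape(ns, nt)
    oob = (~in_bounds).reshape(ns, nt)
    labels[oob] = 0

    template_image = None
    if atlas.template is not None:
        from scipy.ndimage import map_coordinates

        template_image = map_coordinates(
            atlas.template, vox.T, order=1, mode="constant", cval=0.0
        ).reshape(ns, nt)
        template_image[oob] = 0.0
    return Slice2D(
        label_image=labels, plane=plane, template_image=template_image, oob_mask=oob
    )


def plane_covering_volume(atlas: AtlasVolume, plane: SlicePlane):
    """Shift a plane in-plane so its positive pixel quadrant covers the volume.

    Returns ``(shifted_plane, (ns, nt))``: projecting all eight volume
    corners onto (u, v) gives the pixel range; the returned plane's
    origin sits at the minimum corner so pixel (0, 0) starts there.
    """
    shape = np.asarray(atlas.shape, dtype=float)
    corners = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    s, t, _ = voxel_to_plane(plane, corners, atlas)
    s0, t0 = np.floor(s.min()), np.floor(t.min())
    ns = int(np.ceil(s.max() - s0)) + 1
    nt = int(np.ceil(t.max() - t0)) + 1
    return plane.shifted(float(s0), float(t0)), (ns, nt)
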