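"""Anchor-point piecewise-affine registration of histology to atlas slices.

The warp is defined by user-clicked corresponding landmark pairs
(anchors) between a histology image and an atlas slice.  The source
(histology) points are Delaunay-triangulated; each triangle carries the
unique affine map sending its three source vertices exactly onto their
destination partners.  The result is a continuous, piecewise-linear
deformation: exact at the anchors, affine inside each triangle, and
consistent across shared edges.

Points outside the source convex hull are not extrapolated — they are
returned unmapped with a cleared mask bit (an optional global-affine
fallback exists for callers that need full-frame behaviour).  Triangles
whose destination image has reversed orientation ("fold-overs", from
crossed anchors) are flagged at fit time; forward mapping through them
still works, but inverse queries inside a folded destination triangle
are ambiguous and raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import ValidationError

__all__ = ["AnchorSet", "PiecewiseAffineMap", "fit_piecewise_affine", "map_points", "warp_image"]

_EDGE_TOL = 1e-12  # barycentric slack for containment tests


@dataclass(frozen=True)
class AnchorSet:
    """Ordered (src, dst) landmark pairs in pixel coordinates."""

    src: np.ndarray  # (n, 2)
    dst: np.ndarray  # (n, 2)

    def __post_init__(self):
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)
        if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
            raise ValidationError("anchors must be matching (n, 2) arrays")
        if len(src) < 3:
            raise ValidationError("at least 3 anchor pairs are required")
        d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 1e-6:
            raise ValidationError("duplicate source anchor points")
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValidationError("source anchor points are collinear")

    def __len__(self) -> int:
        return len(self.src)

    def to_dict(self) -> dict:
        return {"src": self.src.tolist(), "dst": self.dst.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "AnchorSet":
        return AnchorSet(src=np.asarray(d["src"]), dst=np.asarray(d["dst"]))


def _triangle_affines(tri_pts: np.ndarray, dst_pts: np.ndarray) -> np.ndarray:
    """Exact per-triangle affine solves.

    ``tri_pts``/``dst_pts``: (T, 3, 2) vertex coordinates.  Returns (T, 2, 3)
    matrices A with ``dst = A @ [x, y, 1]``.
    """
    T = len(tri_pts)
    M = np.concatenate([tri_pts, np.ones((T, 3, 1))], axis=2)  # (T, 3, 3)
    # solve M @ A.T = dst  per triangle
    A_t = np.linalg.solve(M, dst_pts)  # (T, 3, 2)
    return np.transpose(A_t, (0, 2, 1))  # (T, 2, 3)


@dataclass
class PiecewiseAffineMap:
    """Delaunay-triangulated anchor correspondence defining a continuous 2D warp."""

    anchors: AnchorSet
    triangles: np.ndarray  # (T, 3) vertex indices into anchors
    affines: np.ndarray  # (T, 2, 3) forward src->dst
    inverse_affines: np.ndarray  # (T, 2, 3) dst->src, NaN where folded/degenerate
    folded: np.ndarray  # (T,) bool

    @property
    def src_triangles(self) -> np.ndarray:
        return self.anchors.src[self.triangles]

    @property
    def dst_triangles(self) -> np.ndarray:
        return self.anchors.dst[self.triangles]


def fit_piecewise_affine(anchors: AnchorSet) -> PiecewiseAffineMap:
    """Triangulate the source anchors and solve one exact affine per triangle.

    Destination triangles inherit the source connectivity, keeping the
    forward map single-valued even when the destination cloud would
    triangulate differently.  Fold-over (a destination triangle with
    reversed orientation) is recorded, not raised.
    """
    try:
        tri = Delaunay(anchors.src)
    except QhullError as exc:
        raise ValidationError(f"triangulation failed: {exc}") from exc
    simplices = np.array(sorted(map(tuple, np.sort(tri.simplices, axis=1))))
    src_tris = anchors.src[simplices]
    dst_tris = anchors.dst[simplices]

    def signed_area(t):
        return 0.5 * (
            (t[:, 1, 0] - t[:, 0, 0]) * (t[:, 2, 1] - t[:, 0, 1])
            - (t[:, 2, 0] - t[:, 0, 0]) * (t[:, 1, 1] - t[:, 0, 1])
        )

    src_area = signed_area(src_tris)
    dst_area = signed_area(dst_tris)
    folded = np.sign(dst_area) != np.sign(src_area)

    affines = _triangle_affines(src_tris, dst_tris)
    inverse_affines = np.full_like(affines, np.nan)
    ok = np.abs(dst_area) > 1e-12
    if ok.any():
        inverse_affines[ok] = _triangle_affines(dst_tris[ok], src_tris[ok])
    return PiecewiseAffineMap(
        anchors=anchors,
        triangles=simplices,
        affines=affines,
        inverse_affines=inverse_affines,
        folded=folded,
    )


def _barycentric(tris: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of each point w.r.t. each triangle.

    ``tris``: (T, 3, 2); ``points``: (P, 2).  Returns (P, T, 3).
    """
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]  # (T, 2) each
    v0 = b - a
    v1 = c - a
    det = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]  # (T,)
    v2 = points[:, None, :] - a[None, :, :]  # (P, T, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        l1 = (v2[..., 0] * v1[None, :, 1] - v1[None, :, 0] * v2[..., 1]) / det
        l2 = (v0[None, :, 0] * v2[..., 1] - v2[..., 0] * v0[None, :, 1]) / det
    l0 = 1.0 - l1 - l2
    return np.stack([l0, l1, l2], axis=-1)


def _locate(tris: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Index of the containing triangle per point (-1 outside all).

    Containment is inclusive of edges; a point on a shared edge or vertex
    resolves deterministically to the lowest triangle index.
    """
    bary = _barycentric(tris, points)
    inside = np.all(bary >= -_EDGE_TOL, axis=-1)  # (P, T)
    found = inside.any(axis=1)
    idx = np.where(found, inside.argmax(axis=1), -1)
    return idx


def map_points(pw_map: PiecewiseAffineMap, points, direction: str = "forward"):
    """Map points through the piecewise-affine warp.

    Returns ``(mapped, in_hull)``.  Points outside the relevant convex
    hull keep their input coordinates and get a cleared mask bit.
    Inverse queries landing inside a folded destination triangle raise,
    naming the triangle, since the local inverse is ambiguous there.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if direction == "forward":
        tris, affines = pw_map.src_triangles, pw_map.affines
    elif direction == "inverse":
        tris, affines = pw_map.dst_triangles, pw_map.inverse_affines
    else:
        raise ValidationError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    idx = _locate(tris, pts)
    in_hull = idx >= 0
    if direction == "inverse" and in_hull.any():
        hit_folded = pw_map.folded[idx[in_hull]]
        if hit_folded.any():
            bad = idx[in_hull][hit_folded][0]
            raise ValidationError(
                f"inverse query inside folded triangle {bad}: mapping is ambiguous"
            )
    mapped = pts.copy()
    if in_hull.any():
        A = affines[idx[in_hull]]  # (k, 2, 3)
        homog = np.concatenate([pts[in_hull], np.ones((in_hull.sum(), 1))], axis=1)
        mapped[in_hull] = np.einsum("kij,kj->ki", A, homog)
    return mapped, in_hull


def warp_image(pw_map: PiecewiseAffineMap, image: np.ndarray, out_shape,
               fill: float = 0.0):
    """Warp a histology image onto the atlas-slice frame (inverse mapping).

    Every output pixel inside the destination hull is sampled from the
    source image at its inverse-mapped location by bilinear
    interpolation; pixels outside the hull take ``fill`` and mask 0.
    Pixel coordinates are (x, y) = (column, row), the convention used for
    anchor clicks; ``image`` is indexed ``[row, col(, channel)]``.
    """
    from scipy.ndimage import map_coordinates

    if not (~pw_map.folded).any():
        raise ValidationError("all triangles are folded; warp is undefined")
    h, w = (int(x) for x in out_shape)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    out_pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src_pts, in_hull = map_points(pw_map, out_pts, direction="inverse")
    mask = in_hull.reshape(h, w)

    coords = np.stack([src_pts[:, 1], src_pts[:, 0]])  # (row, col) for sampling
    # snap float undershoot at the image border: map_coordinates treats a
    # coordinate of -1e-15 as fully out of bounds (constant fill)
    for axis, size in enumerate(image.shape[:2]):
        c = coords[axis]
        c[(c > -1e-6) & (c < 0)] = 0.0
        c[(c > size - 1) & (c < size - 1 + 1e-6)] = size - 1
    if image.ndim == 2:
        channels = [image]
    else:
        channels = [image[..., c] for c in range(image.shape[2])]
    warped_channels = []
    for chan in channels:
        samp = map_coordinates(
            chan.astype(float), coords, order=1, mode="constant", cval=fill
        ).reshape(h, w)
        samp[~mask] = fill
        warped_channels.append(samp)
    warped = warped_channels[0] if image.ndim == 2 else np.stack(warped_channels, axis=-1)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        warped = np.clip(np.rint(warped), info.min, info.max).astype(image.dtype)
    return warped, mask
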