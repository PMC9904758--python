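"""Annotated atlas volumes and the bregma-relative coordinate contract.

An :class:`AtlasVolume` holds a 3D integer annotation grid (region labels)
and an optional scalar template, on a fixed axis convention:

* axis 0 — medio-lateral (ML), increasing left -> right,
* axis 1 — anterior-posterior (AP), increasing posterior -> anterior,
* axis 2 — dorso-ventral (DV), increasing ventral -> dorsal.

Stereotaxic coordinates are millimetre offsets from a bregma reference
voxel: AP positive anterior, ML positive toward the right hemisphere, DV
negative below bregma.  Voxel indices are 0-based and fractional voxel
coordinates are allowed everywhere; nearest-neighbour label sampling
rounds to the nearest index, while containment tests (used when binning
points into voxels) use the half-open extent ``[i, i + 1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "AtlasVolume",
    "LabelEntry",
    "LabelTable",
    "StereotaxicCoord",
    "load_atlas",
    "parse_label_file",
    "parse_label_csv",
    "save_atlas",
    "voxel_to_stereotaxic",
    "stereotaxic_to_voxel",
    "sample_labels",
    "containing_voxel",
    "make_synthetic_atlas",
]


@dataclass(frozen=True)
class StereotaxicCoord:
    """Bregma-relative position in millimetres (AP anterior+, ML right+, DV dorsal+)."""

    ap_mm: float
    ml_mm: float
    dv_mm: float

    def as_xyz(self) -> np.ndarray:
        """Return the (ML, AP, DV) vector matching the atlas axis order."""
        return np.array([self.ml_mm, self.ap_mm, self.dv_mm], dtype=float)

    @staticmethod
    def from_xyz(xyz) -> "StereotaxicCoord":
        ml, ap, dv = (float(c) for c in xyz)
        return StereotaxicCoord(ap_mm=ap, ml_mm=ml, dv_mm=dv)


@dataclass(frozen=True)
class LabelEntry:
    name: str
    color: tuple[int, int, int]
    parent_id: int | None = None


class LabelTable:
    """Mapping from region label id to name, RGB color, and optional parent."""

    def __init__(self, entries: dict[int, LabelEntry]):
        for label_id, entry in entries.items():
            if label_id < 0:
                raise ValidationError(f"negative label id {label_id}")
            if any(c < 0 or c > 255 for c in entry.color):
                raise ValidationError(
                    f"label {label_id}: color {entry.color} outside [0, 255]"
                )
        for label_id, entry in entries.items():
            if entry.parent_id is not None and entry.parent_id not in entries:
                raise ValidationError(
                    f"label {label_id}: parent {entry.parent_id} not in table"
                )
        self.entries: dict[int, LabelEntry] = dict(entries)

    def __contains__(self, label_id: int) -> bool:
        return label_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def name(self, label_id: int) -> str:
        """Region name, or ``unknown(<id>)`` for ids absent from the table."""
        entry = self.entries.get(label_id)
        return entry.name if entry is not None else f"unknown({label_id})"

    def color(self, label_id: int) -> tuple[int, int, int]:
        entry = self.entries.get(label_id)
        return entry.color if entry is not None else (128, 128, 128)

    def to_dict(self) -> dict:
        return {
            str(i): {"name": e.name, "color": list(e.color), "parent_id": e.parent_id}
            for i, e in sorted(self.entries.items())
        }


@dataclass
class AtlasVolume:
    """Annotated 3D label grid with optional intensity template.

    Parameters
    ----------
    annotation
        Integer region labels, shape ``(nx, ny, nz)`` on the (ML, AP, DV)
        axis convention.  Label 0 is reserved for outside-brain background.
    template
        Optional scalar grid of identical shape.
    voxel_size_mm
        Per-axis voxel edge length in mm (anisotropic voxels supported).
    bregma_voxel
        Possibly fractional voxel coordinates of bregma; must lie within
        the grid bounds.
    """

    annotation: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    bregma_voxel: tuple[float, float, float]
    template: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.annotation = np.asarray(self.annotation)
        if self.annotation.ndim != 3:
            raise ValidationError("annotation must be a 3D grid")
        if not np.issubdtype(self.annotation.dtype, np.integer):
            raise ValidationError("annotation must hold integer labels")
        if self.annotation.min() < 0:
            raise ValidationError("labels must be non-negative")
        if self.template is not None:
            self.template = np.asarray(self.template, dtype=float)
            if self.template.shape != self.annotation.shape:
                raise ValidationError("template shape differs from annotation shape")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel_size_mm must be three strictly positive values")
        self.bregma_voxel = tuple(float(v) for v in self.bregma_voxel)
        for axis, (b, n) in enumerate(zip(self.bregma_voxel, self.annotation.shape)):
            if not (0 <= b <= n - 1):
                raise ValidationError(
                    f"bregma voxel {self.bregma_voxel} outside grid bounds on axis {axis}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.annotation.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def voxel_to_stereotaxic(voxel, atlas: AtlasVolume):
    """Convert (fractional) voxel coordinates to bregma-relative mm.

    Accepts a single triple or an ``(n, 3)`` array; returns a
    :class:`StereotaxicCoord` or an ``(n, 3)`` array of (ML, AP, DV) mm.
    Out-of-bounds inputs pass through unclamped (callers can mask).
    """
    v = np.asarray(voxel, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    mm = (v - np.asarray(atlas.bregma_voxel)) * np.asarray(atlas.voxel_size_mm)
    if single:
        return StereotaxicCoord.from_xyz(mm[0])
    return mm


def stereotaxic_to_voxel(coord, atlas: AtlasVolume):
    """Inverse of :func:`voxel_to_stereotaxic`; exact arithmetic inverse.

    ``coord`` is a :class:`StereotaxicCoord` or an ``(n, 3)`` array of
    (ML, AP, DV) mm.  Returns fractional voxel coordinates plus a boolean
    in-bounds flag (array input) so callers can mask.
    """
    if isinstance(coord, StereotaxicCoord):
        mm = coord.as_xyz()[None, :]
        single = True
    else:
        mm = np.atleast_2d(np.asarray(coord, dtype=float))
        single = False
    v = mm / np.asarray(atlas.voxel_size_mm) + np.asarray(atlas.bregma_voxel)
    shape = np.asarray(atlas.shape)
    in_bounds = np.all((v >= 0) & (v <= shape - 1), axis=1)
    if single:
        return v[0], bool(in_bounds[0])
    return v, in_bounds


def containing_voxel(voxel_coords) -> np.ndarray:
    """Integer voxel index whose half-open extent [i, i+1) contains the point.

    A 1e-7-voxel guard keeps points computed to sit exactly on a voxel
    coordinate from flooring into the neighbour below through float error.
    """
    return np.floor(np.asarray(voxel_coords, dtype=float) + 1e-7).astype(np.int64)


def sample_labels(atlas: AtlasVolume, voxel_coords) -> np.ndarray:
    """Nearest-neighbour label sampling; out-of-bounds points yield label 0."""
    v = np.atleast_2d(np.asarray(voxel_coords, dtype=float))
    idx = np.rint(v).astype(np.int64)
    shape = np.asarray(atlas.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(len(v), dtype=atlas.annotation.dtype)
    if ok.any():
        sel = idx[ok]
        labels[ok] = atlas.annotation[sel[:, 0], sel[:, 1], sel[:, 2]]
    return labels


# ---------------------------------------------------------------------------
# File I/O

_LABEL_LINE = re.compile(
    r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)\s+\S+\s+\S+\s+\S+\s+\"(.*)\"\s*$"
)


def parse_label_file(text: str) -> LabelTable:
    """Parse an ITK-SNAP style label description.

    Comment lines start with ``#``; data lines read
    ``IDX  R G B A VIS MSH  "NAME"``.  Quoted names are preserved
    verbatim, including internal spaces.  The dialect has no hierarchy,
    so ``parent_id`` is left unset.
    """
    entries: dict[int, LabelEntry] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _LABEL_LINE.match(line)
        if m is None:
            raise FormatError(f"malformed label line {lineno}: {line!r}")
        idx = int(m.group(1))
        color = (int(m.group(2)), int(m.group(3)), int(m.group(4)))
        if idx in entries:
            raise ValidationError(f"duplicate label id {idx} at line {lineno}")
        entries[idx] = LabelEntry(name=m.group(5), color=color)
    return LabelTable(entries)


def parse_label_csv(text: str) -> LabelTable:
    """Parse a flat CSV structure list: ``id,name,parent_id,r,g,b`` with header."""
    import csv
    import io

    entries: dict[int, LabelEntry] = {}
    reader = csv.DictReader(io.StringIO(text))
    required = {"id", "name", "parent_id", "r", "g", "b"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise FormatError(f"label CSV must have columns {sorted(required)}")
    for row in reader:
        idx = int(row["id"])
        if idx in entries:
            raise ValidationError(f"duplicate label id {idx}")
        parent = row["parent_id"].strip()
        entries[idx] = LabelEntry(
            name=row["name"],
            color=(int(row["r"]), int(row["g"]), int(row["b"])),
            parent_id=int(parent) if parent else None,
        )
    return LabelTable(entries)


# NIfTI axis codes accepted for each atlas axis; loaders flip data so that
# ML increases left->right, AP posterior->anterior, DV ventral->dorsal.
_AXIS_CODES = {
    0: {"R": False, "L": True},
    1: {"A": False, "P": True},
    2: {"S": False, "I": True},
}


def _reorient(data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    codes = nib.orientations.aff2axcodes(affine)
    order = [None, None, None]
    flips = [False, False, False]
    for data_axis, code in enumerate(codes):
        for atlas_axis, accepted in _AXIS_CODES.items():
            if code in accepted:
                order[atlas_axis] = data_axis
                flips[atlas_axis] = accepted[code]
    if any(o is None for o in order):
        raise FormatError(
            f"unsupported NIfTI orientation {codes}; expected a permutation of R/L, A/P, S/I axes"
        )
    data = np.transpose(data, order)
    for axis, flip in enumerate(flips):
        if flip:
            data = np.flip(data, axis=axis)
    return np.ascontiguousarray(data)


def load_atlas(volume_path, label_path, bregma_voxel, template_path=None):
    """Load a NIfTI annotation volume plus label table into an :class:`AtlasVolume`.

    Voxel sizes come from the NIfTI header (converted to mm); data are
    reoriented into the package's (ML, AP, DV) convention using the header
    affine.  Labels present in the volume but missing from the table are
    collected into ``atlas.warnings`` rather than raising.
    """
    try:
        img = nib.load(str(volume_path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for corrupt files
        raise FormatError(f"cannot read NIfTI volume {volume_path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    rounded = np.rint(data)
    if not np.array_equal(rounded, data):
        raise FormatError("annotation volume is not integer-valued")
    annotation = _reorient(rounded.astype(np.int64), img.affine)

    units = img.header.get_xyzt_units()[0]
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if units == "micron":
        zooms = zooms / 1000.0
    elif units == "meter":
        zooms = zooms * 1000.0
    # header zooms are per data axis; permute to atlas axis order
    codes = nib.orientations.aff2axcodes(img.affine)
    order = []
    for atlas_axis, accepted in _AXIS_CODES.items():
        for data_axis, code in enumerate(codes):
            if code in accepted:
                order.append(data_axis)
    voxel_size = tuple(zooms[order])

    label_text = open(label_path, "r", encoding="utf-8").read()
    if str(label_path).endswith(".csv"):
        table = parse_label_csv(label_text)
    else:
        table = parse_label_file(label_text)

    template = None
    if template_path is not None:
        timg = nib.load(str(template_path))
        template = _reorient(
            np.asanyarray(timg.dataobj).astype(float), timg.affine
        )

    atlas = AtlasVolume(
        annotation=annotation,
        template=template,
        voxel_size_mm=voxel_size,
        bregma_voxel=bregma_voxel,
    )
    present = set(np.unique(annotation).tolist())
    missing = sorted(present - set(table.entries))
    atlas.warnings = missing
    return atlas, table


def save_atlas(atlas: AtlasVolume, volume_path) -> None:
    """Write the annotation grid as NIfTI in RAS orientation with mm zooms."""
    affine = np.diag(list(atlas.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(atlas.annotation.astype(np.int32), affine)
    img.header.set_zooms(atlas.voxel_size_mm)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(volume_path))


# ---------------------------------------------------------------------------
# Synthetic atlases

def make_synthetic_atlas(spec: dict, seed: int = 0):
    """Build a small annotated volume from analytic primitives.

    ``spec`` keys: ``shape`` (nx, ny, nz); ``voxel_size_mm``;
    ``bregma_voxel``; ``primitives`` — a list of dicts, each either

    * ``{"kind": "box", "label": id, "lo": (x,y,z), "hi": (x,y,z)}`` with
      half-open voxel bounds ``[lo, hi)``, or
    * ``{"kind": "ellipsoid", "label": id, "center": (x,y,z),
      "semi_axes": (a,b,c)}`` in voxel units.

    Voxels take the label of the *last* primitive containing their center.
    Primitives never reach the outermost voxel layer, guaranteeing a
    label-0 margin of at least one voxel on every face.  Output is
    deterministic given ``(spec, seed)``; the seed feeds optional label
    noise (none by default) and is recorded for provenance.
    """
    shape = tuple(int(n) for n in spec["shape"])
    prims = spec["primitives"]
    labels_seen: set[int] = set()
    for prim in prims:
        lab = int(prim["label"])
        if lab in labels_seen:
            raise ValidationError(f"label {lab} used by more than one primitive")
        labels_seen.add(lab)

    annotation = np.zeros(shape, dtype=np.int64)
    # voxel i spans [i, i+1); primitives are evaluated at the extent center
    cx, cy, cz = np.meshgrid(
        np.arange(shape[0], dtype=float) + 0.5,
        np.arange(shape[1], dtype=float) + 0.5,
        np.arange(shape[2], dtype=float) + 0.5,
        indexing="ij",
    )
    for prim in prims:
        lab = int(prim["label"])
        if prim["kind"] == "box":
            lo = np.asarray(prim["lo"], dtype=float)
            hi = np.asarray(prim["hi"], dtype=float)
            inside = (
                (cx >= lo[0]) & (cx < hi[0])
                & (cy >= lo[1]) & (cy < hi[1])
                & (cz >= lo[2]) & (cz < hi[2])
            )
        elif prim["kind"] == "ellipsoid":
            c = np.asarray(prim["center"], dtype=float)
            ax = np.asarray(prim["semi_axes"], dtype=float)
            inside = (
                ((cx - c[0]) / ax[0]) ** 2
                + ((cy - c[1]) / ax[1]) ** 2
                + ((cz - c[2]) / ax[2]) ** 2
            ) <= 1.0
        else:
            raise ValidationError(f"unknown primitive kind {prim['kind']!r}")
        annotation[inside] = lab

    # enforce the one-voxel background margin on all faces
    annotation[0, :, :] = 0
    annotation[-1, :, :] = 0
    annotation[:, 0, :] = 0
    annotation[:, -1, :] = 0
    annotation[:, :, 0] = 0
    annotation[:, :, -1] = 0

    rng = np.random.default_rng(seed)
    template = rng.random(shape) * 0.01 + (annotation > 0) * 1.0

    atlas = AtlasVolume(
        annotation=annotation,
        template=template,
        voxel_size_mm=spec.get("voxel_size_mm", (0.04, 0.04, 0.04)),
        bregma_voxel=spec.get("bregma_voxel", tuple((n - 1) / 2 for n in shape)),
    )
    entries = {0: LabelEntry(name="background", color=(0, 0, 0))}
    rng_colors = np.random.default_rng(seed + 1)
    for prim in prims:
        lab = int(prim["label"])
        color = tuple(int(c) for c in rng_colors.integers(32, 224, size=3))
        entries[lab] = LabelEntry(name=prim.get("name", f"region_{lab}"), color=color)
    return atlas, LabelTable(entries)
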