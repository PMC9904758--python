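"""JSON project files: one file per animal/session.

The project file replaces the GUI session of interactive tools: it
stores the atlas reference, slice poses, anchor sets, clicked points,
ROI mask paths and probe geometries, so every pipeline stage can be run
headlessly and reproducibly.  Serialisation uses UTF-8 JSON with sorted
keys, making load -> save idempotent byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .planner import ProbeGeometry
from .registration import AnchorSet
from .slicer import SlicePlane

SCHEMA_VERSION = 1


@dataclass
class ProjectFile:
    atlas: dict = field(default_factory=dict)  # paths, bregma, orientation note
    slices: dict = field(default_factory=dict)  # slice_id -> {plane, image_path}
    anchors: dict = field(default_factory=dict)  # slice_id -> AnchorSet
    clicked_points: list = field(default_factory=list)  # [slice_id, s, t]
    roi_masks: dict = field(default_factory=dict)  # slice_id -> mask path
    geometries: dict = field(default_factory=dict)  # name -> ProbeGeometry
    reports: dict = field(default_factory=dict)  # name -> path
    schema_version: int = SCHEMA_VERSION

    def add_slice(self, slice_id: str, plane: SlicePlane, image_path: str | None = None):
        self.slices[slice_id] = {"plane": plane, "image_path": image_path}

    def plane(self, slice_id: str) -> SlicePlane:
        if slice_id not in self.slices:
            raise ValidationError(f"unknown slice id {slice_id!r}")
        return self.slices[slice_id]["plane"]

    def validate(self) -> None:
        for slice_id in self.anchors:
            if slice_id not in self.slices:
                raise ValidationError(f"anchors reference unknown slice {slice_id!r}")
        for slice_id in self.roi_masks:
            if slice_id not in self.slices:
                raise ValidationError(f"ROI mask references unknown slice {slice_id!r}")
        for point in self.clicked_points:
            if point[0] not in self.slices:
                raise ValidationError(f"clicked point references unknown slice {point[0]!r}")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "atlas": self.atlas,
            "slices": {
                sid: {"plane": rec["plane"].to_dict(), "image_path": rec["image_path"]}
                for sid, rec in self.slices.items()
            },
            "anchors": {sid: a.to_dict() for sid, a in self.anchors.items()},
            "clicked_points": [list(p) for p in self.clicked_points],
            "roi_masks": dict(self.roi_masks),
            "geometries": {name: g.to_dict() for name, g in self.geometries.items()},
            "reports": dict(self.reports),
        }

    @staticmethod
    def from_dict(d: dict) -> "ProjectFile":
        if "schema_version" not in d:
            raise ValidationError("project file missing schema_version")
        proj = ProjectFile(
            atlas=d.get("atlas", {}),
            clicked_points=[tuple(p) for p in d.get("clicked_points", [])],
            roi_masks=d.get("roi_masks", {}),
            reports=d.get("reports", {}),
            schema_version=d["schema_version"],
        )
        for sid, rec in d.get("slices", {}).items():
            proj.slices[sid] = {
                "plane": SlicePlane.from_dict(rec["plane"]),
                "image_path": rec.get("image_path"),
            }
        for sid, a in d.get("anchors", {}).items():
            proj.anchors[sid] = AnchorSet.from_dict(a)
        for name, g in d.get("geometries", {}).items():
            proj.geometries[name] = ProbeGeometry.from_dict(g)
        proj.validate()
        return proj

    def save(self, path) -> None:
        self.validate()
        Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )

    @staticmethod
    def load(path) -> "ProjectFile":
        try:
            d = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ValidationError(f"cannot parse project file {path}: {exc}") from exc
        return ProjectFile.from_dict(d)
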