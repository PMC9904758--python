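"""Report writers: JSON, CSV and printable text tables.

Mirrors the read-outs a user would print and bring to the surgery room:
entry/tip coordinates, insertion angle and length, traversed regions
with per-region path length and channel counts, and per-region ROI
overlap percentages.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .errors import HistoAtlasError, ValidationError
from .planner import PlanReport

PLAN_CSV_COLUMNS = ["region", "name", "path_length_mm", "n_channels", "color"]
ROI_CSV_COLUMNS = ["region", "name", "overlap_voxels", "percent_of_region", "percent_of_roi", "color"]


def _color_hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def write_report(report, path, format: str = "json") -> None:
    """Write a plan report or ROI read-out to disk.

    ``report`` is a :class:`~histoatlas.planner.PlanReport` or the list
    of rows returned by :func:`~histoatlas.reconstruction.region_overlap`.
    CSV columns are stable and documented; txt renders a human-readable
    table of the same fields; JSON preserves full numeric precision.
    """
    path = Path(path)
    try:
        if format == "json":
            payload = report.to_dict() if isinstance(report, PlanReport) else report
            path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
        elif format == "csv":
            _write_csv(report, path)
        elif format == "txt":
            path.write_text(render_text(report))
        else:
            raise ValidationError(f"unknown report format {format!r}")
    except OSError as exc:
        raise HistoAtlasError(f"cannot write report to {path}: {exc}") from exc


def _write_csv(report, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if isinstance(report, PlanReport):
            writer.writerow(PLAN_CSV_COLUMNS)
            for row in report.regions:
                writer.writerow(
                    [
                        row["label_id"],
                        row["name"],
                        f"{row['path_length_mm']:.6f}",
                        row["n_channels"],
                        _color_hex(row["color"]),
                    ]
                )
        else:  # ROI overlap rows
            writer.writerow(ROI_CSV_COLUMNS)
            for row in report:
                pct = row["percent_of_region"]
                writer.writerow(
                    [
                        row["label_id"],
                        row["name"],
                        row["overlap_voxels"],
                        "" if pct is None else f"{pct:.4f}",
                        f"{row['percent_of_roi']:.4f}",
                        _color_hex(row["color"]),
                    ]
                )


def render_text(report) -> str:
    """Printable table mirroring the on-screen read-out."""
    lines = []
    if isinstance(report, PlanReport):
        lines.append("Probe plan read-out")
        lines.append("===================")
        lines.append(
            f"entry (AP, ML, DV) mm : ({report.entry.ap_mm:+.3f}, {report.entry.ml_mm:+.3f}, {report.entry.dv_mm:+.3f})"
        )
        lines.append(
            f"tip   (AP, ML, DV) mm : ({report.tip.ap_mm:+.3f}, {report.tip.ml_mm:+.3f}, {report.tip.dv_mm:+.3f})"
        )
        lines.append(f"lateral tilt          : {report.lateral_tilt_deg:.1f} deg")
        lines.append(f"AP tilt               : {report.ap_tilt_deg:.1f} deg")
        lines.append(f"insertion length      : {report.insertion_length_mm:.3f} mm")
        lines.append(f"channels in brain     : {report.total_channels_in_brain}")
        lines.append("")
        lines.append(f"{'region':>8}  {'name':<28} {'length_mm':>10} {'channels':>9}")
        for row in report.regions:
            lines.append(
                f"{row['label_id']:>8}  {row['name']:<28} {row['path_length_mm']:>10.3f} {row['n_channels']:>9}"
            )
    else:
        lines.append("ROI region read-out")
        lines.append("===================")
        lines.append(f"{'region':>8}  {'name':<28} {'voxels':>8} {'% region':>9} {'% ROI':>7}")
        for row in report:
            pct = row["percent_of_region"]
            pct_str = "-" if pct is None else f"{pct:.2f}"
            lines.append(
                f"{row['label_id']:>8}  {row['name']:<28} {row['overlap_voxels']:>8} {pct_str:>9} {row['percent_of_roi']:>7.2f}"
            )
    return "\n".join(lines) + "\n"
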