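"""Serialization of maneuver reports to JSON and flat CSV."""

from __future__ import annotations

import csv
import json
from typing import Any

__all__ = ["report_to_dict", "write_report", "read_report", "report_rows", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "step_index",
    "pose",
    "gravity_deg",
    "branch_label",
    "direction",
    "intensity",
    "final_compartment",
    "final_p",
]


def report_to_dict(report: Any) -> dict:
    """Accept a report object (anything with ``to_dict``) or a plain dict."""
    if isinstance(report, dict):
        return report
    return report.to_dict()


def report_rows(report: Any) -> list[dict]:
    """Flatten a maneuver report into one row per step x branch."""
    doc = report_to_dict(report)
    rows = []
    for step in doc.get("steps", []):
        for br in step["branches"]:
            rows.append(
                {
                    "step_index": step["index"],
                    "pose": step["pose"] or "",
                    "gravity_deg": step["gravity"],
                    "branch_label": br["label"],
                    "direction": br["nystagmus"]["direction"],
                    "intensity": br["nystagmus"]["intensity"],
                    "final_compartment": br["final"]["compartment"],
                    "final_p": "" if br["final"]["p"] is None else br["final"]["p"],
                }
            )
    return rows


def write_report(report: Any, path: str, format: str = "json") -> None:
    """Write a report as canonical JSON or a flat CSV.

    JSON output is indented with sorted keys, so identical reports are
    byte-identical on disk; CSV has one row per step x branch with the
    columns in :data:`CSV_COLUMNS` (an empty report yields a header-only
    file).
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(report_rows(report))
    else:
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
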