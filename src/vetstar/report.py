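"""Tray-ordered result reports as structured JSON.

The detection system's deliverable is a machine-readable report listing each
window's verdict in tray location order (row-major over the physical tray),
plus reagent/lab metadata.  The schema ships with the package
(``report_schema.json``) and serialization is canonical, so
serialize→parse→serialize is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .detection import DetectionBox, nms
from .synthetic import CLASS_NAMES

__all__ = ["TrayReport", "order_results", "build_report", "validate_report", "load_schema"]

SCHEMA_VERSION = "1.0"


def load_schema() -> dict:
    with resources.files("vetstar").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def order_results(dets: list, layout: str | None = None) -> list:
    """Row-major ordering of detections on one tray.

    Box centers are clustered into rows with tolerance half the median box
    height; rows sort by y, boxes within a row by x.  Returns
    ``[(position_index, row, col, det), ...]`` with indices starting at 1.
    """
    if not dets:
        return []
    cx = np.array([(d.x_min + d.x_max) / 2 for d in dets])
    cy = np.array([(d.y_min + d.y_max) / 2 for d in dets])
    tol = np.median([d.y_max - d.y_min for d in dets]) / 2
    order_y = np.argsort(cy)
    rows: list[list[int]] = []
    row_anchor = None
    for i in order_y:
        if row_anchor is None or cy[i] - row_anchor > tol:
            rows.append([int(i)])
            row_anchor = cy[i]
        else:
            rows[-1].append(int(i))
    out = []
    pos = 1
    for r, members in enumerate(rows, start=1):
        for c, i in enumerate(sorted(members, key=lambda i: cx[i]), start=1):
            out.append((pos, r, c, dets[i]))
            pos += 1
    return out


@dataclass
class TrayReport:
    reagent_source: str
    testing_company: str
    timestamp: str
    tray_layout: str
    results: list
    summary: dict

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "reagent_source": self.reagent_source,
            "testing_company": self.testing_company,
            "timestamp": self.timestamp,
            "tray_layout": self.tray_layout,
            "results": self.results,
            "summary": self.summary,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    @staticmethod
    def from_json(text: str) -> "TrayReport":
        d = json.loads(text)
        return TrayReport(
            d["reagent_source"], d["testing_company"], d["timestamp"],
            d["tray_layout"], d["results"], d["summary"],
        )


def build_report(dets: list, metadata: dict, layout: str | None = None) -> TrayReport:
    """Assemble a TrayReport from one image's detections.

    ``metadata`` must provide reagent_source, testing_company, timestamp and
    tray_layout.  Results are ordered by tray position; summary counts are
    tallied from the detections.  No image hashes are included.
    """
    missing = {"reagent_source", "testing_company", "timestamp", "tray_layout"} - set(metadata)
    if missing:
        raise ValueError(f"missing metadata fields: {sorted(missing)}")
    # one verdict per physical window: class-agnostic dedupe by confidence
    if len(dets) > 1:
        boxes = np.array([d.xyxy for d in dets])
        confs = np.array([d.confidence for d in dets])
        dets = [dets[i] for i in sorted(nms(boxes, confs, 0.5))]
    results = []
    counts = {"n_positive": 0, "n_negative": 0}
    for pos, row, col, d in order_results(dets, layout or metadata["tray_layout"]):
        label = CLASS_NAMES[d.class_id]
        counts["n_positive" if label == "positive" else "n_negative"] += 1
        results.append(
            {
                "position_index": pos,
                "row": row,
                "col": col,
                "class_label": label,
                "confidence": round(float(d.confidence), 4),
                "bbox": [round(float(v), 2) for v in d.xyxy],
            }
        )
    report = TrayReport(
        reagent_source=str(metadata["reagent_source"]),
        testing_company=str(metadata["testing_company"]),
        timestamp=str(metadata["timestamp"]),
        tray_layout=str(metadata["tray_layout"]),
        results=results,
        summary=counts,
    )
    validate_report(json.loads(report.to_json()))
    return report


def validate_report(payload: dict) -> None:
    """Check a report dict against the shipped schema (subset validator)."""
    schema = load_schema()
    for key, spec in schema["properties"].items():
        if key in schema.get("required", []) and key not in payload:
            raise ValueError(f"report missing required field {key!r}")
    if set(payload) - set(schema["properties"]):
        raise ValueError("report carries fields outside the schema")
    if "image_hash" in payload:
        raise ValueError("reports must not embed image hashes")
    prev = None
    for r in payload["results"]:
        if prev is not None and r["position_index"] <= prev:
            raise ValueError("results must be ordered by position_index")
        prev = r["position_index"]
        if r["class_label"] not in CLASS_NAMES:
            raise ValueError(f"unknown class label {r['class_label']!r}")
    n_pos = sum(r["class_label"] == "positive" for r in payload["results"])
    n_neg = sum(r["class_label"] == "negative" for r in payload["results"])
    if payload["summary"] != {"n_positive": n_pos, "n_negative": n_neg}:
        raise ValueError("summary counts disagree with results list")
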