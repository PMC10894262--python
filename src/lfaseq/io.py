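"""Manifest and image-stack IO.

Manifests are stored as CSV (columns: record_id, image_dir, interval_s,
duration_s, concentration, units, level, class_label, split) or as a JSON
mirror with the same keys; frame stacks are one 8-bit RGB PNG per timestamp,
named ``t<seconds>.png`` inside the record's image directory.  Timestamps are
reconstructed from the acquisition grid (interval, duration).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dataset import (
    ClassLabel,
    FrameSequence,
    Manifest,
    ManifestRecord,
    frame_grid,
)

__all__ = ["read_manifest", "write_manifest", "read_sequence",
           "write_sequence", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["record_id", "image_dir", "interval_s", "duration_s",
                    "concentration", "units", "level", "class_label", "split"]


def _records_from_rows(rows) -> Manifest:
    records = []
    seen = set()
    for i, row in enumerate(rows):
        missing = [c for c in MANIFEST_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise ValueError(f"row {i}: missing column(s) {missing}")
        rid = str(row["record_id"])
        if rid in seen:
            raise ValueError(f"duplicate record_id {rid!r}")
        seen.add(rid)
        try:
            records.append(ManifestRecord(
                record_id=rid,
                image_dir=str(row["image_dir"]),
                timestamps_s=frame_grid(float(row["duration_s"]),
                                        float(row["interval_s"])),
                concentration=float(row["concentration"]),
                level=int(row["level"]),
                class_label=ClassLabel[str(row["class_label"])],
                split=str(row["split"]),
                units=str(row["units"]),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"row {i} (record_id {rid!r}): {exc}") from exc
    return Manifest(records)


def _rows_from_manifest(manifest: Manifest):
    rows = []
    for r in manifest.records:
        ts = r.timestamps_s
        interval = ts[0] if len(ts) == 1 else ts[1] - ts[0]
        rows.append({
            "record_id": r.record_id,
            "image_dir": r.image_dir,
            "interval_s": interval,
            "duration_s": ts[-1],
            "concentration": r.concentration,
            "units": r.units,
            "level": r.level,
            "class_label": r.class_label.name,
            "split": r.split,
        })
    return rows


def read_manifest(path) -> Manifest:
    """Read a manifest from CSV or JSON (chosen by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())["records"]
    else:
        frame = pd.read_csv(path)
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"manifest missing column(s) {missing}")
        rows = frame.to_dict("records")
    return _records_from_rows(rows)


def write_manifest(manifest: Manifest, path) -> None:
    """Write a manifest as CSV or JSON (chosen by file extension)."""
    path = Path(path)
    rows = _rows_from_manifest(manifest)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"records": rows}, indent=2) + "\n")
    else:
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def _frame_name(t: float) -> str:
    return f"t{t:g}.png"


def read_sequence(image_dir, timestamps) -> FrameSequence:
    """Load the PNG stack for one record, ordered by timestamp."""
    image_dir = Path(image_dir)
    frames = []
    shape = None
    for t in timestamps:
        fp = image_dir / _frame_name(float(t))
        if not fp.exists():
            raise FileNotFoundError(
                f"missing frame for timestamp {t:g}s: {fp}")
        frame = iio.imread(fp)
        if frame.dtype != np.uint8 or frame.ndim != 3 or frame.shape[-1] != 3:
            raise ValueError(f"{fp}: 8-bit RGB required")
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(f"{fp}: dimension mismatch "
                             f"({frame.shape} vs {shape})")
        frames.append(frame)
    return FrameSequence(np.stack(frames),
                         np.asarray([float(t) for t in timestamps]))


def write_sequence(image_dir, seq: FrameSequence) -> None:
    """Write one PNG per frame under image_dir."""
    image_dir = Path(image_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    for frame, t in zip(seq.frames, seq.timestamps_s):
        iio.imwrite(image_dir / _frame_name(float(t)), frame)
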