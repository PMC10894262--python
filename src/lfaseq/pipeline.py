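"""Manifest-level pipeline: locate ROIs, assemble tensors, train, evaluate.

Glue between the manifest/simulator layer and the estimators: every record's
sequence is ROI-located on its late frames, cropped in the requested mode
(test line only by default — the higher-accuracy choice — or the wide
window), optionally truncated to its first k frames for duration sweeps, and
fed to the conv-LSTM estimators.  Training doubles the train split with the
HSV color-space augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import FrameSequence, Manifest
from .io import read_sequence
from .metrics import (
    BinaryCall,
    EvalReport,
    binary_decision,
    confusion,
    frames_vs_rmse,
    roc_auc,
    rmse,
    score_to_level,
    sens_spec_acc,
)
from .model import (
    ModelConfig,
    ScoreBatch,
    StripSequenceRegressor,
    build_model,
    hsv_augment,
)
from .dataset import level_to_class
from .roi import RoiMode, control_line_valid, crop_roi, locate_lines, window_box

__all__ = ["RoiSettings", "PreparedRecord", "prepare_record", "load_panel",
           "train_on_panel", "predict_panel", "evaluate_panel",
           "tradeoff_curve"]


@dataclass(frozen=True)
class RoiSettings:
    """Detector settings derived from the strip layout."""

    mode: RoiMode = RoiMode.TEST_LINE
    line_width_px: int = 4
    expected_spacing_px: float = 40.0
    min_control_contrast: float = 0.1


@dataclass
class PreparedRecord:
    record_id: str
    cropped: FrameSequence
    valid: bool
    test_box: object
    control_box: object
    level: int
    split: str


def _record_sequence(record, image_root=None) -> FrameSequence:
    seq = getattr(record, "sequence", None)
    if seq is not None:
        return seq
    root = Path(image_root) if image_root is not None else Path(".")
    return read_sequence(root / record.image_dir, record.timestamps_s)


def prepare_record(record, roi: RoiSettings = RoiSettings(),
                   image_root=None) -> PreparedRecord:
    """Locate lines, check control-line validity, and crop one record."""
    seq = _record_sequence(record, image_root)
    test_box, control_box = locate_lines(
        seq, line_width_px=roi.line_width_px,
        expected_spacing_px=roi.expected_spacing_px)
    valid = control_line_valid(seq, control_box,
                               min_contrast=roi.min_control_contrast)
    if roi.mode is RoiMode.WINDOW:
        box = window_box(test_box, control_box, width_px=seq.frames.shape[2])
    elif roi.mode is RoiMode.CONTROL_LINE:
        box = control_box
    else:
        box = test_box
    return PreparedRecord(record.record_id, crop_roi(seq, box), valid,
                          test_box, control_box, record.level, record.split)


def load_panel(manifest: Manifest, roi: RoiSettings = RoiSettings(),
               image_root=None, frame_count: int | None = None) -> list:
    """Prepare every record; optionally truncate to the first k frames."""
    prepared = []
    for record in manifest.records:
        p = prepare_record(record, roi, image_root)
        if frame_count is not None:
            if frame_count > len(p.cropped):
                raise ValueError(
                    f"record {record.record_id!r} has only "
                    f"{len(p.cropped)} frames (need {frame_count})")
            p.cropped = FrameSequence(
                p.cropped.frames[:frame_count],
                p.cropped.timestamps_s[:frame_count])
        prepared.append(p)
    return prepared


def _split_xy(prepared, split, augment=False):
    X, y = [], []
    for p in prepared:
        if p.split != split:
            continue
        samples = hsv_augment(p.cropped) if augment else [p.cropped]
        for s in samples:
            X.append(s)
            y.append(float(p.level))
    return X, np.asarray(y)


def train_on_panel(manifest: Manifest, config: ModelConfig | None = None,
                   roi: RoiSettings = RoiSettings(), image_root=None,
                   frame_count: int | None = None):
    """Train the level regressor on a manifest's train/val splits.

    Returns (model, TrainReport).  The train split is doubled by the HSV
    augmentation; the validation split is used as-is for the loss trace.
    """
    config = config or ModelConfig()
    prepared = load_panel(manifest, roi, image_root, frame_count)
    X_train, y_train = _split_xy(prepared, "train", augment=True)
    X_val, y_val = _split_xy(prepared, "val", augment=False)
    if not X_train:
        raise ValueError("manifest has no train records")
    model = build_model(config)
    model.fit(X_train, y_train,
              X_val=X_val or None, y_val=y_val if len(y_val) else None)
    return model, model.train_report_


def predict_panel(model: StripSequenceRegressor, manifest: Manifest,
                  roi: RoiSettings = RoiSettings(), image_root=None,
                  threshold: float = 0.5,
                  frame_count: int | None = None) -> list:
    """Per-record predictions: score, level, class, binary call, validity."""
    prepared = load_panel(manifest, roi, image_root, frame_count)
    scores = model.predict([p.cropped for p in prepared])
    out = []
    for p, score in zip(prepared, scores):
        entry = {
            "record_id": p.record_id,
            "valid": bool(p.valid),
            "true_level": p.level,
            "split": p.split,
            "roi": {"test": p.test_box.to_dict(),
                    "control": p.control_box.to_dict()},
        }
        if p.valid:
            level = score_to_level(float(score))
            entry.update({
                "score": float(score),
                "level": level,
                "class": level_to_class(level).name,
                "call": binary_decision(float(score), threshold).name,
            })
        else:
            entry.update({"score": None, "level": None, "class": None,
                          "call": None})
        out.append(entry)
    return out


def evaluate_panel(model, manifest: Manifest, split: str = "test",
                   roi: RoiSettings = RoiSettings(), image_root=None,
                   threshold: float = 0.5,
                   frame_count: int | None = None) -> EvalReport:
    """Full diagnostic-accuracy report on one manifest split."""
    preds = [p for p in predict_panel(model, manifest, roi, image_root,
                                      threshold, frame_count)
             if p["split"] == split or split == "all"]
    usable = [p for p in preds if p["valid"]]
    if not usable:
        raise ValueError(f"no valid records in split {split!r}")
    truth_levels = [p["true_level"] for p in usable]
    scores = [p["score"] for p in usable]
    calls = [BinaryCall[p["call"]] for p in usable]
    truth_classes = [level_to_class(lv) for lv in truth_levels]
    pred_classes = [level_to_class(p["level"]) for p in usable]

    table = confusion(truth_classes, pred_classes)
    # binary counts must follow the thresholded call, not the rounded class
    binary_truth = [c.name != "NEGATIVE" for c in truth_classes]
    tp = sum(t and c is BinaryCall.POSITIVE for t, c in zip(binary_truth, calls))
    fn = sum(t and c is BinaryCall.NEGATIVE for t, c in zip(binary_truth, calls))
    fp = sum((not t) and c is BinaryCall.POSITIVE
             for t, c in zip(binary_truth, calls))
    tn = sum((not t) and c is BinaryCall.NEGATIVE
             for t, c in zip(binary_truth, calls))
    table.tp, table.fn, table.fp, table.tn = tp, fn, fp, tn

    sens, spec, acc = sens_spec_acc(table)
    return EvalReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=roc_auc(scores, truth_classes),
        rmse=rmse(ScoreBatch(tuple(float(t) for t in truth_levels),
                             tuple(float(s) for s in scores))),
        confusion=table, n=len(usable),
    )


def tradeoff_curve(manifest: Manifest, frame_counts, seeds,
                   config: ModelConfig | None = None,
                   roi: RoiSettings = RoiSettings(), image_root=None,
                   split: str = "test"):
    """Frame-count vs held-out RMSE trade-off on a manifest."""
    base = config or ModelConfig()

    def train_fn(panel, k, seed):
        cfg = ModelConfig(**{**_cfg_dict(base), "seed": int(seed)})
        model, _ = train_on_panel(panel, cfg, roi, image_root, frame_count=k)
        report = evaluate_panel(model, panel, split, roi, image_root,
                                frame_count=k)
        return report.rmse

    return frames_vs_rmse(train_fn, manifest, frame_counts, seeds)


def _cfg_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict
    return asdict(cfg)
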