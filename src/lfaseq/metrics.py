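"""Decision mapping and diagnostic-accuracy evaluation.

Scores live on the color-chart level scale (0-8).  Rounding a score gives a
chart level, the level maps onto the five reporting classes, and a strict
threshold on the raw score gives the binary positive/negative call.  The
evaluation artifacts are the standard diagnostic-accuracy quantities:
confusion tables, sensitivity/specificity/accuracy in percent, rank-based
ROC-AUC, RMSE, and the frame-count versus RMSE trade-off curve.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dataset import ClassLabel, level_to_class
from .model import ScoreBatch

__all__ = [
    "BinaryCall",
    "ConfusionTable",
    "EvalReport",
    "TradeoffCurve",
    "score_to_level",
    "binary_decision",
    "confusion",
    "sens_spec_acc",
    "roc_auc",
    "rmse",
    "frames_vs_rmse",
]

_CLASS_ORDER = [ClassLabel.HIGH, ClassLabel.MIDDLE, ClassLabel.MID_LOW,
                ClassLabel.LOW, ClassLabel.NEGATIVE]


class BinaryCall(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass
class ConfusionTable:
    """Binary TP/FP/TN/FN counts plus the 5x5 class matrix.

    The multiclass matrix is indexed truth-rows x prediction-columns in the
    order HIGH, MIDDLE, MID_LOW, LOW, NEGATIVE.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    multiclass: np.ndarray = field(
        default_factory=lambda: np.zeros((5, 5), dtype=int))

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        self.multiclass = np.asarray(self.multiclass, dtype=int)
        if self.multiclass.shape != (5, 5) or (self.multiclass < 0).any():
            raise ValueError("multiclass table must be a non-negative 5x5 matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def class_order(self):
        return list(_CLASS_ORDER)


@dataclass
class EvalReport:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    rmse: float
    confusion: ConfusionTable
    n: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "accuracy": round(self.accuracy, 1),
            "auc": self.auc,
            "rmse": self.rmse,
            "n": self.n,
            "confusion": {
                "binary": {"TP": self.confusion.tp, "FP": self.confusion.fp,
                           "TN": self.confusion.tn, "FN": self.confusion.fn},
                "multiclass": self.confusion.multiclass.tolist(),
                "class_order": [c.name for c in _CLASS_ORDER],
            },
        }


@dataclass
class TradeoffCurve:
    frame_counts: list
    rmse_values: list
    resource_proxy: list

    def __post_init__(self) -> None:
        if not (len(self.frame_counts) == len(self.rmse_values)
                == len(self.resource_proxy)):
            raise ValueError("curve fields must have equal length")
        if any(a >= b for a, b in zip(self.frame_counts,
                                      self.frame_counts[1:])):
            raise ValueError("frame_counts must be strictly increasing")


def score_to_level(y_hat: float) -> int:
    """Round a regression score half-away-from-zero and clip to [0, 8]."""
    if not math.isfinite(y_hat):
        raise ValueError("score must be finite")
    level = math.floor(abs(y_hat) + 0.5) * (1 if y_hat >= 0 else -1)
    return int(min(max(level, 0), 8))


def binary_decision(y_hat: float, threshold: float = 0.5) -> BinaryCall:
    """POSITIVE iff the score strictly surpasses the threshold."""
    if not (math.isfinite(y_hat) and math.isfinite(threshold)):
        raise ValueError("score and threshold must be finite")
    return BinaryCall.POSITIVE if y_hat > threshold else BinaryCall.NEGATIVE


def _as_binary(label) -> bool:
    """True for positive. Accepts ClassLabel, BinaryCall, level int, or str."""
    if isinstance(label, ClassLabel):
        return label is not ClassLabel.NEGATIVE
    if isinstance(label, BinaryCall):
        return label is BinaryCall.POSITIVE
    if isinstance(label, (bool, np.bool_)):
        return bool(label)
    if isinstance(label, (int, np.integer)):
        return level_to_class(int(label)) is not ClassLabel.NEGATIVE
    if isinstance(label, str):
        if label in BinaryCall.__members__ and label != "NEGATIVE":
            return True
        return ClassLabel[label] is not ClassLabel.NEGATIVE
    raise ValueError(f"unsupported label {label!r}")


def _as_class(label) -> ClassLabel | None:
    if isinstance(label, ClassLabel):
        return label
    if isinstance(label, (int, np.integer)):
        return level_to_class(int(label))
    if isinstance(label, str) and label in ClassLabel.__members__:
        return ClassLabel[label]
    return None


def confusion(truth, pred) -> ConfusionTable:
    """Exact confusion counts; classes collapse to binary by NEGATIVE vs rest.

    Inputs may be ClassLabel values, chart levels (ints), BinaryCall values
    or their string names.  The 5x5 matrix is filled only when both sides
    carry class information.
    """
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    if not truth:
        raise ValueError("empty input")
    table = ConfusionTable()
    mc = np.zeros((5, 5), dtype=int)
    for t, p in zip(truth, pred):
        t_pos, p_pos = _as_binary(t), _as_binary(p)
        if t_pos and p_pos:
            table.tp += 1
        elif t_pos:
            table.fn += 1
        elif p_pos:
            table.fp += 1
        else:
            table.tn += 1
        tc, pc = _as_class(t), _as_class(p)
        if tc is not None and pc is not None:
            mc[_CLASS_ORDER.index(tc), _CLASS_ORDER.index(pc)] += 1
    table.multiclass = mc
    return table


def sens_spec_acc(table: ConfusionTable):
    """(sensitivity, specificity, accuracy) in percent, unrounded.

    Sensitivity = 100*TP/(TP+FN), specificity = 100*TN/(TN+FP), accuracy =
    100*(TP+TN)/n.  Display rounding to one decimal is the caller's job
    (EvalReport.to_dict applies it).
    """
    if table.tp + table.fn == 0 or table.tn + table.fp == 0:
        raise ValueError("undefined metric: need at least one positive and "
                         "one negative truth")
    sens = 100.0 * table.tp / (table.tp + table.fn)
    spec = 100.0 * table.tn / (table.tn + table.fp)
    acc = 100.0 * (table.tp + table.tn) / table.n
    return sens, spec, acc


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve by the Mann-Whitney rank formula.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2 — identical to trapezoidal integration
    of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([_as_binary(t) for t in truth])
    if len(scores) != len(pos):
        raise ValueError("scores and truth must have equal length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def rmse(batch: ScoreBatch) -> float:
    """Root-mean-squared error sqrt((1/N) * sum (y_i - y_hat_i)^2)."""
    y = np.asarray(batch.y)
    y_hat = np.asarray(batch.y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def frames_vs_rmse(train_fn, panel, frame_counts, seeds) -> TradeoffCurve:
    """Held-out RMSE as a function of the number of frames used.

    For each frame count k, ``train_fn(panel, k, seed)`` must train a fresh
    model on sequences truncated to their first k frames and return the
    held-out RMSE; the curve records the median over seeds.  The resource
    proxy is k normalized by the largest k (frame count stands in for
    compute/memory, which scales monotonically with sequence length).
    """
    frame_counts = [int(k) for k in frame_counts]
    if any(a >= b for a, b in zip(frame_counts, frame_counts[1:])):
        raise ValueError("frame_counts must be strictly increasing")
    max_frames = min(len(r.timestamps_s) for r in panel.records)
    if frame_counts and frame_counts[-1] > max_frames:
        raise ValueError(
            f"frame count {frame_counts[-1]} exceeds available frames "
            f"({max_frames})")
    rmses = [float(np.median([train_fn(panel, k, s) for s in seeds]))
             for k in frame_counts]
    top = max(frame_counts) if frame_counts else 1
    return TradeoffCurve(frame_counts, rmses,
                         [k / top for k in frame_counts])
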