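"""Test-line / control-line localization and ROI cropping.

A trained object detector is overkill for fixed-geometry reader images; the
detector here scores each column by its gold-nanoparticle color deficit
(green+blue relative to red), subtracts a rolling-median baseline, and takes
the two most prominent peaks of the late-frame average profile.  Any callable
with the same ``FrameSequence -> (test RoiBox, control RoiBox)`` contract can
be plugged in instead (e.g. a learned detector).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .dataset import FrameSequence
from .simulate import region_contrast

__all__ = [
    "RoiMode",
    "RoiBox",
    "LineProfile",
    "line_profile",
    "locate_lines",
    "window_box",
    "crop_roi",
    "control_line_valid",
]


class RoiMode(enum.Enum):
    TEST_LINE = "TEST_LINE"
    WINDOW = "WINDOW"
    CONTROL_LINE = "CONTROL_LINE"


@dataclass(frozen=True)
class RoiBox:
    """0-based, half-open [start, end) crop box."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    mode: RoiMode
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.row_start >= self.row_end or self.col_start >= self.col_end:
            raise ValueError("box must have positive extent on both axes")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("box must lie within image bounds")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def col_center(self) -> float:
        return (self.col_start + self.col_end) / 2.0

    def to_dict(self) -> dict:
        return {
            "row_start": self.row_start, "row_end": self.row_end,
            "col_start": self.col_start, "col_end": self.col_end,
            "mode": self.mode.value, "confidence": self.confidence,
        }


@dataclass(frozen=True)
class LineProfile:
    positions_px: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_px)
        val = np.asarray(self.values, dtype=float)
        if len(pos) != len(val):
            raise ValueError("positions and values must have equal length")
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions_px", pos)
        object.__setattr__(self, "values", val)


def line_profile(frame: np.ndarray, baseline_window: int = 31) -> LineProfile:
    """Per-column line-signal score for one RGB frame.

    Score = row-mean of (R - (G+B)/2)/255, with a rolling-median baseline
    subtracted so that slowly varying background (wet membrane, illumination)
    drops out and line peaks remain.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("RGB frame of shape (H, W, 3) required")
    if frame.shape[1] < 16:
        raise ValueError("frame too narrow (width >= 16 px required)")
    img = frame.astype(np.float64)
    deficit = np.mean(img[..., 0] - (img[..., 1] + img[..., 2]) / 2.0,
                      axis=0) / 255.0
    baseline = median_filter(deficit, size=baseline_window, mode="nearest")
    return LineProfile(np.arange(frame.shape[1]), deficit - baseline)


def _boxes_from_centers(shape, test_c, control_c, line_width_px,
                        conf_test, conf_control):
    h, w = shape

    def make(center, mode, conf):
        half = int(math.ceil(1.5 * line_width_px))
        lo = max(int(round(center)) - half, 0)
        hi = min(int(round(center)) + half, w)
        return RoiBox(int(0.1 * h), max(int(0.9 * h), int(0.1 * h) + 1),
                      lo, hi, mode, conf)

    return (make(test_c, RoiMode.TEST_LINE, conf_test),
            make(control_c, RoiMode.CONTROL_LINE, conf_control))


def locate_lines(seq: FrameSequence, *, line_width_px: int = 4,
                 min_separation_px: int = 10, noise_floor: float = 0.02,
                 expected_spacing_px: float | None = None,
                 baseline_window: int = 31):
    """Locate the test and control lines; returns (test RoiBox, control RoiBox).

    Column profiles are averaged over the last quarter of frames (lines are
    strongest late in the assay).  The two most prominent peaks are assigned
    test = upstream, control = downstream.  On negative strips only the
    control line is visible: if ``expected_spacing_px`` is given, the test
    box is then placed upstream of the control line at that spacing with low
    confidence; otherwise a single peak is an error, as is none ("control
    line not found").
    """
    if len(seq) == 0:
        raise ValueError("empty frame sequence")
    n_late = max(1, math.ceil(0.25 * len(seq)))
    profiles = [line_profile(f, baseline_window).values
                for f in seq.frames[-n_late:]]
    mean_profile = np.mean(profiles, axis=0)

    peaks, props = find_peaks(mean_profile, prominence=noise_floor,
                              distance=min_separation_px)
    prominences = props["prominences"]
    order = np.argsort(prominences)[::-1]
    shape = seq.frames.shape[1:3]
    norm = max(float(prominences[order[0]]), 1e-12) if len(peaks) else 1.0

    if len(peaks) >= 2:
        top2 = sorted(peaks[order[:2]].tolist())
        confs = {int(p): min(1.0, float(pr) / norm)
                 for p, pr in zip(peaks, prominences)}
        test_c, control_c = top2
        return _boxes_from_centers(shape, test_c, control_c, line_width_px,
                                   confs[test_c], confs[control_c])
    if len(peaks) == 1 and expected_spacing_px is not None:
        # the control line is the one guaranteed present on a valid strip
        control_c = int(peaks[0])
        test_c = control_c - expected_spacing_px
        if test_c - 1.5 * line_width_px < 0:
            raise ValueError("control line not found (implied test box "
                             "outside the image)")
        return _boxes_from_centers(shape, test_c, control_c, line_width_px,
                                   0.0, min(1.0, float(prominences[0]) / norm))
    raise ValueError("control line not found (invalid strip)")


def window_box(test: RoiBox, control: RoiBox, margin_px: int = 6,
               width_px: int | None = None) -> RoiBox:
    """Wide box spanning upstream of the test line to downstream of control."""
    lo = max(test.col_start - margin_px, 0)
    hi = control.col_end + margin_px
    if width_px is not None:
        hi = min(hi, width_px)
    return RoiBox(test.row_start, test.row_end, lo, hi, RoiMode.WINDOW,
                  min(test.confidence, control.confidence))


def crop_roi(seq: FrameSequence, box: RoiBox) -> FrameSequence:
    """Crop every frame to the box; timestamps are preserved."""
    _, h, w, _ = seq.frames.shape
    if box.row_end > h or box.col_end > w:
        raise ValueError("box out of bounds for this sequence")
    return FrameSequence(
        seq.frames[:, box.row_start:box.row_end, box.col_start:box.col_end],
        seq.timestamps_s,
    )


def control_line_valid(seq: FrameSequence, control: RoiBox,
                       min_contrast: float = 0.1) -> bool:
    """True iff the control line shows at least ``min_contrast`` at the end.

    Measures the background-subtracted color contrast of the control box in
    the final frame; a strip whose control line never develops is invalid.
    """
    if len(seq) == 0:
        return False
    try:
        contrast = region_contrast(seq.frames[-1], control.col_start,
                                   control.col_end)
    except ValueError:
        return False
    return contrast >= min_contrast
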