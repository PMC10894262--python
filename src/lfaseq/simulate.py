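"""Synthetic time-resolved lateral-flow strip images with known ground truth.

The simulator emulates the temporal phenomenology of a colloidal-gold LFA
read by a fixed reader: buffer wicks along the membrane with a Washburn-like
sqrt(t) front that reaches the test line at ``arrival_time_s`` (~30 s in the
default geometry); the test line then develops first-order toward a
concentration-dependent saturation, the control line develops for every
sample once the front passes it, and a decaying wet-membrane wash darkens the
wetted region early in the assay.  Line and wash color follow the
reddish-purple gold-nanoparticle convention: a contrast q removes q*255
counts from the green and blue channels while leaving red untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import (
    ClassLabel,
    DilutionLadder,
    FrameSequence,
    Manifest,
    ManifestRecord,
    concentration_to_level,
    frame_grid,
    level_to_class,
)

__all__ = [
    "StripLayout",
    "KineticParams",
    "AcquisitionSpec",
    "NoiseSpec",
    "GroundTruth",
    "expected_line_contrast",
    "simulate_sequence",
    "simulate_panel",
    "region_contrast",
]


@dataclass(frozen=True)
class StripLayout:
    """Strip geometry: image size, line centers along the flow axis, color."""

    image_height_px: int = 40
    image_width_px: int = 160
    flow_axis: str = "horizontal"
    test_line_center_px: int = 60
    control_line_center_px: int = 100
    line_width_px: int = 4
    membrane_base_rgb: tuple = (250, 248, 245)

    def __post_init__(self) -> None:
        if self.flow_axis != "horizontal":
            raise ValueError("only horizontal flow is supported")
        if self.image_height_px < 16 or self.image_width_px < 16:
            raise ValueError("image dimensions must be at least 16 px")
        if not (0 < self.test_line_center_px < self.control_line_center_px
                < self.image_width_px):
            raise ValueError(
                "need 0 < test center < control center < width "
                "(flow reaches the test line first)"
            )
        if self.line_width_px < 1:
            raise ValueError("line_width_px must be >= 1")
        if not all(0 <= v <= 255 for v in self.membrane_base_rgb):
            raise ValueError("membrane_base_rgb components must lie in [0, 255]")


@dataclass(frozen=True)
class KineticParams:
    """First-order color-development model.

    The test-line contrast at time t for concentration c is
    ``A_max * c/(c+K) * (1 - exp(-k*(t - arrival)))`` for t past the arrival
    time: Michaelis-Menten saturation in concentration times first-order
    development in time.  The control line develops with the same rate from
    its own (later) arrival, with fixed amplitude ``control_amplitude``.
    """

    arrival_time_s: float = 30.0
    dev_rate_k: float = 0.03
    sat_amplitude_A_max: float = 0.85
    half_sat_conc_K: float = 5.0
    control_amplitude: float = 0.6
    bg_wash_amplitude: float = 0.15
    bg_decay_tau_s: float = 90.0

    def __post_init__(self) -> None:
        for name in ("arrival_time_s", "dev_rate_k", "half_sat_conc_K",
                     "bg_decay_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("sat_amplitude_A_max", "control_amplitude",
                     "bg_wash_amplitude"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AcquisitionSpec:
    duration_s: float = 120.0
    interval_s: float = 10.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if self.duration_s < self.interval_s:
            raise ValueError("duration_s must cover at least one interval")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit acquisition is supported")


@dataclass(frozen=True)
class NoiseSpec:
    pixel_sigma: float = 2.0
    illum_gain_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sigma < 0 or self.illum_gain_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    concentration: float
    level: int
    class_label: ClassLabel
    true_test_line_center_px: int
    true_control_line_center_px: int

    def __post_init__(self) -> None:
        if (self.level == 0) != (self.class_label is ClassLabel.NEGATIVE):
            raise ValueError("level 0 and class NEGATIVE must coincide")
        if (self.concentration == 0) != (self.level == 0):
            raise ValueError("zero concentration must coincide with level 0")


def expected_line_contrast(kinetics: KineticParams, concentration: float,
                           t: float) -> float:
    """Closed-form test-line contrast in [0, 1] at time t.

    Zero before the wicking front arrives; thereafter first-order development
    toward the concentration-dependent saturation amplitude.  Non-decreasing
    in both t and concentration.
    """
    if t < 0 or concentration < 0:
        raise ValueError("time and concentration must be non-negative")
    if concentration == 0 or t <= kinetics.arrival_time_s:
        return 0.0
    sat = (kinetics.sat_amplitude_A_max * concentration
           / (concentration + kinetics.half_sat_conc_K))
    return sat * (1.0 - math.exp(-kinetics.dev_rate_k
                                 * (t - kinetics.arrival_time_s)))


def _front_position(layout: StripLayout, kinetics: KineticParams,
                    t: float) -> float:
    # Washburn sqrt(t) front, calibrated so the test line is reached exactly
    # at arrival_time_s.
    if t <= 0:
        return 0.0
    pos = layout.test_line_center_px * math.sqrt(t / kinetics.arrival_time_s)
    return min(pos, float(layout.image_width_px))


def _control_arrival(layout: StripLayout, kinetics: KineticParams) -> float:
    ratio = layout.control_line_center_px / layout.test_line_center_px
    return kinetics.arrival_time_s * ratio * ratio


def _line_mask(layout: StripLayout, center: int) -> slice:
    half = layout.line_width_px / 2.0
    lo = int(round(center - half))
    return slice(max(lo, 0), min(lo + layout.line_width_px,
                                 layout.image_width_px))


def _render_frame(layout: StripLayout, kinetics: KineticParams,
                  concentration: float, t: float) -> np.ndarray:
    """Noiseless float frame (H, W, 3) in 8-bit units."""
    h, w = layout.image_height_px, layout.image_width_px
    frame = np.empty((h, w, 3), dtype=np.float64)
    frame[:] = np.asarray(layout.membrane_base_rgb, dtype=np.float64)

    # contrast per column, applied as a G+B deficit
    deficit = np.zeros(w)
    front = _front_position(layout, kinetics, t)
    wet = int(math.floor(front))
    if wet > 0:
        deficit[:wet] += (kinetics.bg_wash_amplitude
                          * math.exp(-t / kinetics.bg_decay_tau_s))
    q_test = expected_line_contrast(kinetics, concentration, t)
    if q_test > 0:
        deficit[_line_mask(layout, layout.test_line_center_px)] += q_test
    t_ctrl = _control_arrival(layout, kinetics)
    if t > t_ctrl:
        q_ctrl = kinetics.control_amplitude * (
            1.0 - math.exp(-kinetics.dev_rate_k * (t - t_ctrl)))
        deficit[_line_mask(layout, layout.control_line_center_px)] += q_ctrl

    frame[:, :, 1] -= 255.0 * deficit
    frame[:, :, 2] -= 255.0 * deficit
    return frame


def simulate_sequence(layout: StripLayout, kinetics: KineticParams,
                      concentration: float, acq: AcquisitionSpec,
                      noise: NoiseSpec, *, ladder: DilutionLadder | None = None,
                      level: int | None = None):
    """Simulate one assay run; returns (FrameSequence, GroundTruth).

    The color-chart level is derived from ``ladder`` when one is supplied,
    taken from ``level`` otherwise; a blank (concentration 0) is always level
    0.  Output is bit-identical for identical inputs including the noise seed.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if kinetics.arrival_time_s >= acq.duration_s:
        raise ValueError("assay too short: sample never reaches the test line")
    if ladder is not None:
        level = concentration_to_level(concentration, ladder)
    elif level is None:
        if concentration == 0:
            level = 0
        else:
            raise ValueError(
                "positive concentration needs an explicit level or a ladder"
            )
    if (concentration == 0) != (level == 0):
        raise ValueError("level 0 is reserved for blanks (concentration 0)")

    timestamps = frame_grid(acq.duration_s, acq.interval_s)
    rng = np.random.default_rng(noise.seed)
    frames = np.empty(
        (len(timestamps), layout.image_height_px, layout.image_width_px, 3),
        dtype=np.uint8,
    )
    for i, t in enumerate(timestamps):
        frame = _render_frame(layout, kinetics, concentration, t)
        if noise.illum_gain_sigma > 0:
            frame = frame * rng.normal(1.0, noise.illum_gain_sigma)
        if noise.pixel_sigma > 0:
            frame = frame + rng.normal(0.0, noise.pixel_sigma, frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames, np.asarray(timestamps, dtype=float))
    truth = GroundTruth(
        concentration=float(concentration),
        level=int(level),
        class_label=level_to_class(int(level)),
        true_test_line_center_px=layout.test_line_center_px,
        true_control_line_center_px=layout.control_line_center_px,
    )
    return seq, truth


def region_contrast(frame: np.ndarray, col_lo: int, col_hi: int,
                    bg_gap: int = 6, bg_width: int = 6) -> float:
    """G+B deficit of a column band relative to neighboring membrane, in [0,1].

    Measures mean (R - (G+B)/2)/255 over the central 80% of rows inside
    [col_lo, col_hi) and subtracts the same statistic over flanking background
    bands, cancelling the shared wet-membrane wash.
    """
    if col_lo >= col_hi:
        raise ValueError("empty column band")
    h, w = frame.shape[:2]
    r0, r1 = int(0.1 * h), max(int(0.1 * h) + 1, int(math.ceil(0.9 * h)))
    img = frame[r0:r1].astype(np.float64)

    def deficit(lo: int, hi: int) -> float:
        band = img[:, max(lo, 0):min(hi, w)]
        if band.size == 0:
            return 0.0
        return float(np.mean(band[..., 0] - (band[..., 1] + band[..., 2]) / 2.0)) / 255.0

    bg_vals = []
    if col_lo - bg_gap - bg_width >= 0:
        bg_vals.append(deficit(col_lo - bg_gap - bg_width, col_lo - bg_gap))
    if col_hi + bg_gap + bg_width <= w:
        bg_vals.append(deficit(col_hi + bg_gap, col_hi + bg_gap + bg_width))
    bg = float(np.mean(bg_vals)) if bg_vals else 0.0
    return deficit(col_lo, col_hi) - bg


def simulate_panel(ladder: DilutionLadder, reps_per_point: int,
                   n_negatives: int, layout: StripLayout,
                   kinetics: KineticParams, acq: AcquisitionSpec,
                   noise: NoiseSpec, out_dir=None, *,
                   image_writer=None) -> Manifest:
    """Simulate a dilution-ladder panel plus blanks and assemble a manifest.

    One record per (ladder point x replicate) plus ``n_negatives`` blanks.
    Per-record noise streams are derived deterministically from
    ``noise.seed``.  When ``out_dir`` is given, frames are written as
    ``<record_id>/t<seconds>.png`` under it and manifest image_dir fields
    point there; otherwise sequences stay in memory on the returned records
    (attribute ``sequence``).
    """
    if reps_per_point < 1:
        raise ValueError("reps_per_point must be >= 1")
    if n_negatives < 0:
        raise ValueError("n_negatives must be >= 0")

    jobs = [(c, rep) for c in ladder.concentrations
            for rep in range(reps_per_point)]
    jobs += [(0.0, rep) for rep in range(n_negatives)]

    records = []
    for idx, (c, rep) in enumerate(jobs):
        level = concentration_to_level(c, ladder)
        rec_noise = NoiseSpec(noise.pixel_sigma, noise.illum_gain_sigma,
                              seed=int(np.random.default_rng(
                                  [noise.seed, idx]).integers(2 ** 31)))
        seq, truth = simulate_sequence(layout, kinetics, c, acq, rec_noise,
                                       level=level)
        record_id = f"rec{idx:04d}_L{level}_r{rep}"
        image_dir = record_id
        if out_dir is not None:
            _write_sequence(Path(out_dir) / record_id, seq,
                            image_writer=image_writer)
        rec = ManifestRecord(
            record_id=record_id,
            image_dir=image_dir,
            timestamps_s=list(seq.timestamps_s),
            concentration=float(c),
            level=level,
            class_label=truth.class_label,
            split="train",
            units=ladder.units,
        )
        rec.sequence = seq  # in-memory convenience; not serialized
        records.append(rec)
    return Manifest(records)


def _write_sequence(directory: Path, seq: FrameSequence,
                    image_writer=None) -> None:
    import imageio.v3 as iio

    write = image_writer or (lambda path, frame: iio.imwrite(path, frame))
    directory.mkdir(parents=True, exist_ok=True)
    for frame, t in zip(seq.frames, seq.timestamps_s):
        write(str(directory / f"t{t:g}.png"), frame)
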