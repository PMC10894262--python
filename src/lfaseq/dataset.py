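"""Frame grids, windows, dilution ladders, color-chart mapping, manifests, splits.

A lateral-flow run is recorded as an ordered stack of time-stamped frames
(:class:`FrameSequence`).  Ground truth for synthetic panels is expressed on
the manufacturer color-chart scale: integer levels 0-8, grouped into the five
reporting classes high / middle / mid-low / low / negative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClassLabel",
    "DilutionLadder",
    "FrameSequence",
    "ManifestRecord",
    "Manifest",
    "frame_grid",
    "select_window",
    "serial_dilution",
    "level_to_class",
    "concentration_to_level",
    "count_frames",
    "split_train_val",
]


class ClassLabel(enum.Enum):
    """Five-way reporting class derived from color-chart levels.

    Ordered HIGH > MIDDLE > MID_LOW > LOW > NEGATIVE; the enum value is the
    rank used for ordering and serialization.
    """

    HIGH = 4
    MIDDLE = 3
    MID_LOW = 2
    LOW = 1
    NEGATIVE = 0

    def __lt__(self, other: "ClassLabel") -> bool:
        if not isinstance(other, ClassLabel):
            return NotImplemented
        return self.value < other.value


@dataclass(frozen=True)
class FrameSequence:
    """Ordered, time-stamped stack of 8-bit RGB strip images for one run.

    frames: uint8 array of shape (T, H, W, 3); timestamps_s: strictly
    increasing, one per frame.
    """

    frames: np.ndarray
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        ts = np.asarray(self.timestamps_s, dtype=float)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8)")
        if ts.ndim != 1 or len(ts) != len(frames):
            raise ValueError("one timestamp per frame required")
        if len(ts) and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps_s", ts)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class DilutionLadder:
    """Geometric concentration ladder (serial dilution)."""

    concentrations: tuple
    units: str = "ng/mL"

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.concentrations)
        if not c:
            raise ValueError("ladder must contain at least one point")
        if any(x <= 0 for x in c):
            raise ValueError("ladder concentrations must be positive")
        if any(a < b for a, b in zip(c, c[1:])):
            raise ValueError("ladder concentrations must be non-increasing")
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class ManifestRecord:
    record_id: str
    image_dir: str
    timestamps_s: list
    concentration: float
    level: int
    class_label: ClassLabel
    split: str = "none"
    units: str = "ng/mL"

    def __post_init__(self) -> None:
        ts = [float(t) for t in self.timestamps_s]
        if any(a >= b for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"record {self.record_id!r}: timestamps must be strictly increasing"
            )
        if not 0 <= int(self.level) <= 8:
            raise ValueError(f"record {self.record_id!r}: level outside 0-8")
        if self.split not in ("train", "val", "test", "none"):
            raise ValueError(f"record {self.record_id!r}: bad split {self.split!r}")
        self.timestamps_s = ts
        self.level = int(self.level)
        if isinstance(self.class_label, str):
            self.class_label = ClassLabel[self.class_label]


@dataclass
class Manifest:
    """Tabular index of assay records (paths, timestamps, labels, split)."""

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate record_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.records if r.split == split])


def frame_grid(duration_s: float, interval_s: float) -> list:
    """Acquisition timestamps on the half-open grid (0, duration].

    Frames are taken every ``interval_s`` seconds starting at ``interval_s``
    (the t=0 loading frame is not recorded); a 2-min assay at 10-s intervals
    yields 12 frames, a 1-min assay 6.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if duration_s < interval_s:
        raise ValueError("empty grid: duration shorter than one interval")
    n = math.floor(duration_s / interval_s + 1e-9)
    return [i * interval_s for i in range(1, n + 1)]


def select_window(seq: FrameSequence, start_s: float, end_s: float) -> FrameSequence:
    """Keep frames with timestamp in the half-open window (start_s, end_s]."""
    if start_s >= end_s:
        raise ValueError("window start must precede end")
    keep = (seq.timestamps_s > start_s) & (seq.timestamps_s <= end_s)
    if not keep.any():
        raise ValueError("window contains no frames")
    return FrameSequence(seq.frames[keep], seq.timestamps_s[keep])


def serial_dilution(start_conc: float, fold: float, n_points: int,
                    units: str = "ng/mL") -> DilutionLadder:
    """Ladder c_i = start_conc / fold**(i-1) for i = 1..n_points."""
    if start_conc <= 0 or fold < 1 or n_points < 1:
        raise ValueError("require start_conc > 0, fold >= 1, n_points >= 1")
    return DilutionLadder(
        tuple(start_conc / fold ** i for i in range(n_points)), units=units
    )


_LEVEL_TO_CLASS = {
    8: ClassLabel.HIGH, 7: ClassLabel.HIGH,
    6: ClassLabel.MIDDLE, 5: ClassLabel.MIDDLE,
    4: ClassLabel.MID_LOW, 3: ClassLabel.MID_LOW,
    2: ClassLabel.LOW, 1: ClassLabel.LOW,
    0: ClassLabel.NEGATIVE,
}


def level_to_class(level: int) -> ClassLabel:
    """Map a color-chart level 0-8 onto the five reporting classes.

    Levels 8-7 are HIGH, 6-5 MIDDLE, 4-3 MID_LOW, 2-1 LOW and 0 NEGATIVE.
    """
    if level != int(level) or not 0 <= int(level) <= 8:
        raise ValueError(f"level must be an integer in 0-8, got {level!r}")
    return _LEVEL_TO_CLASS[int(level)]


def concentration_to_level(c: float, ladder: DilutionLadder,
                           rtol: float = 1e-6) -> int:
    """Assign a color-chart level from a ladder point.

    A blank (c == 0) is level 0; the highest ladder point maps to level 8 and
    each subsequent dilution to the next level down.  Off-ladder
    concentrations are rejected, not interpolated.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return 0
    for i, point in enumerate(ladder.concentrations):
        if math.isclose(c, point, rel_tol=rtol):
            return 8 - i
    raise ValueError(f"off-ladder concentration {c!r}")


def count_frames(manifest: Manifest) -> int:
    """Total frame count across all records."""
    return sum(len(r.timestamps_s) for r in manifest.records)


def split_train_val(manifest: Manifest, frac: float = 0.10,
                    seed: int = 0) -> Manifest:
    """Re-label a seeded random fraction of the train records as validation.

    floor(frac * n_train) records move to the 'val' split; all other records
    (including any test split) are untouched.  Returns a new manifest.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    train_idx = [i for i, r in enumerate(manifest.records) if r.split == "train"]
    if len(train_idx) < 2:
        raise ValueError("need at least 2 train records to split")
    n_val = math.floor(frac * len(train_idx))
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(train_idx, size=n_val, replace=False).tolist())
    records = []
    for i, r in enumerate(manifest.records):
        new = replace(r, split="val") if i in val_idx else replace(r)
        if hasattr(r, "sequence"):  # in-memory panels carry their frames
            new.sequence = r.sequence
        records.append(new)
    return Manifest(records)
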