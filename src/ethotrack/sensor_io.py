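"""Data model and I/O for inertial recordings and behaviour label tracks.

The measurement unit is a harness-mounted logger on the dog's back carrying a
tri-axial accelerometer (units of g) and a tri-axial gyroscope (degrees per
second), sampled uniformly at 100 Hz in a body-fixed frame: x points toward
the head, y toward the right side, z into the body.  In a static posture the
accelerometer reads only the gravity vector expressed in that frame, so
postures differ by device attitude alone; gaits add periodic dynamic
acceleration and angular velocity on top.

Behaviour annotations are SubRip (SRT) subtitle tracks: each cue maps a time
interval to one of seven non-overlapping categories (lay, sit, stand, walk,
trot, canter, gallop).  Intervals are half-open ``[start, end)`` in seconds
on the recording clock; recordings and tracks are assumed pre-aligned.

Misclassifications are later graded by an ad-hoc *activity level* A per
category (static postures 0, walk 1, trot 2, canter/gallop 3); the mapping
lives here next to the category enum.
"""

from __future__ import annotations

import enum
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorCategory",
    "CATEGORIES",
    "ACTIVITY_LEVELS",
    "activity_level",
    "InertialRecording",
    "LabelInterval",
    "LabelTrack",
    "ParseError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "apply_margin",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


class BehaviorCategory(enum.Enum):
    """The seven mutually exclusive behaviour categories of the ethogram."""

    LAY = "lay"
    SIT = "sit"
    STAND = "stand"
    WALK = "walk"
    TROT = "trot"
    CANTER = "canter"
    GALLOP = "gallop"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_text(cls, text: str) -> "BehaviorCategory":
        """Resolve a canonical category name (case-insensitive, trimmed)."""
        key = text.strip().lower()
        for member in cls:
            if member.value == key:
                return member
        raise ValidationError(f"unknown behaviour category text: {text!r}")


#: Canonical category order used by feature datasets and 7x7 matrices.
CATEGORIES: tuple[BehaviorCategory, ...] = tuple(BehaviorCategory)

#: Ad-hoc activity level A of each category (0 static ... 3 fastest gaits).
ACTIVITY_LEVELS: dict[BehaviorCategory, int] = {
    BehaviorCategory.LAY: 0,
    BehaviorCategory.SIT: 0,
    BehaviorCategory.STAND: 0,
    BehaviorCategory.WALK: 1,
    BehaviorCategory.TROT: 2,
    BehaviorCategory.CANTER: 3,
    BehaviorCategory.GALLOP: 3,
}


def activity_level(category: BehaviorCategory) -> int:
    """Activity level A of a category; ``abs(A_out - A_in)`` grades errors."""
    return ACTIVITY_LEVELS[category]


# --------------------------------------------------------------------------
# Inertial recordings
# --------------------------------------------------------------------------

#: Channel attribute names in file-column order (after the time column).
CHANNELS: tuple[str, ...] = ("a_x", "a_y", "a_z", "w_roll", "w_pitch", "w_yaw")

_COLUMN_ALIASES = {
    "t": "t",
    "ax": "a_x", "a_x": "a_x",
    "ay": "a_y", "a_y": "a_y",
    "az": "a_z", "a_z": "a_z",
    "wr": "w_roll", "w_roll": "w_roll", "wroll": "w_roll",
    "wp": "w_pitch", "w_pitch": "w_pitch", "wpitch": "w_pitch",
    "wy": "w_yaw", "w_yaw": "w_yaw", "wyaw": "w_yaw",
}

_TIME_TOL = 1e-9  # uniform-sampling tolerance in seconds


@dataclass(frozen=True)
class InertialRecording:
    """A uniformly sampled 6-channel inertial stream with metadata.

    Acceleration channels are in g along the body-fixed axes; angular
    velocity channels are in deg/s about those axes (roll about x, pitch
    about y, yaw about z).
    """

    t: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    a_z: np.ndarray
    w_roll: np.ndarray
    w_pitch: np.ndarray
    w_yaw: np.ndarray
    sample_rate: float = 100.0
    dog_id: str = ""
    breed: str = ""
    session_index: int = 0

    def __post_init__(self) -> None:
        for name in ("t",) + CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise ValidationError(f"channel {name} must be 1-D")
        n = len(self.t)
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"channel {name} length {len(getattr(self, name))} != time length {n}"
                )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > _TIME_TOL):
                k = int(np.argmax(np.abs(dt - 1.0 / self.sample_rate)))
                raise ValidationError(
                    f"non-uniform sampling at sample {k + 1}: dt={dt[k]:.6g} s "
                    f"(expected {1.0 / self.sample_rate:.6g} s)"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (0 for empty streams)."""
        return len(self) / self.sample_rate

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) acceleration matrix in g."""
        return np.column_stack([self.a_x, self.a_y, self.a_z])

    @property
    def gyro(self) -> np.ndarray:
        """(n, 3) angular-velocity matrix in deg/s."""
        return np.column_stack([self.w_roll, self.w_pitch, self.w_yaw])


def read_recording(
    path: str | Path,
    sample_rate: float = 100.0,
    *,
    dog_id: str = "",
    breed: str = "",
    session_index: int = 0,
) -> InertialRecording:
    """Read a raw sensor CSV (columns t, ax, ay, az, wr, wp, wy).

    Lines starting with ``#`` are comments; a header row is optional.  The
    time column must be a strictly increasing uniform grid at *sample_rate*.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", header=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(np.empty((0, 7)))
    if df.shape[1] != 7:
        raise ParseError(f"{path}: expected 7 columns, found {df.shape[1]}")
    # optional header row: first row not fully numeric
    first = df.iloc[0] if len(df) else None
    if first is not None and pd.to_numeric(first, errors="coerce").isna().any():
        names = [str(v).strip().lower() for v in first]
        if not all(n in _COLUMN_ALIASES for n in names):
            raise ParseError(f"{path}: unrecognized header {names}")
        # map aliases to canonical order t, a_x.., w_yaw
        canon = [_COLUMN_ALIASES[n] for n in names]
        want = ["t", "a_x", "a_y", "a_z", "w_roll", "w_pitch", "w_yaw"]
        if sorted(canon) != sorted(want):
            raise ParseError(f"{path}: header must name all of {want}, got {canon}")
        df = df.iloc[1:].reset_index(drop=True)
        df = df[[canon.index(w) for w in want]]
        df.columns = range(7)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: malformed numeric row (data row {row + 1})")
    arr = numeric.to_numpy(dtype=float)
    return InertialRecording(
        t=arr[:, 0], a_x=arr[:, 1], a_y=arr[:, 2], a_z=arr[:, 3],
        w_roll=arr[:, 4], w_pitch=arr[:, 5], w_yaw=arr[:, 6],
        sample_rate=sample_rate,
        dog_id=dog_id, breed=breed, session_index=session_index,
    )


def write_recording(rec: InertialRecording, path: str | Path) -> None:
    """Write the sensor CSV read back by :func:`read_recording`.

    Values are printed with 12 significant digits so a round-trip preserves
    them to well below 1e-9.
    """
    path = Path(path)
    data = np.column_stack([rec.t] + [getattr(rec, c) for c in CHANNELS])
    with open(path, "w") as fh:
        fh.write("# t [s], ax/ay/az [g], wr/wp/wy [deg/s]\n")
        fh.write("t,ax,ay,az,wr,wp,wy\n")
        np.savetxt(fh, data, fmt="%.12g", delimiter=",")


# --------------------------------------------------------------------------
# Label tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class LabelInterval:
    """A half-open labelled time interval ``[start, end)`` in seconds."""

    start: float
    end: float
    category: BehaviorCategory = field(compare=False)

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"interval end {self.end} must exceed start {self.start}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class LabelTrack:
    """An ordered, non-overlapping set of labelled intervals from one coder.

    Gaps between intervals are allowed and meaningful: only unambiguous
    behaviour is annotated, so tracks are interrupted by design.
    """

    intervals: tuple[LabelInterval, ...]
    coder_id: str = ""

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start))
        object.__setattr__(self, "intervals", ivs)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end - 1e-12:
                raise ValidationError(
                    f"overlapping intervals: [{prev.start}, {prev.end}) and "
                    f"[{cur.start}, {cur.end})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_duration(self) -> float:
        return sum(iv.duration for iv in self.intervals)

    @property
    def end(self) -> float:
        return self.intervals[-1].end if self.intervals else 0.0

    def category_at(self, time: float) -> BehaviorCategory | None:
        """Category covering *time*, or None in a gap (half-open semantics)."""
        starts = [iv.start for iv in self.intervals]
        k = bisect_right(starts, time) - 1
        if k >= 0 and time < self.intervals[k].end:
            return self.intervals[k].category
        return None


_SRT_TIME = re.compile(
    r"(\d+):(\d\d):(\d\d)[,.](\d{1,3})\s*-->\s*(\d+):(\d\d):(\d\d)[,.](\d{1,3})"
)


def _srt_seconds(h: str, m: str, s: str, ms: str) -> float:
    return int(h) * 3600 + int(m) * 60 + int(s) + int(ms.ljust(3, "0")) / 1000.0


def read_labels(
    path: str | Path,
    category_map: Mapping[str, BehaviorCategory] | None = None,
    *,
    coder_id: str = "",
) -> LabelTrack:
    """Read a SubRip (SRT) subtitle file into a :class:`LabelTrack`.

    Each cue's text, trimmed and lower-cased, must resolve through
    *category_map* (default: the seven canonical category names).  Unknown
    texts are an error, never silently skipped; overlapping cues are
    rejected.
    """
    path = Path(path)
    if category_map is None:
        lookup = {c.value: c for c in BehaviorCategory}
    else:
        lookup = {k.strip().lower(): v for k, v in category_map.items()}
    text = Path(path).read_text()
    intervals: list[LabelInterval] = []
    for block in re.split(r"\n\s*\n", text.strip()):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        if not lines:
            continue
        # optional numeric cue index on the first line
        if lines[0].isdigit():
            lines = lines[1:]
        if not lines:
            raise ParseError(f"{path}: cue with no time line")
        m = _SRT_TIME.match(lines[0])
        if m is None:
            raise ParseError(f"{path}: malformed time line {lines[0]!r}")
        start = _srt_seconds(*m.groups()[:4])
        end = _srt_seconds(*m.groups()[4:])
        label = " ".join(lines[1:]).strip().lower()
        if label not in lookup:
            raise ValidationError(
                f"{path}: cue text {label!r} not in category map "
                f"(known: {sorted(lookup)})"
            )
        intervals.append(LabelInterval(start, end, lookup[label]))
    return LabelTrack(tuple(intervals), coder_id=coder_id)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write a :class:`LabelTrack` as a SubRip (SRT) file (ms precision)."""

    def fmt(seconds: float) -> str:
        ms = int(round(seconds * 1000))
        h, rem = divmod(ms, 3600_000)
        m, rem = divmod(rem, 60_000)
        s, ms = divmod(rem, 1000)
        return f"{h:02d}:{m:02d}:{s:02d},{ms:03d}"

    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals, start=1):
            fh.write(f"{i}\n{fmt(iv.start)} --> {fmt(iv.end)}\n{iv.category.value}\n\n")


def apply_margin(track: LabelTrack, margin: float = 1.0) -> LabelTrack:
    """Trim *margin* seconds from both ends of every interval.

    Near interval boundaries the video-derived labels are least reliable
    (reaction delays, ambiguous transitions), so a safety margin on both
    sides of every annotation is simply dropped before any window is cut.
    Intervals no longer than ``2 * margin`` disappear entirely.  The
    operation is *not* idempotent: applying it twice trims twice.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    kept = [
        LabelInterval(iv.start + margin, iv.end - margin, iv.category)
        for iv in track.intervals
        if iv.duration > 2 * margin
    ]
    return LabelTrack(tuple(kept), coder_id=track.coder_id)
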