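"""Core data types and CSV I/O for smart-cushion sensor streams.

The cushion delivers, at a fixed sampling rate (10 Hz by default), six
non-negative force readings from force-sensing resistors (FSRs) embedded in
the seat plus two angular-velocity channels from a gyroscope mounted under
the seat centre: ``gyro_x`` tracks anterior-posterior body swing and
``gyro_y`` medial-lateral swing.  Streams are exchanged as plain CSV with
columns ``t,fsr1..fsr6,gyro_x,gyro_y`` and optional ``activity``/``subject``
columns carrying per-sample ground-truth labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Activity",
    "ActivityLevel",
    "MET_RANGES",
    "LEVEL_OF_ACTIVITY",
    "level_of",
    "CushionGeometry",
    "DEFAULT_GEOMETRY",
    "RawStream",
    "FormatError",
    "ValidationError",
    "read_raw_stream",
    "write_raw_stream",
    "FEATURE_COLUMNS",
    "STD_COLUMNS",
    "APEN_COLUMNS",
    "read_feature_table",
    "write_feature_table",
]

TIME_TOLERANCE = 1e-6  # seconds; allowed jitter on the uniform sample clock


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


class ValidationError(ValueError):
    """Data violates a stream invariant (negative force, bad clock, ...)."""


class Activity(str, enum.Enum):
    """The five sitting activities the cushion is trained to recognise."""

    READING = "reading"
    DESK_WORKING = "desk_working"
    CONVERSATION = "conversation"
    SWING = "swing"
    EXERCISE = "exercise"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ActivityLevel(str, enum.Enum):
    """Intensity classes anchored to MET (metabolic equivalent) ranges."""

    LIGHT = "light"
    MODERATE = "moderate"
    VIGOROUS = "vigorous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Informational MET ranges per level; 1 MET is quiet sitting.  These anchor
#: the level definitions but play no computational role.
MET_RANGES: dict[ActivityLevel, tuple[float, float]] = {
    ActivityLevel.LIGHT: (1.0, 3.0),
    ActivityLevel.MODERATE: (3.0, 6.0),
    ActivityLevel.VIGOROUS: (6.0, 9.0),
}

#: Activity -> intensity level.  Reading, desk work and conversation are
#: ordinary seated tasks (light); left-right / front-back swinging is the
#: pressure-relief movement recommended to wheelchair users (moderate);
#: exercise such as lifting a weight is vigorous.
LEVEL_OF_ACTIVITY: dict[Activity, ActivityLevel] = {
    Activity.READING: ActivityLevel.LIGHT,
    Activity.DESK_WORKING: ActivityLevel.LIGHT,
    Activity.CONVERSATION: ActivityLevel.LIGHT,
    Activity.SWING: ActivityLevel.MODERATE,
    Activity.EXERCISE: ActivityLevel.VIGOROUS,
}


def level_of(activity: Activity | str) -> ActivityLevel:
    """Map an activity to its intensity level.

    Raises ``KeyError`` for an unknown activity id.
    """
    return LEVEL_OF_ACTIVITY[Activity(activity)]


@dataclass(frozen=True)
class CushionGeometry:
    """Positions of the six FSRs on the seat, as relative grid distances.

    The seat is conceptually a 5x5 grid with the origin at its centre; each
    sensor coordinate is the (x, y) offset of that sensor from the origin.
    The default layout is symmetric front/back and left/right, so its
    centroid sits at the origin.
    """

    coords: tuple[tuple[float, float], ...] = (
        (-1.0, 2.0),   # Fsr1 front-left
        (1.0, 2.0),    # Fsr2 front-right
        (-2.0, 0.0),   # Fsr3 mid-left
        (2.0, 0.0),    # Fsr4 mid-right
        (-1.0, -2.0),  # Fsr5 rear-left
        (1.0, -2.0),   # Fsr6 rear-right
    )

    def __post_init__(self) -> None:
        if len(self.coords) != 6:
            raise ValidationError(
                f"geometry must have 6 sensor coordinates, got {len(self.coords)}"
            )

    @property
    def x(self) -> np.ndarray:
        return np.array([c[0] for c in self.coords], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([c[1] for c in self.coords], dtype=float)


DEFAULT_GEOMETRY = CushionGeometry()


@dataclass
class RawStream:
    """A validated multichannel cushion recording.

    Attributes
    ----------
    t : array of sample times in seconds, strictly increasing with uniform
        step ``1/fs`` (tolerance ``1e-6`` s).
    fsr : (n, 6) array of non-negative force readings, sensor order
        Fsr1..Fsr6.  Units are arbitrary (relative FSR readings); the
        centre-of-pressure is invariant to the unit.
    gyro_x, gyro_y : angular velocities in deg/s.
    label : optional per-sample activity id (one per sample when present).
    subject : optional subject identifier for the whole stream.
    fs : sampling frequency in Hz.
    """

    t: np.ndarray
    fsr: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    fs: float = 10.0
    label: Optional[np.ndarray] = None
    subject: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fsr = np.asarray(self.fsr, dtype=float)
        self.gyro_x = np.asarray(self.gyro_x, dtype=float)
        self.gyro_y = np.asarray(self.gyro_y, dtype=float)
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = len(self.t)
        if self.fsr.shape != (n, 6):
            raise ValidationError(
                f"fsr must be (n, 6); got {self.fsr.shape} for n={n}"
            )
        if self.gyro_x.shape != (n,) or self.gyro_y.shape != (n,):
            raise ValidationError("gyro channels must be 1-D, one per sample")
        if n:
            if not np.all(np.isfinite(self.fsr)):
                raise ValidationError("non-finite force reading")
            if self.fsr.min() < 0:
                raise ValidationError("negative force reading")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if np.max(np.abs(steps - 1.0 / self.fs)) > TIME_TOLERANCE:
                raise ValidationError(
                    f"timestamps not uniform at 1/fs={1.0 / self.fs:g} s "
                    f"(tolerance {TIME_TOLERANCE:g} s)"
                )
        if self.label is not None and len(self.label) != n:
            raise ValidationError("label must have one entry per sample")

    def slice(self, start: int, stop: int) -> "RawStream":
        """Sub-stream over sample index range [start, stop)."""
        return RawStream(
            t=self.t[start:stop],
            fsr=self.fsr[start:stop],
            gyro_x=self.gyro_x[start:stop],
            gyro_y=self.gyro_y[start:stop],
            fs=self.fs,
            label=None if self.label is None else self.label[start:stop],
            subject=self.subject,
        )


RAW_REQUIRED = ["fsr1", "fsr2", "fsr3", "fsr4", "fsr5", "fsr6", "gyro_x", "gyro_y"]


def read_raw_stream(path: str | Path, fs: float = 10.0) -> RawStream:
    """Read a raw-stream CSV and return a validated :class:`RawStream`.

    The ``t`` column is optional; when absent, timestamps are synthesized
    from ``fs`` (the device streams at a fixed rate with no explicit clock).
    ``activity`` and ``subject`` columns are optional.
    """
    df = pd.read_csv(path)
    missing = [c for c in RAW_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    n = len(df)
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
    else:
        t = np.arange(n, dtype=float) / fs
    label = None
    if "activity" in df.columns:
        label = df["activity"].to_numpy(dtype=object)
    subject = None
    if "subject" in df.columns and n:
        subjects = df["subject"].astype(str).unique()
        if len(subjects) > 1:
            raise FormatError(f"{path}: multiple subject ids in one stream")
        subject = subjects[0]
    fsr = df[RAW_REQUIRED[:6]].to_numpy(dtype=float)
    return RawStream(
        t=t,
        fsr=fsr,
        gyro_x=df["gyro_x"].to_numpy(dtype=float),
        gyro_y=df["gyro_y"].to_numpy(dtype=float),
        fs=fs,
        label=label,
        subject=subject,
    )


def write_raw_stream(stream: RawStream, path: str | Path) -> None:
    """Write a stream as CSV; ``read_raw_stream`` round-trips it to 1e-9."""
    data: dict[str, object] = {"t": stream.t}
    for i in range(6):
        data[f"fsr{i + 1}"] = stream.fsr[:, i] if len(stream) else np.empty(0)
    data["gyro_x"] = stream.gyro_x
    data["gyro_y"] = stream.gyro_y
    if stream.label is not None:
        data["activity"] = stream.label
    if stream.subject is not None:
        data["subject"] = np.full(len(stream), stream.subject, dtype=object)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Feature-table CSV (one row per analysis window)
# ---------------------------------------------------------------------------

STD_COLUMNS = ["std_cx", "std_cy", "std_gx", "std_gy"]
APEN_COLUMNS = ["apen_cx", "apen_cy", "apen_gx", "apen_gy"]
FEATURE_COLUMNS = STD_COLUMNS + APEN_COLUMNS
META_COLUMNS = ["activity", "level", "subject", "window_start_s"]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    feature_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    if not feature_cols:
        raise FormatError(f"{path}: no feature columns found")
    return df


def apply_moving_average(stream: RawStream, width: int) -> RawStream:
    """Optional pre-filter: centred moving-average smoothing of all channels.

    Off by default throughout the pipeline; the acquisition front end's
    smoothing step is not specified, so none is assumed.  ``width`` is in
    samples and must be >= 1 (1 is the identity).
    """
    if width < 1:
        raise ValidationError("moving-average width must be >= 1")
    if width == 1 or len(stream) == 0:
        return stream
    kernel = np.ones(width) / width

    def smooth(x: np.ndarray) -> np.ndarray:
        pad = width // 2
        xp = np.pad(x, pad_width=((pad, width - 1 - pad)), mode="edge")
        return np.convolve(xp, kernel, mode="valid")

    fsr = np.column_stack([smooth(stream.fsr[:, i]) for i in range(6)])
    return RawStream(
        t=stream.t,
        fsr=np.maximum(fsr, 0.0),
        gyro_x=smooth(stream.gyro_x),
        gyro_y=smooth(stream.gyro_y),
        fs=stream.fs,
        label=stream.label,
        subject=stream.subject,
    )
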