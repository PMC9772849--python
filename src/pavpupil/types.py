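"""Core data containers shared across the pipeline.

Each container is a light dataclass over numpy arrays with an explicit
``validate`` method; constructors validate by default so that malformed
sessions fail loudly at the boundary rather than deep inside an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: Experimental groups: whether reward delivery is yoked to CS offset.
GROUPS = ("contingent", "non-contingent")

#: Dose labels for the haloperidol dose-response arm (mg/kg), plus vehicle.
DOSES = ("saline", "0.1", "0.2", "0.5")

#: The eight annotated pupil-edge positions, counter-clockwise from "right".
POINT_NAMES = (
    "right",
    "top_right",
    "top",
    "top_left",
    "left",
    "bottom_left",
    "bottom",
    "bottom_right",
)

#: Angle (radians) of each named landmark on the pupil ellipse.
POINT_ANGLES = np.deg2rad(np.arange(0.0, 360.0, 45.0))


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class EventSchedule:
    """CS/US event times and condition labels for one session.

    Times are in seconds from session start. ``us_times`` holds reward
    (sucrose) deliveries; in the contingent group each reward follows a CS
    by exactly ``cs_duration`` seconds, while in the non-contingent group
    the two streams are generated independently.
    """

    cs_onsets: np.ndarray
    us_times: np.ndarray
    group: str
    dose: str = "saline"
    cs_duration: float = 1.0
    session_length: float = 0.0

    def __post_init__(self):
        self.cs_onsets = _as_1d(self.cs_onsets, "cs_onsets")
        self.us_times = _as_1d(self.us_times, "us_times")
        if self.session_length <= 0.0 and (len(self.cs_onsets) or len(self.us_times)):
            last = max(
                self.cs_onsets[-1] + self.cs_duration if len(self.cs_onsets) else 0.0,
                self.us_times[-1] if len(self.us_times) else 0.0,
            )
            self.session_length = float(last)
        self.validate()

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; allowed values are {GROUPS}"
            )
        if self.dose not in DOSES:
            raise ValueError(f"unknown dose {self.dose!r}; allowed values are {DOSES}")
        if self.cs_duration <= 0:
            raise ValueError("cs_duration must be positive")
        for name, arr in (("cs_onsets", self.cs_onsets), ("us_times", self.us_times)):
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
            if len(arr) and (arr[0] < 0 or arr[-1] > self.session_length):
                raise ValueError(f"{name} must lie within [0, session_length]")

    @property
    def cs_intervals(self) -> np.ndarray:
        """Inter-CS intervals (the experiment's ITIs), seconds."""
        return np.diff(self.cs_onsets)

    @property
    def us_intervals(self) -> np.ndarray:
        return np.diff(self.us_times)


@dataclass
class LickTrain:
    """Strictly ascending lick contact times (seconds) for one session."""

    lick_times: np.ndarray
    session_length: Optional[float] = None

    def __post_init__(self):
        self.lick_times = _as_1d(self.lick_times, "lick_times")
        self.validate()

    def validate(self) -> None:
        t = self.lick_times
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("lick_times must be strictly ascending")
        if len(t) and t[0] < 0:
            raise ValueError("lick_times must be non-negative")
        if self.session_length is not None and len(t) and t[-1] > self.session_length:
            raise ValueError("lick_times exceed session_length")

    def __len__(self) -> int:
        return len(self.lick_times)


@dataclass
class LandmarkSeries:
    """Per-frame tracked pupil-edge landmarks.

    ``xy`` has shape (n_frames, 8, 2) and ``likelihood`` (n_frames, 8),
    mirroring the per-point confidence a pose tracker reports.
    """

    time_s: np.ndarray
    xy: np.ndarray
    likelihood: np.ndarray
    point_names: Tuple[str, ...] = POINT_NAMES

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.time_s)
        if n == 0:
            raise ValueError("empty landmark series")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.xy.shape != (n, 8, 2):
            raise ValueError(f"xy must have shape ({n}, 8, 2), got {self.xy.shape}")
        if self.likelihood.shape != (n, 8):
            raise ValueError("likelihood must have shape (n_frames, 8)")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class EllipseParams:
    """Ellipse fitted to the pupil edge: center, semi-axes (a >= b), tilt."""

    center: Tuple[float, float]
    a: float
    b: float
    theta: float

    def validate(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        if not (0.0 <= self.theta < np.pi):
            raise ValueError("theta must lie in [0, pi)")

    @property
    def major_diameter(self) -> float:
        return 2.0 * self.a

    @property
    def minor_diameter(self) -> float:
        return 2.0 * self.b


@dataclass
class PupilTrace:
    """Per-frame pupil area (px^2) with validity mask and optional z-score.

    ``area_z`` is the per-session standardization of ``area`` over valid
    frames (mean 0, sample sd 1); NaN where invalid or not yet computed.
    """

    time_s: np.ndarray
    area: np.ndarray
    valid: np.ndarray
    area_z: Optional[np.ndarray] = None
    interpolated: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.area = _as_1d(self.area, "area")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.area_z is not None:
            self.area_z = _as_1d(self.area_z, "area_z")
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.time_s), dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.time_s)
        if self.area.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("area/valid must match time_s length")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    def with_z(self, area_z: np.ndarray) -> "PupilTrace":
        return replace(self, area_z=np.asarray(area_z, dtype=float))


@dataclass
class SessionData:
    """One processed session: schedule, licks and (optionally) pupil trace."""

    subject: str
    session: int
    schedule: EventSchedule
    licks: LickTrain
    pupil: Optional[PupilTrace] = None

    @property
    def group(self) -> str:
        return self.schedule.group

    @property
    def dose(self) -> str:
        return self.schedule.dose
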