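"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text: schedule JSON, one-column lick CSV, wide
landmark CSV (``time_s`` plus ``<point>_x, <point>_y, <point>_likelihood``
per landmark), pupil-trace CSV and the tidy window-summary CSV. The
landmark reader also accepts the 3-row-header table exported by common
pose trackers (scorer / bodyparts / coords header rows).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import POINT_NAMES, EventSchedule, LandmarkSeries, LickTrain, PupilTrace

PathLike = Union[str, Path]


# ---------------------------------------------------------------- schedules

def write_schedule(schedule: EventSchedule, path: PathLike) -> None:
    payload = {
        "group": schedule.group,
        "dose": schedule.dose,
        "cs_duration_s": schedule.cs_duration,
        "cs_onsets_s": [round(float(t), 6) for t in schedule.cs_onsets],
        "us_times_s": [round(float(t), 6) for t in schedule.us_times],
        "session_length_s": round(float(schedule.session_length), 6),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_schedule(path: PathLike) -> EventSchedule:
    payload = json.loads(Path(path).read_text())
    return EventSchedule(
        cs_onsets=np.asarray(payload["cs_onsets_s"], dtype=float),
        us_times=np.asarray(payload["us_times_s"], dtype=float),
        group=payload["group"],
        dose=payload.get("dose", "saline"),
        cs_duration=float(payload.get("cs_duration_s", 1.0)),
        session_length=float(payload["session_length_s"]),
    )


# -------------------------------------------------------------------- licks

def write_licks(licks: LickTrain, path: PathLike) -> None:
    df = pd.DataFrame({"lick_time_s": np.round(licks.lick_times, 6)})
    df.to_csv(path, index=False)


def read_licks(path: PathLike, session_length: float | None = None) -> LickTrain:
    df = pd.read_csv(path)
    return LickTrain(df["lick_time_s"].to_numpy(float), session_length=session_length)


# ---------------------------------------------------------------- landmarks

def write_landmarks(series: LandmarkSeries, path: PathLike) -> None:
    cols = {"time_s": np.round(series.time_s, 6)}
    for j, name in enumerate(series.point_names):
        cols[f"{name}_x"] = np.round(series.xy[:, j, 0], 4)
        cols[f"{name}_y"] = np.round(series.xy[:, j, 1], 4)
        cols[f"{name}_likelihood"] = np.round(series.likelihood[:, j], 4)
    pd.DataFrame(cols).to_csv(path, index=False)


def _read_landmarks_flat(df: pd.DataFrame) -> LandmarkSeries:
    names = [c[:-2] for c in df.columns if c.endswith("_x")]
    if not names:
        raise ValueError("no landmark '_x' columns found")
    n = len(df)
    xy = np.empty((n, len(names), 2))
    lik = np.ones((n, len(names)))
    for j, name in enumerate(names):
        xy[:, j, 0] = df[f"{name}_x"]
        xy[:, j, 1] = df[f"{name}_y"]
        lcol = f"{name}_likelihood"
        if lcol in df.columns:
            lik[:, j] = df[lcol]
    return LandmarkSeries(
        time_s=df["time_s"].to_numpy(float),
        xy=xy,
        likelihood=lik,
        point_names=tuple(names),
    )


def _read_landmarks_posetracker(
    path: PathLike, frame_rate: float
) -> LandmarkSeries:
    """Read the 3-row-header pose-tracker export (scorer/bodyparts/coords)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    n = len(df)
    xy = np.empty((n, len(bodyparts), 2))
    lik = np.ones((n, len(bodyparts)))
    scorer = df.columns.get_level_values(0)[0]
    for j, bp in enumerate(bodyparts):
        xy[:, j, 0] = df[(scorer, bp, "x")]
        xy[:, j, 1] = df[(scorer, bp, "y")]
        if (scorer, bp, "likelihood") in df.columns:
            lik[:, j] = df[(scorer, bp, "likelihood")]
    time_s = np.arange(n) / frame_rate
    return LandmarkSeries(time_s, xy, lik, point_names=tuple(bodyparts))


def read_landmarks(path: PathLike, frame_rate: float = 30.0) -> LandmarkSeries:
    """Read a landmark table; dialect is sniffed from the header.

    The native dialect carries an explicit ``time_s`` column; the
    pose-tracker dialect indexes by frame and needs ``frame_rate`` to
    reconstruct timestamps.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip() in ("time_s", '"time_s"'):
        return _read_landmarks_flat(pd.read_csv(path))
    return _read_landmarks_posetracker(path, frame_rate)


# ------------------------------------------------------------- pupil traces

def write_trace(trace: PupilTrace, path: PathLike) -> None:
    z = trace.area_z if trace.area_z is not None else np.full(len(trace), np.nan)
    pd.DataFrame(
        {
            "time_s": np.round(trace.time_s, 6),
            "area_px2": np.round(trace.area, 6),
            "area_z": np.round(z, 8),
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_trace(path: PathLike) -> PupilTrace:
    df = pd.read_csv(path)
    z = df["area_z"].to_numpy(float)
    return PupilTrace(
        time_s=df["time_s"].to_numpy(float),
        area=df["area_px2"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        area_z=None if np.all(np.isnan(z)) else z,
    )
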