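"""Synthetic session generator.

Emulates the three measurement streams of a head-fixed Pavlovian delay
conditioning session — the event schedule (CS tones and sucrose rewards),
the lick-contact train, and the tracked 8-point pupil-edge landmark table
— with the statistical structure the downstream analysis assumes:

* inter-event intervals uniform on [10, 20] s (mean 15 s), 120 rewards per
  session by default, 1-s CS; in the contingent group each reward follows
  a CS by exactly the CS duration, in the non-contingent group the two
  streams are independent renewal processes;
* licking as an alternating bout/pause renewal process whose pooled
  inter-response times (IRTs) follow the normalized two-exponential
  mixture q·w·e^{-wτ} + (1-q)·b·e^{-bτ} (geometric bout length with
  continuation probability q, pause hazard b, within-bout rate w);
* anticipatory licking during the CS in the contingent group and
  consummatory licking after every reward, as multiplicative gains on the
  pause (bout-initiation) hazard, plus a dose-dependent multiplicative
  suppression standing in for haloperidol;
* a latent pupil radius driven by difference-of-exponential kernels at CS
  (contingent only), US and bout onsets, a small pre-bout constriction
  dip, and slow AR(1) drift; each frame emits the 8 landmarks at
  45-degree spacing with Gaussian jitter, per-point confidence, and
  occasional blinks that collapse the points and drop confidence.

All randomness derives from a single root seed through documented child
streams, so identical seeds reproduce sessions file-for-file.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import io as pio
from .types import DOSES, GROUPS, POINT_ANGLES, POINT_NAMES, EventSchedule, LandmarkSeries, LickTrain

# Child-stream constants: rng for stream k of session seed s is
# numpy.random.default_rng([s, STREAM_*]). Keeping the constants distinct
# keeps e.g. the CS and US streams of a non-contingent session independent.
STREAM_CS = 11
STREAM_US = 12
STREAM_LICKS = 21
STREAM_LANDMARKS = 31


class PupilKernel(BaseModel):
    """Difference-of-exponentials pupil impulse response.

    ``amplitude`` is the peak radius change in pixels (negative for a
    constriction), reached ``latency`` + rise-to-peak seconds after the
    event; ``rise`` and ``decay`` are the two time constants (s), with
    rise < decay.
    """

    model_config = ConfigDict(extra="forbid")

    amplitude: float
    latency: float = 0.0
    rise: float = 0.3
    decay: float = 1.0

    @model_validator(mode="after")
    def _check(self):
        if not (0 < self.rise < self.decay):
            raise ValueError("require 0 < rise < decay")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        return self

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel value at times ``t`` (s) relative to the event."""
        t = np.asarray(t, dtype=float)
        s = t - self.latency
        raw = np.where(s > 0, np.exp(-s / self.decay) - np.exp(-s / self.rise), 0.0)
        # normalize so the peak equals `amplitude`
        s_peak = (math.log(self.decay) - math.log(self.rise)) * self.rise * self.decay / (
            self.decay - self.rise
        )
        peak = math.exp(-s_peak / self.decay) - math.exp(-s_peak / self.rise)
        return self.amplitude * raw / peak

    @property
    def support(self) -> float:
        """Time past which the kernel is negligible (s)."""
        return self.latency + 8.0 * self.decay


def _default_kernels() -> Dict[str, PupilKernel]:
    return {
        "cs": PupilKernel(amplitude=1.5, latency=0.2, rise=0.3, decay=1.2),
        "us": PupilKernel(amplitude=2.0, latency=0.3, rise=0.5, decay=1.5),
        "bout": PupilKernel(amplitude=1.0, latency=0.1, rise=0.4, decay=1.2),
        # small constriction just before bout onset (anchored dip_lead_s early)
        "pre_bout_dip": PupilKernel(amplitude=-0.5, latency=0.0, rise=0.1, decay=0.3),
    }


def _default_suppression() -> Dict[str, float]:
    return {"saline": 1.0, "0.1": 0.6, "0.2": 0.4, "0.5": 0.2}


class GeneratorConfig(BaseModel):
    """All tunables of the synthetic-session generator.

    Bout parameters default to (q, w, b) = (0.7, 8, 0.3): roughly 8 licks/s
    inside bouts, a baseline bout-initiation hazard of 0.3 s^-1, and 70% of
    IRTs falling inside bouts, typical of mouse licking microstructure.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0

    # bout/pause lick process
    q_true: float = 0.7
    w_true: float = 8.0   # licks/s within bouts
    b_true: float = 0.3   # bout initiations/s during pauses
    cs_anticipation_gain: float = 5.0   # on pause hazard during CS (contingent)
    us_consummatory_gain: float = 10.0  # on pause hazard for 1 s after US
    event_gain_window_s: float = 1.0
    dose_suppression: Dict[str, float] = None  # type: ignore[assignment]

    # pupil / landmarks
    pupil_kernels: Dict[str, PupilKernel] = None  # type: ignore[assignment]
    dip_lead_s: float = 0.5
    pupil_baseline_radius: float = 30.0  # px
    pupil_aspect: float = 1.0            # semi-minor / semi-major
    pupil_center: Tuple[float, float] = (320.0, 240.0)
    noise_sd: float = 0.5                # px landmark jitter
    frame_rate: float = 30.0             # Hz
    drift_sd: float = 0.8                # px, stationary sd of AR(1) drift
    drift_tau_s: float = 30.0            # AR(1) time constant
    blink_rate_hz: float = 0.02
    blink_duration_s: float = 0.2
    confidence_mean: float = 0.98
    blink_confidence: float = 0.1

    # schedule
    min_iti_s: float = 10.0
    max_iti_s: float = 20.0
    cs_duration_s: float = 1.0
    post_session_buffer_s: float = 10.0

    @model_validator(mode="before")
    @classmethod
    def _fill_defaults(cls, data):
        if isinstance(data, dict):
            if data.get("dose_suppression") is None:
                data["dose_suppression"] = _default_suppression()
            if data.get("pupil_kernels") is None:
                data["pupil_kernels"] = _default_kernels()
        return data

    @model_validator(mode="after")
    def _check(self):
        if not (self.w_true > self.b_true > 0):
            raise ValueError("require w_true > b_true > 0")
        if not (0 < self.q_true < 1):
            raise ValueError("require 0 < q_true < 1")
        supp = [self.dose_suppression[d] for d in DOSES if d in self.dose_suppression]
        if any(not (0 < s <= 1) for s in supp):
            raise ValueError("dose_suppression values must lie in (0, 1]")
        if any(later > earlier for earlier, later in zip(supp, supp[1:])):
            raise ValueError("dose_suppression must be non-increasing in dose")
        if not (0 < self.min_iti_s < self.max_iti_s):
            raise ValueError("require 0 < min_iti_s < max_iti_s")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return self


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ----------------------------------------------------------------- schedule

def gen_schedule(
    group: str,
    n_rewards: int,
    config: GeneratorConfig,
    dose: str = "saline",
    seed: Optional[int] = None,
) -> EventSchedule:
    """Generate one session's CS/US schedule.

    Contingent sessions place each of the ``n_rewards`` rewards exactly
    ``cs_duration_s`` after a CS onset; non-contingent sessions draw the
    US renewal process from an independent stream and emit CS onsets
    until the session ends (last US + post-session buffer).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; allowed values are {GROUPS}")
    if n_rewards < 1:
        raise ValueError("n_rewards must be >= 1")
    seed = config.seed if seed is None else seed
    lo, hi = config.min_iti_s, config.max_iti_s
    rng_cs = _rng(seed, STREAM_CS)
    rng_us = _rng(seed, STREAM_US)

    if group == "contingent":
        cs = np.cumsum(rng_cs.uniform(lo, hi, size=n_rewards))
        us = cs + config.cs_duration_s
        length = us[-1] + config.post_session_buffer_s
    else:
        us = np.cumsum(rng_us.uniform(lo, hi, size=n_rewards))
        length = us[-1] + config.post_session_buffer_s
        # CS stream: independent renewal process truncated at session end
        n_max = int(length / lo) + 2
        cs = np.cumsum(rng_cs.uniform(lo, hi, size=n_max))
        cs = cs[cs + config.cs_duration_s <= length]
    return EventSchedule(
        cs_onsets=cs,
        us_times=us,
        group=group,
        dose=dose,
        cs_duration=config.cs_duration_s,
        session_length=float(length),
    )


# -------------------------------------------------------------------- licks

def _gain_windows(schedule: EventSchedule, config: GeneratorConfig):
    """(starts, ends, gains) of pause-hazard modulation windows."""
    starts, ends, gains = [], [], []
    if schedule.group == "contingent" and config.cs_anticipation_gain != 1.0:
        for t in schedule.cs_onsets:
            starts.append(t)
            ends.append(t + config.event_gain_window_s)
            gains.append(config.cs_anticipation_gain)
    if config.us_consummatory_gain != 1.0:
        for t in schedule.us_times:
            starts.append(t)
            ends.append(t + config.event_gain_window_s)
            gains.append(config.us_consummatory_gain)
    order = np.argsort(starts) if starts else []
    return (
        np.asarray(starts, float)[order] if len(starts) else np.empty(0),
        np.asarray(ends, float)[order] if len(starts) else np.empty(0),
        np.asarray(gains, float)[order] if len(starts) else np.empty(0),
    )


def gen_licks(
    schedule: EventSchedule,
    config: GeneratorConfig,
    seed: Optional[int] = None,
    return_bout_onsets: bool = False,
) -> Union[LickTrain, Tuple[LickTrain, np.ndarray]]:
    """Simulate the lick train for one session.

    Alternating renewal process: pauses end with hazard
    ``b_true * gain(t) * dose_suppression[dose]`` (inhomogeneous
    exponential, sampled by Lewis thinning), bouts have within-bout IRTs
    Exp(``w_true``) and geometric length with continuation probability
    ``q_true``. With all gains at 1, pooled IRTs follow the normalized
    two-exponential mixture exactly.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, STREAM_LICKS)
    supp = config.dose_suppression[schedule.dose]
    starts, ends, gains = _gain_windows(schedule, config)
    gmax = max(1.0, float(gains.max()) if len(gains) else 1.0)
    lam_max = config.b_true * supp * gmax
    L = schedule.session_length

    def hazard(t: float) -> float:
        g = 1.0
        if len(starts):
            i = np.searchsorted(starts, t, side="right") - 1
            # windows can overlap (CS then US 1 s later); take the max gain
            j = i
            while j >= 0 and ends[j] > t:
                g = max(g, gains[j])
                j -= 1
                if j >= 0 and t - starts[j] > 2 * config.event_gain_window_s:
                    break
        return config.b_true * supp * g

    licks: List[float] = []
    onsets: List[float] = []
    t = 0.0
    while True:
        # pause: thinned inhomogeneous exponential
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= L:
                break
            if rng.uniform() * lam_max <= hazard(t):
                break
        if t >= L:
            break
        onsets.append(t)
        licks.append(t)
        # bout: geometric number of continuation licks
        while rng.uniform() < config.q_true:
            t += rng.exponential(1.0 / config.w_true)
            if t >= L:
                break
            licks.append(t)
        if t >= L:
            break
        # next pause restarts at the bout's last lick (memoryless hazard)
        t = licks[-1]
    train = LickTrain(np.asarray(licks), session_length=L)
    if return_bout_onsets:
        return train, np.asarray(onsets)
    return train


# ---------------------------------------------------------------- landmarks

def _add_kernel_responses(
    radius: np.ndarray, time_s: np.ndarray, events: np.ndarray, kernel: PupilKernel
) -> None:
    if len(events) == 0:
        return
    dt = time_s[1] - time_s[0] if len(time_s) > 1 else 1.0
    n_sup = int(kernel.support / dt) + 1
    for e in events:
        i0 = np.searchsorted(time_s, e)
        i1 = min(i0 + n_sup, len(time_s))
        if i0 >= len(time_s):
            continue
        radius[i0:i1] += kernel.evaluate(time_s[i0:i1] - e)


def gen_landmarks(
    schedule: EventSchedule,
    licks: LickTrain,
    config: GeneratorConfig,
    seed: Optional[int] = None,
    bout_onsets: Optional[np.ndarray] = None,
) -> LandmarkSeries:
    """Emit the 8-point landmark table a pose tracker would produce.

    The latent pupil radius is baseline + event-kernel responses + AR(1)
    drift; frames place the 8 named landmarks at 45-degree spacing on the
    (optionally anisotropic) ellipse of that radius, add isotropic
    Gaussian jitter of sd ``noise_sd`` and a per-point confidence.
    Blinks (Bernoulli onsets at ``blink_rate_hz``) collapse the points
    toward the eyelid line and drop confidence to ``blink_confidence``.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, STREAM_LANDMARKS)
    dt = 1.0 / config.frame_rate
    n = int(schedule.session_length / dt) + 1
    time_s = np.arange(n) * dt

    radius = np.full(n, config.pupil_baseline_radius)
    kern = config.pupil_kernels
    if "cs" in kern and schedule.group == "contingent":
        _add_kernel_responses(radius, time_s, schedule.cs_onsets, kern["cs"])
    if "us" in kern:
        _add_kernel_responses(radius, time_s, schedule.us_times, kern["us"])
    if bout_onsets is None:
        bout_onsets = _true_param_bout_onsets(licks, config)
    if "bout" in kern:
        _add_kernel_responses(radius, time_s, bout_onsets, kern["bout"])
    if "pre_bout_dip" in kern:
        _add_kernel_responses(
            radius, time_s, bout_onsets - config.dip_lead_s, kern["pre_bout_dip"]
        )

    # slow AR(1) drift with stationary sd drift_sd
    if config.drift_sd > 0:
        rho = math.exp(-dt / config.drift_tau_s)
        innov = rng.normal(0.0, config.drift_sd * math.sqrt(1 - rho**2), size=n)
        drift = np.empty(n)
        drift[0] = rng.normal(0.0, config.drift_sd)
        for i in range(1, n):
            drift[i] = rho * drift[i - 1] + innov[i]
        radius = radius + drift
    radius = np.clip(radius, 1.0, None)

    cx, cy = config.pupil_center
    cos_a, sin_a = np.cos(POINT_ANGLES), np.sin(POINT_ANGLES)
    xy = np.empty((n, 8, 2))
    xy[:, :, 0] = cx + radius[:, None] * cos_a[None, :]
    xy[:, :, 1] = cy + (radius * config.pupil_aspect)[:, None] * sin_a[None, :]
    if config.noise_sd > 0:
        xy += rng.normal(0.0, config.noise_sd, size=xy.shape)

    conf = np.clip(rng.normal(config.confidence_mean, 0.01, size=(n, 8)), 0.0, 1.0)

    # blinks: Bernoulli onset per frame, fixed duration
    if config.blink_rate_hz > 0:
        blink_onset = rng.uniform(size=n) < config.blink_rate_hz * dt
        blink = np.zeros(n, dtype=bool)
        span = max(1, int(round(config.blink_duration_s / dt)))
        for i in np.flatnonzero(blink_onset):
            blink[i : i + span] = True
        if blink.any():
            # points collapse toward the eyelid line through the eye center
            xy[blink, :, 1] = cy + 0.05 * (xy[blink, :, 1] - cy)
            conf[blink] = np.clip(
                rng.normal(config.blink_confidence, 0.03, size=(int(blink.sum()), 8)),
                0.0,
                0.45,
            )

    return LandmarkSeries(time_s=time_s, xy=xy, likelihood=conf, point_names=POINT_NAMES)


def _true_param_bout_onsets(licks: LickTrain, config: GeneratorConfig) -> np.ndarray:
    """Bout onsets implied by the generator's own (q, w, b)."""
    from .bouts import IRTMixtureParams, classify_licks, compute_irts, segment_bouts

    if len(licks) < 2:
        return np.empty(0)
    params = IRTMixtureParams(q=config.q_true, w=config.w_true, b=config.b_true)
    labels = classify_licks(compute_irts(licks), params)
    return segment_bouts(licks, labels).bout_onsets


# --------------------------------------------------------------- experiment

def _subject_dose_plan(
    n_subjects: int, n_training_sessions: int, dose_blocks: Optional[Sequence[str]]
) -> List[List[str]]:
    """Per-subject session dose labels: training (saline) then dose blocks.

    Each dose block is a saline session followed by a drug session; the
    first half of subjects receives the blocks in the given (ascending)
    order, the second half in reverse (descending).
    """
    plans = []
    for i in range(n_subjects):
        plan = ["saline"] * n_training_sessions
        if dose_blocks:
            order = list(dose_blocks) if i < n_subjects / 2 else list(dose_blocks)[::-1]
            for dose in order:
                plan.extend(["saline", dose])
        plans.append(plan)
    return plans


def gen_experiment(
    n_subjects_per_group: int,
    n_sessions: int,
    dose_blocks: Optional[Sequence[str]],
    config: GeneratorConfig,
    out_dir: Union[str, Path],
    n_rewards: int = 120,
    include_landmarks: bool = True,
) -> dict:
    """Write a full synthetic experiment to ``out_dir`` and return its manifest.

    Layout: ``<subject>/ses<k>/{schedule.json, licks.csv, landmarks.csv}``
    with a top-level ``manifest.json`` recording the generator config and
    the SHA-256 of every file. Identical seeds reproduce the directory
    byte-for-byte.
    """
    if n_subjects_per_group < 1 or n_sessions < 0:
        raise ValueError("counts must be >= 1 (sessions >= 0)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}
    subjects = []
    for gi, group in enumerate(GROUPS):
        plans = _subject_dose_plan(n_subjects_per_group, n_sessions, dose_blocks)
        for si in range(n_subjects_per_group):
            subject = f"{'C' if group == 'contingent' else 'N'}{si + 1:02d}"
            subjects.append({"subject": subject, "group": group, "doses": plans[si]})
            for k, dose in enumerate(plans[si]):
                ses_seed = int(
                    np.random.SeedSequence(
                        [config.seed, gi, si, k]
                    ).generate_state(1)[0] % (2**31)
                )
                sdir = out / subject / f"ses{k + 1:02d}"
                sdir.mkdir(parents=True, exist_ok=True)
                schedule = gen_schedule(group, n_rewards, config, dose=dose, seed=ses_seed)
                licks, onsets = gen_licks(
                    schedule, config, seed=ses_seed, return_bout_onsets=True
                )
                pio.write_schedule(schedule, sdir / "schedule.json")
                pio.write_licks(licks, sdir / "licks.csv")
                if include_landmarks:
                    lm = gen_landmarks(
                        schedule, licks, config, seed=ses_seed, bout_onsets=onsets
                    )
                    pio.write_landmarks(lm, sdir / "landmarks.csv")
                for f in sorted(sdir.iterdir()):
                    files[str(f.relative_to(out))] = hashlib.sha256(
                        f.read_bytes()
                    ).hexdigest()
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "n_rewards": n_rewards,
        "n_sessions_training": n_sessions,
        "dose_blocks": list(dose_blocks) if dose_blocks else [],
        "subjects": subjects,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def sample_annotation_frames(
    sources: Sequence[Union[str, Path, LandmarkSeries]],
    frames_per_video: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample frames for a tracker training set (annotation fixture).

    Draws ``frames_per_video`` distinct frames from each landmark source
    (file path or in-memory series), mirroring how pose-tracker training
    sets are assembled; e.g. 15 frames from each of 110 videos gives a
    1,650-frame dataset. Returns one row per sampled frame.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for vi, src in enumerate(sources):
        series = src if isinstance(src, LandmarkSeries) else pio.read_landmarks(src)
        n = len(series)
        if n < frames_per_video:
            raise ValueError(
                f"source {vi} has only {n} frames; need {frames_per_video}"
            )
        idx = np.sort(rng.choice(n, size=frames_per_video, replace=False))
        for i in idx:
            rows.append(
                {"video": vi, "frame_index": int(i), "time_s": float(series.time_s[i])}
            )
    return pd.DataFrame(rows)
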