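"""Event-aligned signal extraction and window statistics.

Aligns lick trains (binned to rates) and pupil z-traces (resampled at bin
centers) to CS onsets, US deliveries or bout onsets over a [-3, +3) s
window; computes Pre/CS/US window means, pre/post difference scores, the
bout-onset contamination filter (bouts with a CS or US within +/-3 s are
excluded), the CS/US overlap statistic for non-contingent schedules, and
the tidy long-format window table that a downstream linear mixed model
consumes. All window and bin conventions are half-open [t0, t1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import EventSchedule, LickTrain, PupilTrace, SessionData

log = logging.getLogger(__name__)

#: Default peri-event window (s) and analysis windows relative to the event.
DEFAULT_WINDOW = (-3.0, 3.0)
PRE_WINDOW = (-1.0, 0.0)
CS_WINDOW = (0.0, 1.0)
US_WINDOW = (0.0, 1.0)


@dataclass
class AlignedMatrix:
    """Trials x time-bins matrix of a signal aligned to an event class."""

    event_class: str              # "CS", "US" or "bout_onset"
    bin_edges: np.ndarray         # len n_bins + 1, seconds relative to event
    values: np.ndarray            # (n_trials, n_bins)
    event_times: np.ndarray       # retained event times (session clock)
    signal_kind: str              # "lick_rate" or "pupil_z"
    n_dropped: int = 0            # trials dropped (incomplete / invalid gaps)
    trial_meta: Optional[pd.DataFrame] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def _check_window(window: Tuple[float, float], bin_width: float) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    n_bins = (t1 - t0) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    return t0 + bin_width * np.arange(int(round(n_bins)) + 1)


def align_signal(
    signal: Union[LickTrain, PupilTrace],
    events: Sequence[float],
    window: Tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = 0.1,
    event_class: str = "CS",
    recording_span: Optional[Tuple[float, float]] = None,
) -> AlignedMatrix:
    """Align a lick train or pupil trace to a set of event times.

    Licks are binned into half-open bins and expressed as rates (licks/s);
    the pupil z-trace is linearly resampled at bin centers. Trials whose
    window extends beyond the recording, or (for pupil) overlaps a
    remaining invalid gap, are dropped and counted in ``n_dropped``.
    """
    events = np.asarray(events, dtype=float)
    if len(events) == 0:
        raise ValueError("events must be non-empty")
    edges = _check_window(window, bin_width)
    t0, t1 = window

    if isinstance(signal, LickTrain):
        lo = 0.0
        hi = signal.session_length if signal.session_length is not None else np.inf
        if recording_span is not None:
            lo, hi = recording_span
        keep = (events + t0 >= lo) & (events + t1 <= hi)
        rows = []
        for e in events[keep]:
            counts, _ = np.histogram(signal.lick_times - e, bins=edges)
            rows.append(counts / bin_width)
        values = np.vstack(rows) if rows else np.empty((0, len(edges) - 1))
        return AlignedMatrix(
            event_class=event_class, bin_edges=edges, values=values,
            event_times=events[keep], signal_kind="lick_rate",
            n_dropped=int((~keep).sum()),
        )

    if isinstance(signal, PupilTrace):
        if signal.area_z is None:
            raise ValueError("pupil trace has no z-scores; run zscore_session first")
        tr_t = signal.time_s
        lo, hi = tr_t[0], tr_t[-1]
        centers = 0.5 * (edges[:-1] + edges[1:])
        valid_t = tr_t[signal.valid]
        valid_z = signal.area_z[signal.valid]
        invalid_t = tr_t[~signal.valid]
        rows, kept, dropped = [], [], 0
        for e in events:
            if e + t0 < lo or e + t1 > hi:
                dropped += 1
                continue
            if len(invalid_t):
                j0, j1 = np.searchsorted(invalid_t, [e + t0, e + t1])
                if j1 > j0:  # an invalid frame falls inside the window
                    dropped += 1
                    continue
            rows.append(np.interp(e + centers, valid_t, valid_z))
            kept.append(e)
        values = np.vstack(rows) if rows else np.empty((0, len(centers)))
        if dropped:
            log.debug("align_signal: dropped %d/%d %s trials", dropped, len(events), event_class)
        return AlignedMatrix(
            event_class=event_class, bin_edges=edges, values=values,
            event_times=np.asarray(kept), signal_kind="pupil_z", n_dropped=dropped,
        )

    raise TypeError("signal must be a LickTrain or PupilTrace")


def window_mean(
    aligned: AlignedMatrix, window: Tuple[float, float]
) -> Tuple[np.ndarray, float]:
    """Per-trial and grand mean over bins whose centers fall in [t0, t1)."""
    t0, t1 = window
    if t0 < aligned.bin_edges[0] - 1e-12 or t1 > aligned.bin_edges[-1] + 1e-12:
        raise ValueError("window lies outside the aligned range")
    centers = aligned.bin_centers
    mask = (centers >= t0) & (centers < t1)
    if not mask.any():
        raise ValueError("no bins fall inside the requested window")
    per_trial = aligned.values[:, mask].mean(axis=1)
    grand = float(per_trial.mean()) if len(per_trial) else float("nan")
    return per_trial, grand


def prepost_diff(aligned: AlignedMatrix, split: float = 0.0) -> Tuple[np.ndarray, float]:
    """Post-minus-pre difference score: mean over [split, end) minus [start, split).

    Returns per-trial differences and the session mean.
    """
    pre, _ = window_mean(aligned, (float(aligned.bin_edges[0]), split))
    post, _ = window_mean(aligned, (split, float(aligned.bin_edges[-1])))
    diff = post - pre
    return diff, float(diff.mean()) if len(diff) else np.nan


def filter_bout_onsets(
    onsets: Sequence[float], schedule: EventSchedule, exclusion_s: float = 3.0
) -> np.ndarray:
    """Drop bout onsets contaminated by a nearby CS or US.

    An onset is retained iff no CS onset and no US time lies in the open
    interval (onset - exclusion_s, onset + exclusion_s).
    """
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) == 0:
        return onsets
    events = np.sort(np.concatenate([schedule.cs_onsets, schedule.us_times]))
    if len(events) == 0:
        return onsets.copy()
    # events strictly inside the open interval; boundary hits do not exclude
    lo = np.searchsorted(events, onsets - exclusion_s, side="right")
    hi = np.searchsorted(events, onsets + exclusion_s, side="left")
    keep = (hi - lo) == 0
    return onsets[keep]


def overlap_fraction(schedule: EventSchedule) -> float:
    """Percentage of CS presentations with >= 1 US during the tone.

    A US counts as overlapping iff it falls in [CS onset, CS onset +
    cs_duration); a US exactly at CS offset (the contingent design) is
    not an overlap under this half-open convention.
    """
    cs = schedule.cs_onsets
    if len(cs) == 0:
        raise ValueError("schedule has no CS presentations")
    us = np.sort(schedule.us_times)
    lo = np.searchsorted(us, cs, side="left")
    hi = np.searchsorted(us, cs + schedule.cs_duration, side="left")
    return 100.0 * float(np.mean(hi > lo))


def session_window_summary(
    data: SessionData, bin_width: float = 0.1
) -> pd.DataFrame:
    """Pre/CS/US window means of lick rate and pupil z for one session."""
    sched = data.schedule
    rows = []
    aligned_lick_cs = align_signal(
        data.licks, sched.cs_onsets, DEFAULT_WINDOW, bin_width, event_class="CS"
    )
    aligned_lick_us = align_signal(
        data.licks, sched.us_times, DEFAULT_WINDOW, bin_width, event_class="US"
    )
    pupil_cs = pupil_us = None
    if data.pupil is not None:
        pupil_cs = align_signal(
            data.pupil, sched.cs_onsets, DEFAULT_WINDOW, bin_width, event_class="CS"
        )
        pupil_us = align_signal(
            data.pupil, sched.us_times, DEFAULT_WINDOW, bin_width, event_class="US"
        )

    def grand(aligned, win):
        if aligned is None or aligned.n_trials == 0:
            return np.nan
        return window_mean(aligned, win)[1]

    for win_name, lick_mat, lick_win, pup_mat, pup_win in (
        ("Pre", aligned_lick_cs, PRE_WINDOW, pupil_cs, PRE_WINDOW),
        ("CS", aligned_lick_cs, CS_WINDOW, pupil_cs, CS_WINDOW),
        ("US", aligned_lick_us, US_WINDOW, pupil_us, US_WINDOW),
    ):
        rows.append(
            {
                "subject": data.subject,
                "group": data.group,
                "dose": data.dose,
                "session": data.session,
                "window": win_name,
                "lick_rate_hz": grand(lick_mat, lick_win),
                "pupil_z": grand(pup_mat, pup_win),
            }
        )
    return pd.DataFrame(rows)


def build_window_table(
    sessions: Iterable[SessionData], bin_width: float = 0.1
) -> pd.DataFrame:
    """Tidy long window table over sessions: one row per subject x session x
    dose x window, with ``lick_rate_hz`` and ``pupil_z`` columns.

    Sessions that fail (e.g. no alignable trials) are logged and skipped,
    mirroring how sessions lost to recording failure are excluded.
    """
    frames = []
    for data in sessions:
        try:
            frames.append(session_window_summary(data, bin_width))
        except (ValueError, TypeError) as exc:
            log.warning(
                "skipping session %s/%s: %s", data.subject, data.session, exc
            )
    if not frames:
        raise ValueError("no sessions could be summarized")
    return pd.concat(frames, ignore_index=True)


#: Fixed-effects / random-effects structure used for the delegated mixed-model
#: fit: window x group (x dose) fixed effects, subject-level random
#: intercepts with random slopes for window.
DEFAULT_MODEL_FORMULA = "lick_rate_hz ~ C(window, Treatment('Pre')) * C(group)"


def fit_window_mixed_model(
    table: pd.DataFrame,
    formula: str = DEFAULT_MODEL_FORMULA,
    re_formula: str = "~C(window, Treatment('Pre'))",
):
    """Delegate the mixed-model fit on the window table to statsmodels.

    Fits ``formula`` with subject-level random effects (``re_formula``)
    via MixedLM/REML and returns the fitted results object; if the
    maximal random structure fails to converge, the fit is retried with
    random intercepts only (the usual simplification step). Estimation
    itself is deliberately not reimplemented here.
    """
    import warnings

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    response = formula.split("~")[0].strip()
    data = table.dropna(subset=[response])

    def _fit(re):
        model = smf.mixedlm(formula, data, groups=data["subject"], re_formula=re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return model.fit(reml=True)

    result = _fit(re_formula)
    if not result.converged and re_formula != "~1":
        log.info("maximal random structure did not converge; retrying with '~1'")
        result = _fit("~1")
    return result
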