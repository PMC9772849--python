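"""Peri-event alignment, window statistics, filters, and the window table."""

import numpy as np
import pandas as pd
import pytest

from pavpupil import alignment, pupil, synthetic as syn
from pavpupil.types import EventSchedule, LickTrain, PupilTrace, SessionData


def _constant_trace(value=0.5, n=4000, dt=0.05):
    t = np.arange(n) * dt
    tr = PupilTrace(time_s=t, area=np.full(n, 100.0), valid=np.ones(n, bool))
    return tr.with_z(np.full(n, value))


class TestAlignSignal:
    def test_constant_pupil_fills_matrix(self):
        tr = _constant_trace(0.5)
        mat = alignment.align_signal(tr, [20.0, 50.0, 90.0])
        np.testing.assert_allclose(mat.values, 0.5)
        assert mat.signal_kind == "pupil_z"

    def test_incomplete_window_trial_dropped(self):
        tr = _constant_trace(0.5, n=200, dt=0.05)  # 10 s recording
        mat = alignment.align_signal(tr, [1.0, 5.0])
        assert mat.n_trials == 1
        assert mat.n_dropped == 1

    def test_bin_count_half_open(self):
        tr = _constant_trace(0.0, n=12000, dt=0.01)
        mat = alignment.align_signal(tr, [60.0], bin_width=0.01)
        assert mat.values.shape == (1, 600)

    def test_invalid_gap_drops_pupil_trial(self):
        tr = _constant_trace(0.5)
        tr.valid[800:815] = False  # 0.75 s gap at t = 40 s
        mat = alignment.align_signal(tr, [40.0, 100.0])
        assert mat.n_trials == 1
        assert mat.n_dropped == 1

    def test_lick_binning_conserves_counts(self):
        """Total binned lick count equals brute-force window counting."""
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 300, size=2000))
        t = t[np.concatenate(([True], np.diff(t) > 0))]
        licks = LickTrain(t, session_length=300.0)
        events = np.arange(10.0, 290.0, 17.0)
        mat = alignment.align_signal(licks, events, bin_width=0.1)
        total_binned = mat.values.sum() * 0.1
        brute = sum(np.sum((t >= e - 3) & (t < e + 3)) for e in mat.event_times)
        assert total_binned == pytest.approx(brute)

    def test_each_lick_in_exactly_one_bin(self):
        """Half-open bins: a lick exactly on an interior edge is counted once."""
        licks = LickTrain(np.array([9.9, 10.0, 10.05, 10.1]), session_length=30.0)
        mat = alignment.align_signal(licks, [10.0], bin_width=0.1)
        assert mat.values.sum() * 0.1 == 4

    def test_empty_events_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            alignment.align_signal(_constant_trace(), [])

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            alignment.align_signal(_constant_trace(), [50.0], bin_width=0.7)


class TestWindowMean:
    def test_constant_signal(self):
        mat = alignment.align_signal(_constant_trace(2.0), [50.0])
        _, grand = alignment.window_mean(mat, (-1.0, 0.0))
        assert grand == pytest.approx(2.0)

    def test_ramp_signal(self):
        """On z(t) = t - event, the Pre window [-1, 0) has mean -0.5."""
        n, dt = 4000, 0.05
        t = np.arange(n) * dt
        tr = PupilTrace(time_s=t, area=np.ones(n), valid=np.ones(n, bool)).with_z(t - 100.0)
        mat = alignment.align_signal(tr, [100.0], bin_width=0.1)
        _, grand = alignment.window_mean(mat, (-1.0, 0.0))
        assert grand == pytest.approx(-0.5, abs=1e-9)

    def test_window_outside_range_errors(self):
        mat = alignment.align_signal(_constant_trace(), [50.0])
        with pytest.raises(ValueError, match="outside"):
            alignment.window_mean(mat, (3.0, 5.0))


class TestPrePostDiff:
    def _trace_with(self, fn):
        n, dt = 8000, 0.05
        t = np.arange(n) * dt
        tr = PupilTrace(time_s=t, area=np.ones(n), valid=np.ones(n, bool))
        return tr.with_z(fn(t))

    def test_step_of_height_h(self):
        h = 1.7
        tr = self._trace_with(lambda t: np.where(t >= 200.0, h, 0.0))
        mat = alignment.align_signal(tr, [200.0], bin_width=0.1)
        _, diff = alignment.prepost_diff(mat)
        assert diff == pytest.approx(h, abs=1e-9)

    def test_time_symmetric_signal_zero(self):
        tr = self._trace_with(lambda t: np.abs(t - 200.0))
        mat = alignment.align_signal(tr, [200.0], bin_width=0.1)
        _, diff = alignment.prepost_diff(mat)
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_linearity(self):
        f1 = lambda t: np.sin(t / 7.0)
        f2 = lambda t: np.where(t >= 200.0, 1.0, 0.0)
        mats = [
            alignment.align_signal(self._trace_with(f), [200.0], bin_width=0.1)
            for f in (f1, f2, lambda t: 2.0 * f1(t) + 3.0 * f2(t))
        ]
        d = [alignment.prepost_diff(m)[1] for m in mats]
        assert d[2] == pytest.approx(2.0 * d[0] + 3.0 * d[1], abs=1e-9)


class TestFilterBoutOnsets:
    def _schedule(self, cs, us):
        return EventSchedule(
            cs_onsets=np.asarray(cs, float), us_times=np.asarray(us, float),
            group="contingent", session_length=1000.0,
        )

    def test_nearby_cs_excludes(self):
        sched = self._schedule([12.0], [13.0])
        assert len(alignment.filter_bout_onsets([10.0], sched)) == 0

    def test_distant_events_retained(self):
        sched = self._schedule([14.0], [15.0])
        np.testing.assert_allclose(alignment.filter_bout_onsets([10.0], sched), [10.0])

    def test_boundary_is_open(self):
        """An event exactly 3 s away does not exclude the onset."""
        sched = self._schedule([13.0], [500.0])
        np.testing.assert_allclose(alignment.filter_bout_onsets([10.0], sched), [10.0])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        onsets = np.sort(rng.uniform(0, 1000, size=1000))
        cs = np.sort(rng.uniform(0, 1000, size=60))
        us = np.sort(rng.uniform(0, 1000, size=60))
        sched = self._schedule(cs, us)
        got = alignment.filter_bout_onsets(onsets, sched)
        events = np.concatenate([cs, us])
        expected = [
            o for o in onsets
            if not np.any((events > o - 3.0) & (events < o + 3.0))
        ]
        np.testing.assert_allclose(got, expected)


class TestOverlapFraction:
    def test_single_overlapping_trial(self):
        sched = EventSchedule(
            cs_onsets=[10.0], us_times=[10.5], group="non-contingent",
            session_length=30.0,
        )
        assert alignment.overlap_fraction(sched) == pytest.approx(100.0)

    def test_contingent_design_never_overlaps(self, config):
        """US at CS offset: half-open convention counts zero overlap."""
        sched = syn.gen_schedule("contingent", 50, config, seed=8)
        assert alignment.overlap_fraction(sched) == 0.0

    def test_no_cs_errors(self):
        sched = EventSchedule(
            cs_onsets=[], us_times=[10.0], group="non-contingent", session_length=20.0
        )
        with pytest.raises(ValueError):
            alignment.overlap_fraction(sched)


class TestWindowTable:
    def _sessions(self, config, n_subjects=2, n_sessions=3, group="contingent"):
        out = []
        for s in range(n_subjects):
            for k in range(n_sessions):
                seed = 1000 + 10 * s + k
                sch = syn.gen_schedule(group, 20, config, seed=seed)
                licks = syn.gen_licks(sch, config, seed=seed)
                out.append(
                    SessionData(
                        subject=f"{group[:4]}-S{s}", session=k + 1,
                        schedule=sch, licks=licks,
                    )
                )
        return out

    def test_cardinality(self, config):
        table = alignment.build_window_table(self._sessions(config))
        assert len(table) == 2 * 3 * 3  # subjects x sessions x windows
        assert set(table["window"]) == {"Pre", "CS", "US"}

    def test_contingent_cs_exceeds_pre(self, config):
        table = alignment.build_window_table(self._sessions(config))
        by_win = table.groupby("window")["lick_rate_hz"].mean()
        assert by_win["CS"] > by_win["Pre"]
        assert by_win["US"] > by_win["Pre"]

    def test_noncontingent_cs_null(self, config):
        """Without anticipation, CS and Pre lick rates agree within
        Monte-Carlo error (contrast within 2 SEM of zero)."""
        sessions = self._sessions(config, n_subjects=5, n_sessions=4,
                                  group="non-contingent")
        table = alignment.build_window_table(sessions)
        wide = table.pivot_table(index=["subject", "session"], columns="window",
                                 values="lick_rate_hz")
        diff = wide["CS"] - wide["Pre"]
        sem = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 2 * sem + 1e-12

    def test_mixed_model_delegation_runs(self, config):
        sessions = self._sessions(config, n_subjects=3) + self._sessions(
            config, n_subjects=3, group="non-contingent"
        )
        table = alignment.build_window_table(sessions)
        result = alignment.fit_window_mixed_model(table)
        # the CS-vs-Pre fixed effect should be positive (anticipatory licking)
        cs_term = [k for k in result.params.index if "[T.CS]" in k and ":" not in k]
        assert result.params[cs_term[0]] > 0
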