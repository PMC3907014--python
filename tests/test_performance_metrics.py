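import numpy as np
import pytest

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import IDLE, WALK, CueEntry, CueSchedule
from gaitbci.online_decoder import StateTrace
from gaitbci.performance_metrics import (
    SessionMetrics,
    aggregate_sessions,
    binarize,
    count_omissions,
    detect_false_alarms,
    max_cross_correlation,
    max_cross_correlation_many,
    score_session,
    walk_episodes,
)


def _trace(states, t0=0.0, thresholds=(0.3, 0.7)):
    times = t0 + 0.25 * np.arange(len(states))
    return StateTrace(times, np.array(states), thresholds)


def _alt_cues(epoch_s=60.0, n=10):
    return CueSchedule(
        [
            CueEntry(IDLE if i % 2 == 0 else WALK, i * epoch_s, epoch_s)
            for i in range(n)
        ]
    )


class TestBinarize:
    def test_all_idle_cues(self):
        cues = CueSchedule([CueEntry(IDLE, 0, 10)])
        np.testing.assert_array_equal(binarize(cues), np.zeros(40, dtype=int))

    def test_alternating_cues_square_wave(self):
        seq = binarize(_alt_cues(60.0, 5))
        assert seq.size == 1200  # 300 s x 4 Hz
        assert seq[:240].sum() == 0 and seq[240:480].sum() == 240

    def test_state_trace_round_trip_preserves_transitions(self):
        states = [IDLE] * 8 + [WALK] * 12 + [IDLE] * 4
        trace = _trace(states, t0=0.75)
        seq = binarize(trace, span=0.75 + 0.25 * len(states))
        on = np.flatnonzero(np.diff(seq) == 1) + 1
        assert on.tolist() == [int((0.75 + 8 * 0.25) * 4)]

    def test_idle_before_first_sample(self):
        trace = _trace([WALK, WALK], t0=1.0)
        seq = binarize(trace, span=1.5)
        np.testing.assert_array_equal(seq, [0, 0, 0, 0, 1, 1])


class TestMaxCrossCorrelation:
    def test_identity(self):
        x = binarize(_alt_cues(10.0, 6))
        assert max_cross_correlation(x, x) == (pytest.approx(1.0), 0.0)

    def test_pure_shift_recovers_lag(self):
        x = binarize(_alt_cues(10.0, 6)).astype(float)
        shifted = np.concatenate([np.zeros(30), x[:-30]])
        r, lag = max_cross_correlation(x, shifted)
        assert r == pytest.approx(1.0)
        assert lag == 7.5

    def test_independent_sequences_low_r(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            a = rng.integers(0, 2, 1200)
            b = rng.integers(0, 2, 1200)
            r, _ = max_cross_correlation(a, b, max_lag=5.0)
            hits += abs(r) < 0.1
        assert hits >= 36  # ~95% of seeds

    def test_constant_sequence_rejected(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            max_cross_correlation(np.zeros(100), np.ones(100))

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            max_cross_correlation(np.zeros(10), np.zeros(11))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        cue = binarize(_alt_cues(15.0, 4))
        S = rng.integers(0, 2, (5, cue.size))
        many = max_cross_correlation_many(cue, S, max_lag=10.0)
        for i in range(5):
            r, _ = max_cross_correlation(cue, S[i], max_lag=10.0)
            assert many[i] == pytest.approx(r)


class TestOmissions:
    def test_perfect_tracking(self):
        cues = _alt_cues(2.0, 4)
        trace = _trace(binarize(cues).astype(object))
        trace.states = np.where(binarize(cues) == 1, WALK, IDLE)
        assert count_omissions(cues, trace) == 0

    def test_all_idle_decode(self):
        cues = _alt_cues(60.0, 10)
        trace = _trace([IDLE] * 2400)
        assert count_omissions(cues, trace) == 5

    def test_walk_just_before_cue_end_not_omission(self):
        cues = CueSchedule([CueEntry(IDLE, 0, 4), CueEntry(WALK, 4, 4)])
        states = [IDLE] * 31 + [WALK]  # walk at t=7.75, cue ends at 8.0
        assert count_omissions(cues, _trace(states)) == 0


class TestFalseAlarms:
    def test_episode_starting_mid_idle(self):
        cues = CueSchedule([CueEntry(IDLE, 0, 20), CueEntry(WALK, 20, 20)])
        states = [IDLE] * 40 + [WALK] * 24 + [IDLE] * 96
        count, durations = detect_false_alarms(cues, _trace(states))
        assert count == 1
        assert durations == [pytest.approx(6.0)]

    def test_episode_spanning_walk_to_idle_not_counted(self):
        cues = CueSchedule([CueEntry(WALK, 0, 10), CueEntry(IDLE, 10, 10)])
        states = [WALK] * 50 + [IDLE] * 30  # starts inside Walk cue
        assert detect_false_alarms(cues, _trace(states)) == (0, [])

    def test_two_episodes_in_one_idle_cue(self):
        cues = CueSchedule([CueEntry(IDLE, 0, 30)])
        states = ([IDLE] * 10 + [WALK] * 8 + [IDLE] * 10 + [WALK] * 4
                  + [IDLE] * 88)
        count, durations = detect_false_alarms(cues, _trace(states))
        assert count == 2
        assert durations == [pytest.approx(2.0), pytest.approx(1.0)]

    def test_matches_exhaustive_oracle(self):
        # brute-force interval-walk oracle over random small traces
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n_cues = rng.integers(2, 5)
            epoch = rng.integers(2, 5) * 1.0
            cues = _alt_cues(epoch, n_cues)
            n = int(cues.span * 4)
            states = np.where(rng.random(n) < 0.4, WALK, IDLE)
            trace = _trace(states)

            episodes = []
            in_walk = False
            for i, s in enumerate(states):
                if s == WALK and not in_walk:
                    start, in_walk = trace.times[i], True
                elif s == IDLE and in_walk:
                    episodes.append((start, trace.times[i]))
                    in_walk = False
            if in_walk:
                episodes.append((start, trace.times[-1] + 0.25))

            oracle_fa = [
                e1 - e0
                for e0, e1 in episodes
                if any(c.label == IDLE and c.onset <= e0 < c.end for c in cues)
            ]
            oracle_om = sum(
                1
                for c in cues
                if c.label == WALK
                and not any(e0 < c.end and e1 > c.onset for e0, e1 in episodes)
            )
            count, durations = detect_false_alarms(cues, trace)
            assert count == len(oracle_fa)
            assert durations == pytest.approx(oracle_fa)
            assert count_omissions(cues, trace) == oracle_om


class TestEpisodeMetricsPaddingInvariance:
    def test_omissions_and_false_alarms_unchanged_by_idle_padding(self):
        cues = _alt_cues(5.0, 4)
        rng = np.random.default_rng(3)
        states = np.where(rng.random(int(cues.span * 4)) < 0.3, WALK, IDLE)
        trace = _trace(states)
        fa0 = detect_false_alarms(cues, trace)
        om0 = count_omissions(cues, trace)
        padded_cues = CueSchedule(
            list(cues.entries) + [CueEntry(IDLE, cues.span, 10.0)]
        )
        padded_trace = _trace(list(states) + [IDLE] * 40)
        assert detect_false_alarms(padded_cues, padded_trace) == fa0
        assert count_omissions(padded_cues, padded_trace) == om0


class TestAggregateSessions:
    def test_identical_sessions(self):
        s = SessionMetrics(0.5, 1.0, 0, 1, [3.0])
        out = aggregate_sessions([s] * 5)
        assert out["overall"]["xcorr_mean"] == pytest.approx(0.5)
        assert out["overall"]["xcorr_sd"] == pytest.approx(0.0)
        assert out["overall"]["false_alarms_per_session"] == pytest.approx(1.0)
        assert out["overall"]["fa_duration_mean_s"] == pytest.approx(3.0)

    def test_grouping(self):
        a = SessionMetrics(0.8, 2.0, 0, 0)
        b = SessionMetrics(0.6, 4.0, 1, 2, [5.0, 7.0])
        out = aggregate_sessions([a, b], groups=["s1", "s2"])
        assert out["s1"]["xcorr_mean"] == pytest.approx(0.8)
        assert out["s2"]["fa_duration_mean_s"] == pytest.approx(6.0)
        assert out["overall"]["omissions_total"] == 1

    def test_count_weighted_duration_from_means(self):
        # sessions carrying only (count, mean): pooled mean is weighted
        s1 = SessionMetrics(0.7, 1.0, 0, 2, [], fa_duration_mean=4.0)
        s2 = SessionMetrics(0.7, 1.0, 0, 1, [], fa_duration_mean=10.0)
        out = aggregate_sessions([s1, s2])
        assert out["overall"]["fa_duration_mean_s"] == pytest.approx(6.0)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_sessions([])


class TestScoreSession:
    def test_walk_episode_extraction(self):
        trace = _trace([IDLE, WALK, WALK, IDLE, WALK])
        eps = walk_episodes(trace)
        assert eps == [(0.25, 0.75), (1.0, pytest.approx(1.25))]

    def test_score_session_shapes(self):
        cues = _alt_cues(5.0, 4)
        seq = binarize(cues)
        trace = _trace(np.where(seq == 1, WALK, IDLE))
        m = score_session(cues, trace)
        assert m.max_xcorr == pytest.approx(1.0)
        assert m.lag_at_max == 0.0
        assert m.omissions == 0 and m.false_alarms == 0
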