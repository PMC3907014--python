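"""Session scoring: lagged cue-vs-state cross-correlation, omissions,
false alarms, and multi-session aggregation.

Conventions: both the cue schedule and the decoded-state trace are sampled
on a shared 4 Hz clock; positive lag means the response lags the cue; a
false alarm is a WALK episode whose *onset* falls inside an Idle cue (its
duration runs to the episode end even across a cue boundary), while WALK
episodes spilling over from a Walk cue are not new false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import IDLE, WALK, CueSchedule
from gaitbci.online_decoder import STEP_S, StateTrace

CLOCK_HZ = 4.0


@dataclass
class SessionMetrics:
    """Per-session performance summary."""

    max_xcorr: float
    lag_at_max: float  # s, multiple of 0.25
    omissions: int
    false_alarms: int
    fa_durations: list[float] = field(default_factory=list)
    fa_duration_mean: float | None = None  # used when only a mean is known

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.max_xcorr <= 1.0 + 1e-9:
            raise ParameterError("max_xcorr must lie in [-1, 1]")
        if any(d <= 0 for d in self.fa_durations):
            raise ParameterError("false-alarm durations must be positive")
        if self.fa_duration_mean is None and self.fa_durations:
            self.fa_duration_mean = float(np.mean(self.fa_durations))


# ---------------------------------------------------------------------------
# binarization onto the shared clock
# ---------------------------------------------------------------------------


def binarize(obj, span: float | None = None, clock: float = CLOCK_HZ) -> np.ndarray:
    """0/1 sequence (WALK=1) sampled at ``clock`` Hz over the session span.

    Accepts a :class:`CueSchedule` (half-open cue intervals; gaps count as
    idle) or a :class:`StateTrace` (zero-order hold; IDLE before the first
    trace sample).  ``span`` defaults to the object's own extent.
    """
    step = 1.0 / clock
    if isinstance(obj, CueSchedule):
        span = obj.span if span is None else span
        n = int(round(span * clock))
        t = np.arange(n) * step
        out = np.zeros(n, dtype=int)
        for e in obj:
            if e.label == WALK:
                out[(t >= e.onset - 1e-9) & (t < e.end - 1e-9)] = 1
        return out
    if isinstance(obj, StateTrace):
        if obj.times.size == 0:
            return np.zeros(0 if span is None else int(round(span * clock)), dtype=int)
        span = float(obj.times[-1]) + step if span is None else span
        n = int(round(span * clock))
        t = np.arange(n) * step
        idx = np.searchsorted(obj.times, t + 1e-9) - 1
        out = np.zeros(n, dtype=int)
        valid = idx >= 0
        out[valid] = (obj.states[idx[valid]] == WALK).astype(int)
        return out
    raise ParameterError(f"cannot binarize object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------


def max_cross_correlation(
    cue_seq: np.ndarray,
    state_seq: np.ndarray,
    max_lag: float = 30.0,
    clock: float = CLOCK_HZ,
) -> tuple[float, float]:
    """Maximum Pearson correlation of the cue sequence against the state
    sequence delayed by 0, 0.25, ..., ``max_lag`` seconds.

    Only the overlapping region enters each correlation.  Returns (r, lag);
    lag ties resolve to the smallest lag.
    """
    cue_seq = np.asarray(cue_seq, dtype=np.float64)
    state_seq = np.asarray(state_seq, dtype=np.float64)
    if cue_seq.shape != state_seq.shape:
        raise ParameterError(
            f"sequence lengths differ: {cue_seq.size} vs {state_seq.size}"
        )
    if max_lag < 0:
        raise ParameterError("max_lag must be >= 0")
    for name, s in (("cue", cue_seq), ("state", state_seq)):
        if s.size and np.ptp(s) == 0:
            raise DegenerateDataError(
                f"{name} sequence is constant; correlation undefined"
            )
    n = cue_seq.size
    max_shift = int(round(max_lag * clock))
    best_r, best_lag = -np.inf, 0.0
    for shift in range(0, max_shift + 1):
        if n - shift < 2:
            break
        a = cue_seq[: n - shift]
        b = state_seq[shift:]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue  # degenerate overlap at this lag only
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r + 1e-12:
            best_r, best_lag = r, shift / clock
    if not np.isfinite(best_r):
        raise DegenerateDataError("no lag produced a defined correlation")
    return best_r, best_lag


def max_cross_correlation_many(
    cue_seq: np.ndarray,
    state_mat: np.ndarray,
    max_lag: float = 30.0,
    clock: float = CLOCK_HZ,
) -> np.ndarray:
    """Vectorized max cross-correlation of one cue sequence against each row
    of ``state_mat`` (trials x time).  Degenerate rows/lags yield r = -inf
    for that lag; an all-degenerate row yields nan."""
    cue_seq = np.asarray(cue_seq, dtype=np.float64)
    S = np.atleast_2d(np.asarray(state_mat, dtype=np.float64))
    n = cue_seq.size
    max_shift = int(round(max_lag * clock))
    best = np.full(S.shape[0], -np.inf)
    for shift in range(0, max_shift + 1):
        m = n - shift
        if m < 2:
            break
        a = cue_seq[:m]
        B = S[:, shift : shift + m]
        a_c = a - a.mean()
        B_c = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((a_c @ a_c) * np.einsum("ij,ij->i", B_c, B_c))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (B_c @ a_c) / denom
        r[~np.isfinite(r)] = -np.inf
        best = np.maximum(best, r)
    best[~np.isfinite(best)] = np.nan
    return best


# ---------------------------------------------------------------------------
# episode logic
# ---------------------------------------------------------------------------


def walk_episodes(trace: StateTrace) -> list[tuple[float, float]]:
    """Half-open (onset, end) intervals of contiguous WALK states.

    An episode still open at the end of the trace closes one clock step
    after its last sample."""
    if trace.times.size == 0:
        return []
    walk = trace.states == WALK
    episodes = []
    start = None
    for i in range(walk.size):
        if walk[i] and start is None:
            start = trace.times[i]
        elif not walk[i] and start is not None:
            episodes.append((float(start), float(trace.times[i])))
            start = None
    if start is not None:
        episodes.append((float(start), float(trace.times[-1]) + STEP_S))
    return episodes


def count_omissions(cues: CueSchedule, trace: StateTrace) -> int:
    """WALK cue intervals that never see a WALK state."""
    episodes = walk_episodes(trace)
    misses = 0
    for e in cues:
        if e.label != WALK:
            continue
        hit = any(on < e.end - 1e-9 and end > e.onset + 1e-9 for on, end in episodes)
        misses += 0 if hit else 1
    return misses


def detect_false_alarms(
    cues: CueSchedule, trace: StateTrace
) -> tuple[int, list[float]]:
    """WALK episodes whose onset lies inside an IDLE cue interval.

    The duration of a false alarm runs to the episode's end even when the
    episode crosses into a following Walk cue (attribution by onset)."""
    durations = []
    for on, end in walk_episodes(trace):
        if cues.label_at(on) == IDLE:
            durations.append(end - on)
    return len(durations), durations


def score_session(
    cues: CueSchedule, trace: StateTrace, max_lag: float = 30.0
) -> SessionMetrics:
    """All per-session metrics from a cue schedule and a decoded trace."""
    span = max(cues.span, float(trace.times[-1]) + STEP_S if trace.times.size else 0.0)
    r, lag = max_cross_correlation(
        binarize(cues, span), binarize(trace, span), max_lag
    )
    fa_count, fa_dur = detect_false_alarms(cues, trace)
    return SessionMetrics(
        max_xcorr=r,
        lag_at_max=lag,
        omissions=count_omissions(cues, trace),
        false_alarms=fa_count,
        fa_durations=fa_dur,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _summary(sessions: list[SessionMetrics]) -> dict:
    xc = np.array([s.max_xcorr for s in sessions])
    lags = np.array([s.lag_at_max for s in sessions])
    fa_counts = np.array([s.false_alarms for s in sessions])
    # pooled episode durations: explicit episodes when present, otherwise
    # session means weighted by episode counts
    dur_sum, dur_n, all_durs = 0.0, 0, []
    for s in sessions:
        if s.fa_durations:
            dur_sum += sum(s.fa_durations)
            dur_n += len(s.fa_durations)
            all_durs.extend(s.fa_durations)
        elif s.fa_duration_mean is not None and s.false_alarms > 0:
            dur_sum += s.fa_duration_mean * s.false_alarms
            dur_n += s.false_alarms
    sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return {
        "n_sessions": len(sessions),
        "xcorr_mean": float(xc.mean()),
        "xcorr_sd": sd(xc),
        "lag_mean_s": float(lags.mean()),
        "lag_sd_s": sd(lags),
        "omissions_total": int(sum(s.omissions for s in sessions)),
        "false_alarms_per_session": float(fa_counts.mean()),
        "fa_duration_mean_s": dur_sum / dur_n if dur_n else None,
        "fa_duration_sd_s": sd(np.array(all_durs)) if len(all_durs) > 1 else None,
        "fa_episodes": dur_n,
    }


def aggregate_sessions(
    sessions: list[SessionMetrics], groups: list | None = None
) -> dict:
    """Per-group and overall summary of session metrics.

    ``groups`` assigns each session a group key (e.g. a subject id); the
    result maps each key plus ``"overall"`` to a summary dict with mean/SD
    cross-correlation and lag, total omissions, mean false alarms per
    session, and the count-weighted pooled false-alarm duration.
    """
    if not sessions:
        raise ParameterError("no sessions to aggregate")
    out = {}
    if groups is not None:
        if len(groups) != len(sessions):
            raise ParameterError("groups must parallel sessions")
        for g in dict.fromkeys(groups):
            out[g] = _summary([s for s, gg in zip(sessions, groups) if gg == g])
    out["overall"] = _summary(sessions)
    return out
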