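"""Streaming decode: sliding windows, posterior averaging, dual-threshold
state machine, and threshold calibration.

Timing conventions: 0.75-s analysis windows emitted every 0.25 s, so the
trace clock runs at 4 Hz anchored at t = 0.75 s (the first full window).
The running posterior average spans 2 s (8 windows); during warm-up it
averages whatever is available so traces stay aligned with the cue clock.
The state machine starts in IDLE and transitions IDLE->WALK when the
averaged posterior strictly exceeds T_W, WALK->IDLE when it falls strictly
below T_I; otherwise it holds the current state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import IDLE, WALK, CueSchedule, EEGRecording
from gaitbci.prediction_model import PredictionModel

logger = logging.getLogger(__name__)

WINDOW_S = 0.75
STEP_S = 0.25
AVG_SPAN_S = 2.0


@dataclass
class PosteriorTrace:
    """4 Hz time series of instantaneous and 2-s-averaged walk posteriors."""

    times: np.ndarray  # s, step exactly 0.25
    P: np.ndarray  # instantaneous P(W|f*)
    P_bar: np.ndarray  # running average

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.P = np.asarray(self.P, dtype=np.float64)
        self.P_bar = np.asarray(self.P_bar, dtype=np.float64)
        for name, arr in (("P", self.P), ("P_bar", self.P_bar)):
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.times.size > 1 and not np.allclose(np.diff(self.times), STEP_S):
            raise ParameterError("trace time step must be exactly 0.25 s")


@dataclass
class StateTrace:
    """4 Hz decoded-state sequence with the thresholds that produced it."""

    times: np.ndarray
    states: np.ndarray  # of IDLE/WALK
    thresholds: tuple[float, float]  # (T_I, T_W)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.states = np.asarray(self.states)
        t_i, t_w = self.thresholds
        if t_i > t_w:
            raise ParameterError(f"need T_I <= T_W, got ({t_i}, {t_w})")

    def to_csv(self, path, posterior: PosteriorTrace | None = None) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "P", "P_bar", "state"])
            for i, t in enumerate(self.times):
                p = posterior.P[i] if posterior is not None else ""
                pb = posterior.P_bar[i] if posterior is not None else ""
                w.writerow([f"{t:.2f}", p, pb, self.states[i]])


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------


def n_sliding_windows(duration: float, win: float = WINDOW_S, step: float = STEP_S) -> int:
    if duration < win - 1e-9:
        return 0
    return int(np.floor((duration - win) / step + 1e-9)) + 1


def stream_windows(
    rec: EEGRecording, win: float = WINDOW_S, step: float = STEP_S
):
    """Yield (end_time, C x T segment) for overlapping windows [t-win, t)
    at t = win, win+step, ...  (times on the session clock)."""
    n = n_sliding_windows(rec.duration, win, step)
    if n == 0 and rec.duration > 0:
        logger.warning(
            "recording of %.2f s shorter than one %.2f-s window", rec.duration, win
        )
    n_win = int(round(win * rec.rate))
    hop = step * rec.rate
    for k in range(n):
        i0 = int(round(k * hop))
        t_end = rec.start_time + (i0 + n_win) / rec.rate
        yield t_end, rec.samples[:, i0 : i0 + n_win]


def stacked_windows(
    rec: EEGRecording, win: float = WINDOW_S, step: float = STEP_S
) -> tuple[np.ndarray, np.ndarray]:
    """All sliding windows stacked (n x C x T) plus their end times."""
    pairs = list(stream_windows(rec, win, step))
    if not pairs:
        n_win = int(round(win * rec.rate))
        return np.empty((0, rec.n_channels, n_win)), np.empty(0)
    times = np.array([t for t, _ in pairs])
    return np.stack([s for _, s in pairs]), times


# ---------------------------------------------------------------------------
# posterior averaging
# ---------------------------------------------------------------------------


def average_posterior(
    P: np.ndarray, span: float = AVG_SPAN_S, step: float = STEP_S
) -> np.ndarray:
    """Trailing moving average over ``span`` seconds (span/step samples).

    Warm-up entries average the values available so far, keeping the output
    aligned with the input times.
    """
    P = np.asarray(P, dtype=np.float64)
    w = max(1, int(round(span / step)))
    if P.size == 0:
        return P.copy()
    c = np.concatenate([[0.0], np.cumsum(P)])
    k = np.arange(1, P.size + 1)
    lo = np.maximum(0, k - w)
    # cumsum rounding can push the mean a few ulp outside [min, max]
    return np.clip((c[k] - c[lo]) / (k - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# dual-threshold state machine
# ---------------------------------------------------------------------------


def step_state(p_bar: float, current_state: str, t_i: float, t_w: float) -> str:
    """One transition of the binary state machine.

    IDLE -> WALK iff p_bar > T_W; WALK -> IDLE iff p_bar < T_I; otherwise
    the current state is kept (strict inequalities).
    """
    if t_i > t_w:
        raise ParameterError(f"need T_I <= T_W, got ({t_i}, {t_w})")
    if current_state == IDLE:
        return WALK if p_bar > t_w else IDLE
    return IDLE if p_bar < t_i else WALK


def run_state_machine(
    p_bar: np.ndarray, t_i: float, t_w: float, initial: str = IDLE
) -> np.ndarray:
    """Vectorized state machine over a P-bar sequence.

    The state after step k is WALK iff the most recent threshold-crossing
    event up to k was an upward crossing (p_bar > T_W), which is exactly the
    hysteresis dynamics of :func:`step_state`.
    """
    if t_i > t_w:
        raise ParameterError(f"need T_I <= T_W, got ({t_i}, {t_w})")
    p_bar = np.asarray(p_bar, dtype=np.float64)
    n = p_bar.size
    marks = np.zeros(n, dtype=np.int8)
    marks[p_bar > t_w] = 1
    marks[p_bar < t_i] = -1
    event_idx = np.where(marks != 0, np.arange(1, n + 1), 0)
    last_event = np.maximum.accumulate(event_idx)
    sign = np.zeros(n, dtype=np.int8)
    has = last_event > 0
    sign[has] = marks[last_event[has] - 1]
    walk = sign == 1
    if initial == WALK:
        walk[sign == 0] = True
    return np.where(walk, WALK, IDLE)


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    t_i: float
    t_w: float
    histogram: dict = field(default_factory=dict)  # per-class (counts, edges)
    crossed_fallback: bool = False


def calibrate_thresholds(
    p_bar: np.ndarray,
    labels: np.ndarray,
    idle_percentile: float = 95.0,
    walk_percentile: float = 5.0,
    n_bins: int = 50,
) -> CalibrationResult:
    """Propose (T_I, T_W) from the per-class averaged-posterior histogram.

    Default proposal: T_W = 95th percentile of the idle-class P-bar, T_I =
    5th percentile of the walk-class P-bar.  If the proposal is crossed
    (T_I > T_W) both collapse to the midpoint between the class medians,
    split by half the median gap.  The 50-bin class histograms are returned
    so a human can override the proposal.
    """
    p_bar = np.asarray(p_bar, dtype=np.float64)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if not {IDLE, WALK} <= present:
        raise DegenerateDataError(
            f"calibration data must contain both classes, got {sorted(present)}"
        )
    idle_p = p_bar[labels == IDLE]
    walk_p = p_bar[labels == WALK]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist = {
        IDLE: (np.histogram(idle_p, bins=edges)[0].tolist(), edges.tolist()),
        WALK: (np.histogram(walk_p, bins=edges)[0].tolist(), edges.tolist()),
    }
    t_w = float(np.percentile(idle_p, idle_percentile))
    t_i = float(np.percentile(walk_p, walk_percentile))
    crossed = t_i > t_w
    if crossed:
        mid = 0.5 * (float(np.median(idle_p)) + float(np.median(walk_p)))
        half_gap = 0.5 * abs(float(np.median(walk_p)) - float(np.median(idle_p)))
        t_i, t_w = mid - half_gap / 2, mid + half_gap / 2
        logger.warning(
            "crossed percentile thresholds; falling back to midpoint +/- half gap"
        )
    return CalibrationResult(t_i=t_i, t_w=t_w, histogram=hist, crossed_fallback=crossed)


# ---------------------------------------------------------------------------
# full online session
# ---------------------------------------------------------------------------


def run_online_session(
    rec: EEGRecording,
    model: PredictionModel,
    t_i: float,
    t_w: float,
    cues: CueSchedule | None = None,
) -> tuple[PosteriorTrace, StateTrace]:
    """Decode a whole session: sliding windows -> band-power features ->
    scalar feature -> walk posterior -> 2-s average -> state machine."""
    sub = rec.pick(model.retained_channels) if rec.n_samples else rec
    windows, times = stacked_windows(sub if rec.n_samples else rec)
    if windows.shape[0] == 0:
        empty = np.empty(0)
        return (
            PosteriorTrace(empty, empty, empty),
            StateTrace(empty, np.empty(0, dtype="<U4"), (t_i, t_w)),
        )
    P = model.posterior_from_windows(windows, rec.rate)
    P_bar = average_posterior(P)
    states = run_state_machine(P_bar, t_i, t_w, initial=IDLE)
    return (
        PosteriorTrace(times, P, P_bar),
        StateTrace(times, states, (t_i, t_w)),
    )
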