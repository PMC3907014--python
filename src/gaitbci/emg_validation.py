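"""Movement-control analysis: EMG preprocessing, gyroscope step
segmentation, per-step EMG power comparison across walking conditions, and
state/EMG/movement onset ordering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from gaitbci.errors import ParameterError
from gaitbci.io_signals import WALK
from gaitbci.online_decoder import StateTrace
from gaitbci.performance_metrics import walk_episodes

logger = logging.getLogger(__name__)

EMG_BAND = (40.0, 400.0)
MIN_STEP_INTERVAL = 0.4  # s


# ---------------------------------------------------------------------------
# EMG preprocessing
# ---------------------------------------------------------------------------


def preprocess_emg(
    raw: np.ndarray, rate: float, band=EMG_BAND, order: int = 4
) -> tuple[np.ndarray, dict]:
    """Zero-phase band-pass then full-wave rectification.

    Returns (rectified EMG, metadata describing the filter design)."""
    if band[1] >= rate / 2:
        raise ParameterError(
            f"band upper edge {band[1]} Hz must be below Nyquist {rate / 2}"
        )
    raw = np.asarray(raw, dtype=np.float64)
    sos = sps.butter(order, band, btype="bandpass", fs=rate, output="sos")
    filtered = sps.sosfiltfilt(sos, raw, axis=-1)
    meta = {
        "filter": "butterworth",
        "order": order,
        "band_hz": list(band),
        "zero_phase": True,
        "rectified": True,
    }
    return np.abs(filtered), meta


# ---------------------------------------------------------------------------
# step segmentation
# ---------------------------------------------------------------------------


@dataclass
class StepSegmentation:
    boundaries: np.ndarray  # s, strictly increasing
    stride_period: float | None  # s, None when < 2 boundaries

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=np.float64)
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise ParameterError("step boundaries must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return max(0, self.boundaries.size - 1)


def segment_steps(
    gyro: np.ndarray,
    rate: float,
    min_interval: float = MIN_STEP_INTERVAL,
    smooth_s: float = 0.1,
) -> StepSegmentation:
    """Step boundaries at the peaks of the smoothed angular-velocity trace.

    Peaks must be at least ``min_interval`` apart and rise meaningfully
    above the trace's spread; a flat trace yields zero steps."""
    gyro = np.asarray(gyro, dtype=np.float64)
    if gyro.size == 0:
        return StepSegmentation(np.empty(0), None)
    k = max(1, int(round(smooth_s * rate)))
    kernel = np.ones(k) / k
    smooth = np.convolve(gyro, kernel, mode="same")
    spread = np.std(smooth)
    if spread == 0:
        logger.warning("flat gyroscope trace: no steps found")
        return StepSegmentation(np.empty(0), None)
    peaks, _ = sps.find_peaks(
        smooth,
        distance=max(1, int(round(min_interval * rate))),
        prominence=1.0 * spread,
    )
    if peaks.size == 0:
        logger.warning("no step peaks found in gyroscope trace")
        return StepSegmentation(np.empty(0), None)
    boundaries = peaks / rate
    period = float(np.median(np.diff(boundaries))) if boundaries.size >= 2 else None
    return StepSegmentation(boundaries, period)


# ---------------------------------------------------------------------------
# per-step EMG power comparison
# ---------------------------------------------------------------------------


def step_log_powers(
    emg: np.ndarray, rate: float, seg: StepSegmentation, band=EMG_BAND
) -> np.ndarray:
    """Integrated band log-power of the (already preprocessed) EMG within
    each step interval.  Multichannel input is summed across channels."""
    emg = np.atleast_2d(np.asarray(emg, dtype=np.float64))
    out = []
    for t0, t1 in zip(seg.boundaries[:-1], seg.boundaries[1:]):
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        chunk = emg[:, i0:i1]
        if chunk.shape[1] < 8:
            continue
        freqs, psd = sps.periodogram(
            chunk, fs=rate, window="hamming", detrend="constant", axis=-1
        )
        mask = (freqs >= band[0]) & (freqs < band[1])
        power = float(psd[:, mask].sum() * (freqs[1] - freqs[0]))
        out.append(np.log(max(power, 1e-300)))
    return np.array(out)


@dataclass
class ConditionComparison:
    condition_a: str
    condition_b: str
    statistic: float
    p_value: float
    direction: str  # "a>b", "a<b", "a~b"
    n_a: int
    n_b: int


def emg_psd_compare(
    per_step_logpower: dict[str, np.ndarray],
    mean_psd: dict[str, np.ndarray] | None = None,
) -> list[ConditionComparison]:
    """Rank-sum comparison of per-step integrated log band power between
    every pair of conditions."""
    conds = list(per_step_logpower)
    out = []
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            xa, xb = per_step_logpower[a], per_step_logpower[b]
            if len(xa) < 2 or len(xb) < 2:
                raise ParameterError(
                    f"need >= 2 steps per condition ({a}: {len(xa)}, {b}: {len(xb)})"
                )
            stat, p = stats.ranksums(xa, xb)
            direction = "a~b" if p > 0.05 else ("a>b" if stat > 0 else "a<b")
            out.append(
                ConditionComparison(a, b, float(stat), float(p), direction,
                                    len(xa), len(xb))
            )
    return out


def mean_psd_curve(emg: np.ndarray, rate: float, seg: StepSegmentation):
    """Average per-step PSD on a common frequency grid (curve analog of the
    published per-condition spectra).  Steps are truncated to the shortest
    step so spectra share a grid."""
    emg = np.atleast_2d(np.asarray(emg, dtype=np.float64))
    lens = [
        int(round(t1 * rate)) - int(round(t0 * rate))
        for t0, t1 in zip(seg.boundaries[:-1], seg.boundaries[1:])
    ]
    lens = [n for n in lens if n >= 8]
    if not lens:
        return np.empty(0), np.empty(0)
    n = min(lens)
    psds = []
    for t0 in seg.boundaries[:-1]:
        i0 = int(round(t0 * rate))
        chunk = emg[:, i0 : i0 + n]
        if chunk.shape[1] < n:
            continue
        freqs, psd = sps.periodogram(
            chunk, fs=rate, window="hamming", detrend="constant", axis=-1
        )
        psds.append(psd.mean(axis=0))
    return freqs, np.mean(psds, axis=0)


# ---------------------------------------------------------------------------
# onset ordering
# ---------------------------------------------------------------------------


def _first_sustained_onset(
    x: np.ndarray, rate: float, t_start: float, baseline_until: float,
    sustain_s: float = 0.05,
) -> float | None:
    """First time >= t_start where |x| exceeds baseline mean + 3 SD for a
    sustained stretch; None when it never does (censored)."""
    x = np.asarray(x, dtype=np.float64)
    nb = int(round(baseline_until * rate))
    if nb < 2:
        nb = min(len(x), max(2, int(round(0.5 * rate))))
    base = np.abs(x[:nb])
    thresh = base.mean() + 3.0 * base.std()
    i0 = int(round(t_start * rate))
    above = np.abs(x[i0:]) > thresh
    k = max(1, int(round(sustain_s * rate)))
    if above.size < k:
        return None
    run = np.convolve(above.astype(float), np.ones(k), mode="valid")
    hits = np.flatnonzero(run >= k)
    if hits.size == 0:
        return None
    return (i0 + hits[0]) / rate


@dataclass
class OnsetReport:
    state_onset: float
    emg_onset: float | None  # None = censored (no activity found)
    gyro_onset: float | None
    emg_lead: float | None  # emg_onset - state_onset
    gyro_lead: float | None
    ok: bool


def onset_ordering(
    trace: StateTrace,
    gyro: np.ndarray,
    gyro_rate: float,
    emg: np.ndarray,
    emg_rate: float,
    baseline_s: float | None = None,
) -> list[OnsetReport]:
    """For each decoded WALK onset, locate the following EMG burst onset and
    gyro movement onset (baseline mean + 3 SD rule) and check that the
    state onset precedes both.  Onsets that never occur are censored and
    count as PASS for that modality."""
    emg = np.atleast_2d(np.asarray(emg, dtype=np.float64))
    reports = []
    episodes = walk_episodes(trace)
    # the baseline must predate any candidate movement, so it defaults to
    # the quiescent start of the recording, not the span up to the episode
    base_until = baseline_s if baseline_s is not None else 0.5
    for onset, _end in episodes:
        emg_on = _first_sustained_onset(emg.sum(axis=0), emg_rate, 0.0, base_until)
        gyro_on = _first_sustained_onset(gyro, gyro_rate, 0.0, base_until)
        # only activity at/after this episode's search context matters:
        # onsets before the state onset indicate movement preceding the
        # decoded state and flag a failure
        emg_lead = None if emg_on is None else emg_on - onset
        gyro_lead = None if gyro_on is None else gyro_on - onset
        ok = (emg_lead is None or emg_lead >= 0) and (
            gyro_lead is None or gyro_lead >= 0
        )
        reports.append(
            OnsetReport(onset, emg_on, gyro_on, emg_lead, gyro_lead, ok)
        )
    return reports
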