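"""Synthetic fixtures: cue-locked EEG with band-power modulation, online
sessions with a reaction delay, and gait-locked EMG/gyroscope traces.

The EEG generator superposes 1/f-shaped background noise (plus a white
floor) with a narrowband component on the modulated channels whose gain is
raised during WALK cues.  The walk gain is calibrated numerically so that
the single-window log band-power separation between classes equals the
requested effect size d'; because each window's band power is a quadratic
function of the gain, the calibration search costs almost nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from gaitbci.errors import ParameterError
from gaitbci.io_signals import (
    IDLE,
    WALK,
    CueEntry,
    CueSchedule,
    EEGRecording,
    make_bin_edges,
)

_WINDOW_S = 0.75


@dataclass
class SynthConfig:
    """Parameters of the synthetic EEG session generator."""

    n_channels: int = 16
    rate: float = 256.0
    modulated_channels: tuple[int, ...] = (2, 5, 8, 11)
    band: tuple[float, float] = (8.0, 12.0)
    effect_size: float = 2.0  # d' of single-window log band power
    noise_exponent: float = 1.0  # 1/f^exponent background
    white_floor: float = 0.2  # white noise amplitude relative to 1/f sigma
    # base narrowband amplitude; kept well below the broadband background so
    # walk-epoch gain changes barely move whole-channel variance/kurtosis
    nb_amplitude: float = 0.35
    artifact_channels: tuple[int, ...] = ()
    artifact_gain: float = 20.0
    reaction_delay: float = 1.0  # s, online sessions only
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("seed is mandatory for reproducible fixtures")
        if self.effect_size < 0:
            raise ParameterError("effect size d' must be >= 0")
        bad = [c for c in self.modulated_channels if not 0 <= c < self.n_channels]
        if bad:
            raise ParameterError(f"modulated channels out of range: {bad}")

    def provenance(self) -> dict:
        return {"generator": "gaitbci.synthetic_data", "config": asdict(self)}


def alternating_cues(
    epoch_s: float, n_epochs: int, first: str = IDLE
) -> CueSchedule:
    """n_epochs alternating equal-length cues starting with ``first``."""
    labels = [first if i % 2 == 0 else (WALK if first == IDLE else IDLE)
              for i in range(n_epochs)]
    return CueSchedule(
        [CueEntry(lab, i * epoch_s, epoch_s) for i, lab in enumerate(labels)]
    )


# ---------------------------------------------------------------------------
# noise + narrowband building blocks
# ---------------------------------------------------------------------------


def _one_over_f(rng, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent-shaped Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _narrowband(rng, n: int, rate: float, band) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


def _window_band_quadratics(
    bg: np.ndarray, nb: np.ndarray, rate: float, band, window_s: float
):
    """Per-window coefficients (A, B, C) of band power as a function of the
    narrowband gain g: P(g) = A + 2gB + g^2 C (windowed-FFT quadratic)."""
    n_win = int(round(window_s * rate))
    n = (bg.size // n_win) * n_win
    BG = bg[:n].reshape(-1, n_win)
    NB = nb[:n].reshape(-1, n_win)
    win = np.hamming(n_win)
    scale = 1.0 / (rate * (win**2).sum())
    F_bg = np.fft.rfft((BG - BG.mean(axis=1, keepdims=True)) * win, axis=1)
    F_nb = np.fft.rfft((NB - NB.mean(axis=1, keepdims=True)) * win, axis=1)
    freqs = np.fft.rfftfreq(n_win, 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs < band[1])
    # one-sided density doubling for interior bins, as in a periodogram
    mult = np.full(freqs.size, 2.0)
    mult[0] = 1.0
    if n_win % 2 == 0:
        mult[-1] = 1.0
    w = (mult * mask) * scale * (freqs[1] - freqs[0])
    A = np.sum(w * np.abs(F_bg) ** 2, axis=1)
    C = np.sum(w * np.abs(F_nb) ** 2, axis=1)
    Bq = np.sum(w * (F_bg * np.conj(F_nb)).real, axis=1)
    return A, Bq, C


def _dprime(idle_logp: np.ndarray, walk_logp: np.ndarray) -> float:
    pooled = np.sqrt(0.5 * (idle_logp.var(ddof=1) + walk_logp.var(ddof=1)))
    if pooled == 0:
        return 0.0
    return float((walk_logp.mean() - idle_logp.mean()) / pooled)


def measure_effect_size(
    rec: EEGRecording, cues: CueSchedule, channel: int, band,
    window_s: float = _WINDOW_S,
) -> float:
    """Single-window log band-power d' between WALK and IDLE windows of one
    channel (generator self-check oracle)."""
    from gaitbci.io_signals import band_power_matrix
    from gaitbci.prediction_model import training_windows

    windows, labels = training_windows(rec, cues, window_s)
    edges = make_bin_edges(band, band[1] - band[0])
    p = band_power_matrix(windows[:, channel : channel + 1, :], rec.rate, edges)
    logp = np.log(p.reshape(len(labels), -1).sum(axis=1))
    return _dprime(logp[labels == IDLE], logp[labels == WALK])


# ---------------------------------------------------------------------------
# EEG session generators
# ---------------------------------------------------------------------------


def _generate_session(
    cfg: SynthConfig, cues: CueSchedule, delay: float
) -> EEGRecording:
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cues.span * cfg.rate))
    t = np.arange(n) / cfg.rate
    n_win = int(round(_WINDOW_S * cfg.rate))

    # walk-gain indicator on the sample clock, shifted by the reaction delay
    walk_on = np.zeros(n, dtype=bool)
    for e in cues:
        if e.label == WALK:
            i0 = min(n, int(round((e.onset + delay) * cfg.rate)))
            i1 = min(n, int(round((e.end + delay) * cfg.rate)))
            walk_on[i0:i1] = True

    samples = np.empty((cfg.n_channels, n))
    base_gain = cfg.nb_amplitude
    # heterogeneous per-channel amplitudes and slow drifts, as on a real
    # cap.  Both are drawn from bounded evenly spaced grids (shuffled) so
    # the clean-channel population spreads log-variance and kurtosis wider
    # than the class modulation moves them, yet has no tail of its own that
    # the median/MAD artifact criterion would flag.  A common scale factor
    # multiplies signal and noise alike, so it cancels in d'.
    channel_scale = np.exp(np.linspace(-0.5, 0.5, cfg.n_channels))[
        rng.permutation(cfg.n_channels)
    ]
    # modulated channels take the shallowest drifts: deep drift inflates
    # their window log-power variance, which the d' calibration would have
    # to overcome with an outlier-sized walk gain
    depth_grid = np.linspace(0.15, 0.45, cfg.n_channels)
    drift_depth = np.empty(cfg.n_channels)
    mod = list(cfg.modulated_channels)
    rest = [c for c in range(cfg.n_channels) if c not in mod]
    drift_depth[mod] = depth_grid[: len(mod)]
    drift_depth[rest] = depth_grid[len(mod) :][rng.permutation(len(rest))]
    drift_period = rng.uniform(7.0, 13.0, size=cfg.n_channels)
    drift_phase = rng.uniform(0.0, 2 * np.pi, size=cfg.n_channels)
    for ch in range(cfg.n_channels):
        drift = 1.0 + drift_depth[ch] * np.sign(
            np.sin(2 * np.pi * t / drift_period[ch] + drift_phase[ch])
        )
        bg = _one_over_f(rng, n, cfg.noise_exponent) + cfg.white_floor * rng.standard_normal(n)
        bg = drift * bg
        if ch in cfg.modulated_channels and cfg.effect_size > 0:
            nb = drift * _narrowband(rng, n, cfg.rate, cfg.band)
            A, Bq, C = _window_band_quadratics(bg, nb, cfg.rate, cfg.band, _WINDOW_S)
            # window class labels on the non-overlapping window grid
            widx = (np.arange(A.size) * n_win + n_win // 2)
            is_walk = walk_on[np.minimum(widx, n - 1)]
            if is_walk.any() and (~is_walk).any():
                idle_logp = np.log(
                    np.maximum(A[~is_walk] + 2 * base_gain * Bq[~is_walk]
                               + base_gain**2 * C[~is_walk], 1e-30)
                )

                def dp(g):
                    walk_logp = np.log(
                        np.maximum(A[is_walk] + 2 * g * Bq[is_walk]
                                   + g**2 * C[is_walk], 1e-30)
                    )
                    return _dprime(idle_logp, walk_logp)

                lo_g, hi_g = base_gain, base_gain
                while dp(hi_g) < cfg.effect_size and hi_g < 1e4:
                    hi_g *= 2.0
                for _ in range(60):
                    mid = 0.5 * (lo_g + hi_g)
                    if dp(mid) < cfg.effect_size:
                        lo_g = mid
                    else:
                        hi_g = mid
                g_walk = 0.5 * (lo_g + hi_g)
            else:
                g_walk = base_gain
            gain = np.where(walk_on, g_walk, base_gain)
            x = bg + gain * nb
        else:
            # same-variance narrowband content, unmodulated
            nb = drift * _narrowband(rng, n, cfg.rate, cfg.band)
            x = bg + base_gain * nb
        x = channel_scale[ch] * x
        if ch in cfg.artifact_channels:
            x = x + cfg.artifact_gain * (
                rng.standard_normal(n)
                + 5.0 * np.sin(2 * np.pi * 1.3 * t + rng.uniform(0, 2 * np.pi))
            )
        samples[ch] = x

    names = [f"CH{ch:02d}" for ch in range(cfg.n_channels)]
    return EEGRecording(samples, cfg.rate, names)


def generate_training_session(cfg: SynthConfig) -> tuple[EEGRecording, CueSchedule]:
    """600-s recording with 20 alternating 30-s idle/walk cues; WALK epochs
    carry extra narrowband power on the modulated channels, calibrated to
    the requested single-window log band-power d'."""
    cues = alternating_cues(30.0, 20, first=IDLE)
    return _generate_session(cfg, cues, delay=0.0), cues


def generate_online_session(
    cfg: SynthConfig, epoch_s: float = 60.0, n_epochs: int = 10
) -> tuple[EEGRecording, CueSchedule]:
    """Alternating 1-min idle/walk session (600 s by default) whose
    modulation follows each cue switch after ``cfg.reaction_delay``."""
    cues = alternating_cues(epoch_s, n_epochs, first=IDLE)
    return _generate_session(cfg, cues, delay=cfg.reaction_delay), cues


def write_provenance(path, cfg: SynthConfig, extra: dict | None = None) -> None:
    doc = cfg.provenance()
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# EMG / gyroscope generator
# ---------------------------------------------------------------------------

EMG_RATE = 4000.0
GYRO_RATE = 100.0
CONDITIONS = ("active", "cooperative", "passive", "decoded")
# burst amplitude by condition: active > cooperative >> passive; passive
# stays nonzero (robot-driven movement still evokes some activity)
CONDITION_AMPLITUDE = {
    "active": 1.0,
    "cooperative": 0.5,
    "passive": 0.1,
    "decoded": 0.1,
}


@dataclass
class EMGGyroTraces:
    emg: np.ndarray  # 3 x n, a.u., at EMG_RATE
    emg_rate: float
    gyro: np.ndarray  # n_g, deg/s, at GYRO_RATE
    gyro_rate: float
    stride_period: float
    condition: str
    movement_onset: float | None = None  # s, when movement starts


def generate_emg_gyro(
    cfg: SynthConfig,
    condition: str,
    duration: float = 30.0,
    stride_period: float = 1.1,  # ~2 km/h
    movement_onset: float = 0.0,
    n_emg_channels: int = 3,
) -> EMGGyroTraces:
    """Periodic gait-locked gyro trace + EMG bursts phase-locked to it.

    EMG bursts are 40-400 Hz band noise under a raised-cosine envelope once
    per stride, scaled by the condition amplitude, on top of a small
    baseline noise floor.  The gyro is a smoothed stride-periodic angular
    velocity.  Everything is zero (noise floor only) before
    ``movement_onset``.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}")
    if duration < 0:
        raise ParameterError("duration must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    n_e = int(round(duration * EMG_RATE))
    n_g = int(round(duration * GYRO_RATE))
    t_e = np.arange(n_e) / EMG_RATE
    t_g = np.arange(n_g) / GYRO_RATE

    moving_g = t_g >= movement_onset
    phase_g = 2 * np.pi * (t_g - movement_onset) / stride_period
    gyro = np.where(
        moving_g,
        80.0 * np.sin(phase_g) + 25.0 * np.sin(2 * phase_g + 0.7),
        0.0,
    ) + 2.0 * rng.standard_normal(n_g)

    amp = CONDITION_AMPLITUDE[condition]
    phase_e = ((t_e - movement_onset) / stride_period) % 1.0
    envelope = np.where(
        (t_e >= movement_onset) & (phase_e < 0.3),
        0.5 * (1 - np.cos(2 * np.pi * phase_e / 0.3)),
        0.0,
    )
    emg = np.empty((n_emg_channels, n_e))
    if n_e:
        sos = sps.butter(4, (40.0, 400.0), btype="bandpass", fs=EMG_RATE, output="sos")
        for ch in range(n_emg_channels):
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(n_e))
            carrier /= max(carrier.std(), 1e-12)
            lag = 0.05 * ch  # muscles fire at slightly different phases
            env = np.roll(envelope, int(lag * EMG_RATE))
            emg[ch] = amp * env * carrier + 0.02 * rng.standard_normal(n_e)
    return EMGGyroTraces(
        emg=emg,
        emg_rate=EMG_RATE,
        gyro=gyro,
        gyro_rate=GYRO_RATE,
        stride_period=stride_period,
        condition=condition,
        movement_onset=movement_onset if duration > 0 else None,
    )
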