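"""Session-level significance control via a saturating autoregressive
surrogate for the posterior sequence.

The surrogate is X_{k+1} = alpha*X_k + beta*W_k with W_k ~ U(0,1),
X_0 ~ U(0,1), observed through the saturation Y_k = clip(X_k, 0, 1).
Fitting matches the lag-1 autocorrelation (alpha = rho) and the mean
(alpha*mu + beta/2 = mu, since E[W] = 1/2).  Monte-Carlo trials push
simulated posteriors through the same averaging and state machine as the
real session and compare cue-correlation maxima against the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import CueSchedule
from gaitbci.online_decoder import AVG_SPAN_S, STEP_S, average_posterior, run_state_machine
from gaitbci.performance_metrics import (
    CLOCK_HZ,
    binarize,
    max_cross_correlation_many,
)
from gaitbci.io_signals import WALK

logger = logging.getLogger(__name__)


@dataclass
class ARNullModel:
    """Fitted surrogate generator for one session's posterior sequence."""

    alpha: float  # AR coefficient (= lag-1 autocorrelation)
    beta: float  # noise gain
    mu: float  # stationary mean of the observed posteriors
    sigma2: float  # stationary variance (reported, unused in fitting)
    rho: float  # lag-1 autocorrelation
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.alpha < 1:
            raise ParameterError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if not 0 <= self.mu <= 1:
            raise ParameterError(f"mu must lie in [0, 1], got {self.mu}")


def fit_ar(P_seq: np.ndarray, seed: int | None = None) -> ARNullModel:
    """Fit (alpha, beta) to an observed posterior sequence.

    alpha is the lag-1 Pearson autocorrelation of the raw posteriors
    (clipped into [0, 1) with a warning if outside); beta = 2*mu*(1-alpha)
    matches the stationary mean given E[W] = 1/2.
    """
    P = np.asarray(P_seq, dtype=np.float64)
    if P.size < 10:
        raise ParameterError(f"need >= 10 posterior samples, got {P.size}")
    if P.min() < -1e-9 or P.max() > 1 + 1e-9:
        raise ParameterError("posteriors must lie in [0, 1]")
    if np.ptp(P) == 0:
        raise DegenerateDataError(
            "constant posterior sequence: lag-1 autocorrelation undefined"
        )
    mu = float(P.mean())
    sigma2 = float(P.var())
    rho = float(np.corrcoef(P[:-1], P[1:])[0, 1])
    alpha = rho
    if not 0 <= alpha < 1:
        clipped = min(max(alpha, 0.0), 1.0 - 1e-6)
        logger.warning("alpha = rho = %.4f outside [0, 1); clipping to %.4f", alpha, clipped)
        alpha = clipped
    beta = 2.0 * mu * (1.0 - alpha)
    return ARNullModel(alpha=alpha, beta=beta, mu=mu, sigma2=sigma2, rho=rho, seed=seed)


def simulate_null_posteriors(
    model: ARNullModel, n_steps: int, seed: int | None = None, n_trials: int = 1
) -> np.ndarray:
    """Simulate surrogate posterior sequences Y (n_trials x n_steps).

    Deterministic given ``seed`` (falls back to the model's stored seed).
    A single trial is returned as a flat length-n_steps array.
    """
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    X = rng.uniform(size=n_trials)
    W = rng.uniform(size=(n_trials, n_steps))
    Y = np.empty((n_trials, n_steps))
    for k in range(n_steps):
        Y[:, k] = np.clip(X, 0.0, 1.0)
        X = model.alpha * X + model.beta * W[:, k]
    return Y[0] if n_trials == 1 else Y


def null_max_correlations(
    model: ARNullModel,
    cues: CueSchedule,
    n_steps: int,
    thresholds: tuple[float, float],
    n_trials: int,
    seed: int,
    span: float = AVG_SPAN_S,
    max_lag: float = 30.0,
    trace_t0: float = 0.75,
) -> np.ndarray:
    """Max cue-correlation of each surrogate trial's decoded state sequence.

    Each trial's simulated posteriors pass through the same 2-s averaging
    and dual-threshold state machine as the real session; trials whose
    state sequence is constant (correlation undefined) carry nan.
    """
    t_i, t_w = thresholds
    Y = simulate_null_posteriors(model, n_steps, seed=seed, n_trials=n_trials)
    Y = np.atleast_2d(Y)
    cue_seq = binarize(cues)
    n_clock = cue_seq.size
    # state sequences start at trace_t0 on the 4 Hz session clock
    offset = int(round(trace_t0 * CLOCK_HZ))
    S = np.zeros((n_trials, n_clock))
    for i in range(n_trials):
        pb = average_posterior(Y[i], span=span, step=STEP_S)
        states = (run_state_machine(pb, t_i, t_w) == WALK).astype(float)
        m = min(n_clock - offset, states.size)
        if m > 0:
            S[i, offset : offset + m] = states[:m]
    return max_cross_correlation_many(cue_seq, S, max_lag=max_lag)


def empirical_pvalue(
    observed_max_xcorr: float,
    cues: CueSchedule,
    model: ARNullModel,
    n_steps: int,
    thresholds: tuple[float, float],
    n_trials: int = 10_000,
    seed: int = 0,
    span: float = AVG_SPAN_S,
    max_lag: float = 30.0,
) -> dict:
    """Empirical p-value: fraction of Monte-Carlo trials whose maximum
    cue correlation strictly exceeds the observed one.

    Returns a dict with ``p`` (floored at 1/n_trials when no trial
    exceeds), the raw exceedance count, and the null's own maximum.
    Trials with a constant (undefined-correlation) state sequence count as
    non-exceeding.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    r_null = null_max_correlations(
        model, cues, n_steps, thresholds, n_trials, seed, span=span, max_lag=max_lag
    )
    finite = r_null[np.isfinite(r_null)]
    exceed = int(np.sum(finite > observed_max_xcorr))
    p = exceed / n_trials
    return {
        "p": p,
        "p_floor": max(p, 1.0 / n_trials) if exceed == 0 else p,
        "exceedances": exceed,
        "n_trials": n_trials,
        "null_max": float(finite.max()) if finite.size else float("nan"),
        "degenerate_trials": int(n_trials - finite.size),
    }
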