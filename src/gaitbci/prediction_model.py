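"""Offline model training.

Pipeline: spectral band-power features -> per-class PCA subspaces with a
piecewise (minimum reconstruction error) assignment -> 1-D discriminant
(information-theoretic criterion, Fisher-LDA fallback) -> linear Bayesian
classifier on the scalar feature.  Includes stratified k-fold
cross-validation and greedy frequency-band optimization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from gaitbci.errors import DegenerateDataError, ParameterError
from gaitbci.io_signals import (
    IDLE,
    WALK,
    CueSchedule,
    EEGRecording,
    band_power_matrix,
    epoch_by_cues,
    exclude_artifact_channels,
    make_bin_edges,
)

CLASSES = (IDLE, WALK)

_BAND_FLOOR = 0.5
_BAND_CEIL = 40.0
_IMPROVE_TOL = 0.5  # percentage points


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Knobs for the offline training pipeline."""

    band: tuple[float, float] = (8.0, 12.0)
    bin_width: float = 2.0
    var_retained: float = 0.9
    discriminant: str = "aida"  # "aida" | "lda"
    priors: tuple[float, float] | None = None  # (P(I), P(W)); None = empirical
    variance_normalize: bool = False
    artifact_z: float = 3.0
    window_s: float = 0.75
    cv_folds: int = 10
    seed: int = 0
    optimize_band: bool = False


# ---------------------------------------------------------------------------
# classwise PCA
# ---------------------------------------------------------------------------


@dataclass
class CPCAMaps:
    """Per-class linear maps from the (centered) data space to an m-dim
    subspace, with a minimum-reconstruction-error piecewise assignment."""

    mean: np.ndarray  # global training mean, p
    scale: np.ndarray  # per-feature divisor (ones when normalization is off)
    bases: dict  # label -> p x m orthonormal-column basis (zero-padded)
    m: int

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Class index (0=IDLE, 1=WALK) whose subspace reconstructs each row
        of ``X`` best; ties break toward IDLE."""
        G = (np.atleast_2d(X) - self.mean) / self.scale
        errs = []
        for label in CLASSES:
            U = self.bases[label]
            resid = G - (G @ U) @ U.T
            errs.append(np.einsum("ij,ij->i", resid, resid))
        e = np.stack(errs, axis=1)
        # IDLE wins ties; the tolerance is relative to the datum's own
        # squared norm so that float noise on two exact (e.g. full-rank)
        # reconstructions cannot split the assignment
        tol = 1e-9 * (np.einsum("ij,ij->i", G, G) + 1e-30)
        return (e[:, 1] < e[:, 0] - tol).astype(int)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Piecewise projection: each row lands in its assigned class's
        subspace coordinates (n x m)."""
        X2 = np.atleast_2d(X)
        G = (X2 - self.mean) / self.scale
        which = self.assign(X2)
        Z = np.empty((X2.shape[0], self.m))
        for ci, label in enumerate(CLASSES):
            sel = which == ci
            if sel.any():
                Z[sel] = G[sel] @ self.bases[label]
        return Z

    def reconstruction_error(self, X: np.ndarray) -> np.ndarray:
        G = (np.atleast_2d(X) - self.mean) / self.scale
        which = self.assign(X)
        out = np.empty(G.shape[0])
        for ci, label in enumerate(CLASSES):
            sel = which == ci
            if sel.any():
                U = self.bases[label]
                resid = G[sel] - (G[sel] @ U) @ U.T
                out[sel] = np.sqrt(np.einsum("ij,ij->i", resid, resid))
        return out


def fit_cpca(
    X: np.ndarray,
    y: Sequence[str],
    var_retained: float = 0.9,
    variance_normalize: bool = False,
) -> CPCAMaps:
    """Fit per-class PCA subspaces on globally centered features.

    Each class keeps the smallest number of principal components explaining
    ``var_retained`` of its variance; both bases are then widened to the
    common dimension m (zero columns pad a rank-deficient class).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not 0 < var_retained <= 1:
        raise ParameterError(f"var_retained must be in (0, 1], got {var_retained}")
    for label in CLASSES:
        if (y == label).sum() < 2:
            raise ParameterError(f"need >= 2 windows of class {label}")
    mean = X.mean(axis=0)
    scale = np.ones(X.shape[1])
    if variance_normalize:
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
    G = (X - mean) / scale

    comps, dims = {}, {}
    for label in CLASSES:
        Gc = G[y == label]
        Gc = Gc - Gc.mean(axis=0)
        _, s, Vt = np.linalg.svd(Gc, full_matrices=False)
        var = s**2
        nonzero = var > var.sum() * 1e-12 if var.sum() > 0 else var > 0
        var = var[nonzero]
        Vt = Vt[nonzero]
        if var.size == 0:
            warnings.warn(
                f"class {label}: zero variance, rank-deficient subspace; "
                "var_retained unreachable",
                stacklevel=2,
            )
            comps[label], dims[label] = np.zeros((X.shape[1], 0)), 0
            continue
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, var_retained - 1e-12) + 1)
        k = min(k, var.size)
        if frac[k - 1] + 1e-12 < var_retained:
            warnings.warn(
                f"class {label}: rank supports only "
                f"{frac[k - 1]:.3f} of variance; retaining all components",
                stacklevel=2,
            )
        comps[label], dims[label] = Vt.T, k

    m = max(dims.values())
    if m == 0:
        raise DegenerateDataError("all classes have zero variance")
    bases = {}
    for label in CLASSES:
        U = comps[label][:, : min(m, comps[label].shape[1])]
        if U.shape[1] < m:
            U = np.hstack([U, np.zeros((U.shape[0], m - U.shape[1]))])
        bases[label] = U
    return CPCAMaps(mean=mean, scale=scale, bases=bases, m=m)


# ---------------------------------------------------------------------------
# 1-D discriminant
# ---------------------------------------------------------------------------


def _class_stats(Z: np.ndarray, y: np.ndarray):
    means, covs, priors = [], [], []
    for label in CLASSES:
        Zc = Z[y == label]
        means.append(Zc.mean(axis=0))
        covs.append(np.atleast_2d(np.cov(Zc, rowvar=False, bias=True)))
        priors.append(len(Zc) / len(Z))
    return np.array(means), covs, np.array(priors)


def information_objective(
    t: np.ndarray, means, covs, priors, total_cov
) -> float:
    """Gaussian-entropy approximation of the mutual information between the
    projected scalar feature and the class label (scale-invariant in t)."""
    t = np.asarray(t, dtype=np.float64)
    tot = float(t @ total_cov @ t)
    if tot <= 0:
        return -np.inf
    j = 0.5 * np.log(tot)
    for cov, p in zip(covs, priors):
        within = float(t @ cov @ t)
        if within <= 0:
            return -np.inf
        j -= 0.5 * p * np.log(within)
    return j


def _lda_direction(means, covs, priors) -> np.ndarray:
    sw = sum(p * c for p, c in zip(priors, covs))
    sw = sw + np.eye(sw.shape[0]) * (1e-12 * max(np.trace(sw), 1.0))
    return np.linalg.solve(sw, means[1] - means[0])


def fit_aida(
    Z: np.ndarray,
    y: Sequence[str],
    method: str = "aida",
) -> np.ndarray:
    """Unit-norm 1-D discriminant over the subspace features.

    ``method="aida"`` maximizes :func:`information_objective` numerically
    (initialized at the Fisher direction); ``method="lda"`` returns the
    Fisher direction itself.  In the equal-covariance two-Gaussian case the
    objective is monotone in the Rayleigh quotient, so both coincide.  The
    sign convention points the WALK mean to the positive side.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    y = np.asarray(y)
    means, covs, priors = _class_stats(Z, y)
    delta = means[1] - means[0]
    spread = np.sqrt(max(np.trace(sum(covs)), 1e-300))
    if np.linalg.norm(delta) <= 1e-9 * max(spread, 1e-9):
        raise DegenerateDataError("classes indistinguishable: zero between-class scatter")

    w0 = _lda_direction(means, covs, priors)
    if method == "lda":
        t = w0
    elif method == "aida":
        total = np.atleast_2d(np.cov(Z, rowvar=False, bias=True))
        # tiny ridge keeps the log-determinants finite on degenerate folds
        ridge = np.eye(Z.shape[1]) * (1e-10 * max(np.trace(total), 1.0))
        covs = [c + ridge for c in covs]
        total = total + ridge

        def neg(t):
            return -information_objective(t, means, covs, priors, total)

        res = minimize(neg, w0 / np.linalg.norm(w0), method="Nelder-Mead"
                       if Z.shape[1] == 1 else "BFGS")
        t = res.x if np.isfinite(neg(res.x)) and neg(res.x) <= neg(w0) else w0
    else:
        raise ParameterError(f"unknown discriminant method {method!r}")

    t = t / np.linalg.norm(t)
    if float(t @ delta) < 0:
        t = -t
    return t


# ---------------------------------------------------------------------------
# Bayesian classifier on the scalar feature
# ---------------------------------------------------------------------------


@dataclass
class BayesParams:
    """Per-class univariate Gaussian + priors for the scalar feature."""

    means: tuple[float, float]  # (IDLE, WALK)
    variances: tuple[float, float]
    priors: tuple[float, float]

    def __post_init__(self):
        if not all(v > 0 for v in self.variances):
            raise DegenerateDataError("per-class feature variance must be positive")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ParameterError("priors must sum to 1")


def fit_bayes(
    f: np.ndarray, y: Sequence[str], priors: tuple[float, float] | None = None
) -> BayesParams:
    """Per-class Gaussian fit of the scalar feature; empirical priors by
    default."""
    f = np.asarray(f, dtype=np.float64).ravel()
    y = np.asarray(y)
    means, variances, counts = [], [], []
    for label in CLASSES:
        fc = f[y == label]
        if fc.size < 2:
            raise ParameterError(f"need >= 2 features of class {label}")
        means.append(float(fc.mean()))
        v = float(fc.var(ddof=1))
        variances.append(max(v, 1e-12 * max(float(f.var()), 1e-12)))
        counts.append(fc.size)
    if priors is None:
        priors = (counts[0] / f.size, counts[1] / f.size)
    return BayesParams(tuple(means), tuple(variances), tuple(priors))


def _log_joint(f, params: BayesParams) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    out = np.empty(f.shape + (2,))
    for i in range(2):
        mu, var, p = params.means[i], params.variances[i], params.priors[i]
        out[..., i] = (
            np.log(p) - 0.5 * np.log(2 * np.pi * var) - (f - mu) ** 2 / (2 * var)
        )
    return out

def posterior_walk(f, params: BayesParams):
    """P(WALK | f) by Bayes rule on the per-class Gaussians."""
    lj = _log_joint(f, params)
    return np.exp(lj[..., 1] - logsumexp(lj, axis=-1))


def classify(f, params: BayesParams):
    """IDLE iff P(IDLE|f) > P(WALK|f); ties go to WALK."""
    lj = _log_joint(np.asarray(f, dtype=np.float64), params)
    labels = np.where(lj[..., 0] > lj[..., 1], IDLE, WALK)
    return labels if labels.ndim else labels.item()


# ---------------------------------------------------------------------------
# fitted pipeline + serializable model
# ---------------------------------------------------------------------------


@dataclass
class FittedPipeline:
    cpca: CPCAMaps
    t: np.ndarray  # unit-norm 1-D discriminant, m
    bayes: BayesParams

    def feature(self, X: np.ndarray) -> np.ndarray:
        return self.cpca.transform(X) @ self.t

    def predict(self, X: np.ndarray) -> np.ndarray:
        return classify(self.feature(X), self.bayes)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        return posterior_walk(self.feature(X), self.bayes)


def fit_pipeline(X: np.ndarray, y, config: ModelConfig) -> FittedPipeline:
    """CPCA -> discriminant -> Bayes on an n x p feature matrix."""
    cpca = fit_cpca(
        X, y, config.var_retained, variance_normalize=config.variance_normalize
    )
    Z = cpca.transform(X)
    t = fit_aida(Z, y, method=config.discriminant)
    f = Z @ t
    bayes = fit_bayes(f, y, priors=config.priors)
    return FittedPipeline(cpca, t, bayes)


@dataclass
class PredictionModel:
    """Everything needed to decode online: retained channels, frequency
    band, the piecewise subspace maps, the 1-D discriminant, and the
    Bayesian classifier parameters."""

    band: tuple[float, float]
    bin_edges: np.ndarray
    retained_channels: list[str]
    pipeline: FittedPipeline
    config: ModelConfig = field(default_factory=ModelConfig)
    cv_report: "CVReport | None" = None

    VERSION = 1

    def feature_vector(self, values_bxc: np.ndarray) -> np.ndarray:
        return np.asarray(values_bxc).reshape(np.asarray(values_bxc).shape[0], -1) \
            if np.asarray(values_bxc).ndim == 3 else np.asarray(values_bxc).ravel()[None, :]

    def posterior_from_windows(self, windows_nct: np.ndarray, rate: float) -> np.ndarray:
        """P(WALK|f*) for stacked raw windows (n x C x T)."""
        feats = band_power_matrix(windows_nct, rate, self.bin_edges)
        X = feats.reshape(feats.shape[0], -1)
        return self.pipeline.posterior(X)

    def salience_map(self) -> dict:
        """Per-class |t . U_c| rendered over bins x channels (feature
        extraction map analog)."""
        B = len(self.bin_edges) - 1
        C = len(self.retained_channels)
        out = {}
        for label in CLASSES:
            w = np.abs(self.pipeline.cpca.bases[label] @ self.pipeline.t)
            amax = w.max()
            out[label] = (w / amax if amax > 0 else w).reshape(B, C)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format_version": self.VERSION,
            "band": list(self.band),
            "bin_edges": self.bin_edges.tolist(),
            "retained_channels": self.retained_channels,
            "cpca": {
                "mean": self.pipeline.cpca.mean.tolist(),
                "scale": self.pipeline.cpca.scale.tolist(),
                "m": self.pipeline.cpca.m,
                "bases": {
                    k: v.tolist() for k, v in self.pipeline.cpca.bases.items()
                },
            },
            "discriminant": self.pipeline.t.tolist(),
            "bayes": asdict(self.pipeline.bayes),
            "config": asdict(self.config),
            "cv_report": asdict(self.cv_report) if self.cv_report else None,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "PredictionModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != cls.VERSION:
            raise ParameterError(
                f"model bundle version {doc.get('format_version')} unsupported"
            )
        cpca = CPCAMaps(
            mean=np.array(doc["cpca"]["mean"]),
            scale=np.array(doc["cpca"]["scale"]),
            bases={k: np.array(v) for k, v in doc["cpca"]["bases"].items()},
            m=doc["cpca"]["m"],
        )
        bayes = BayesParams(
            tuple(doc["bayes"]["means"]),
            tuple(doc["bayes"]["variances"]),
            tuple(doc["bayes"]["priors"]),
        )
        cfg_d = doc["config"]
        cfg_d["band"] = tuple(cfg_d["band"])
        if cfg_d.get("priors"):
            cfg_d["priors"] = tuple(cfg_d["priors"])
        config = ModelConfig(**cfg_d)
        cvr = CVReport(**doc["cv_report"]) if doc.get("cv_report") else None
        return cls(
            band=tuple(doc["band"]),
            bin_edges=np.array(doc["bin_edges"]),
            retained_channels=doc["retained_channels"],
            pipeline=FittedPipeline(cpca, np.array(doc["discriminant"]), bayes),
            config=config,
            cv_report=cvr,
        )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    fold_accuracies: list[float]  # percent
    mean_accuracy: float
    sd_accuracy: float
    confusion: list[list[int]]  # rows true (I, W), cols predicted
    seed: int


def stratified_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Index sets of k folds whose class proportions match the full data
    within one sample."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def crossvalidate(
    X: np.ndarray, y, config: ModelConfig | None = None, k: int | None = None,
    seed: int | None = None,
) -> CVReport:
    """Stratified k-fold CV of the full pipeline on an n x p feature matrix.

    The pipeline (CPCA, discriminant, classifier) is refit from scratch on
    each training split.
    """
    config = config or ModelConfig()
    k = k or config.cv_folds
    seed = config.seed if seed is None else seed
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    folds = stratified_folds(y, k, seed)
    accs = []
    confusion = np.zeros((2, 2), dtype=int)
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        pipe = fit_pipeline(X[mask], y[mask], config)
        pred = np.atleast_1d(pipe.predict(X[test_idx]))
        truth = y[test_idx]
        accs.append(100.0 * float(np.mean(pred == truth)))
        for ti, tl in enumerate(CLASSES):
            for pi, pl in enumerate(CLASSES):
                confusion[ti, pi] += int(np.sum((truth == tl) & (pred == pl)))
    accs_arr = np.array(accs)
    return CVReport(
        fold_accuracies=[float(a) for a in accs],
        mean_accuracy=float(accs_arr.mean()),
        sd_accuracy=float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
        confusion=confusion.tolist(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training windows + band optimization
# ---------------------------------------------------------------------------


def training_windows(
    rec: EEGRecording, cues: CueSchedule, window_s: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Cut cue epochs into consecutive non-overlapping windows.

    Returns (windows n x C x T, labels n)."""
    n_win = int(round(window_s * rec.rate))
    segs, labels = [], []
    for label, ep in epoch_by_cues(rec, cues):
        n = ep.n_samples // n_win
        for i in range(n):
            segs.append(ep.samples[:, i * n_win : (i + 1) * n_win])
            labels.append(label)
    if not segs:
        return np.empty((0, rec.n_channels, n_win)), np.empty(0, dtype="<U4")
    return np.stack(segs), np.array(labels)


def windows_to_features(
    windows_nct: np.ndarray, rate: float, band, bin_width: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened band-power feature matrix (n x B*C) + bin edges."""
    edges = make_bin_edges(band, bin_width)
    feats = band_power_matrix(windows_nct, rate, edges)
    return feats.reshape(feats.shape[0], -1), edges


def optimize_band(
    windows_nct: np.ndarray,
    labels,
    rate: float,
    config: ModelConfig | None = None,
    seed_band: tuple[float, float] | None = None,
) -> tuple[tuple[float, float], CVReport]:
    """Greedy 2-Hz-grid expansion of the frequency band.

    Starting from ``seed_band``, repeatedly extend the bound (lower, down to
    a 0.5 Hz floor; upper, up to 40 Hz) whose extension most improves mean
    CV accuracy; stop when neither improves by more than 0.5 percentage
    points.  Folds are fixed across candidate bands for comparability.
    """
    config = config or ModelConfig()
    lo, hi = seed_band or config.band
    if hi - lo < config.bin_width - 1e-9:
        raise ParameterError(
            f"seed band [{lo}, {hi}) holds less than one {config.bin_width}-Hz bin"
        )
    if hi > rate / 2:
        raise ParameterError(f"band upper edge {hi} Hz exceeds Nyquist {rate / 2}")

    def cv_at(band):
        X, _ = windows_to_features(windows_nct, rate, band, config.bin_width)
        return crossvalidate(X, labels, config)

    best = cv_at((lo, hi))
    while True:
        candidates = []
        new_lo = max(_BAND_FLOOR, lo - config.bin_width)
        if new_lo < lo - 1e-9:
            candidates.append((new_lo, hi))
        new_hi = min(_BAND_CEIL, min(hi + config.bin_width, rate / 2))
        if new_hi > hi + 1e-9:
            candidates.append((lo, new_hi))
        if not candidates:
            break
        reports = [cv_at(b) for b in candidates]
        gains = [r.mean_accuracy - best.mean_accuracy for r in reports]
        j = int(np.argmax(gains))
        if gains[j] <= _IMPROVE_TOL:
            break
        (lo, hi), best = candidates[j], reports[j]
    return (lo, hi), best


# ---------------------------------------------------------------------------
# one-call offline training
# ---------------------------------------------------------------------------


def extract_feature(d: np.ndarray, model: PredictionModel | FittedPipeline) -> float:
    """Scalar feature f = t . Phi_C(d) for one flattened data vector."""
    pipe = model.pipeline if isinstance(model, PredictionModel) else model
    return float(pipe.feature(np.asarray(d, dtype=np.float64).ravel()[None, :])[0])


def train_model(
    rec: EEGRecording, cues: CueSchedule, config: ModelConfig | None = None
) -> PredictionModel:
    """Full offline training: artifact-channel exclusion, cue epoching,
    windowing, optional band search, pipeline fit, and CV report."""
    config = config or ModelConfig()
    retained = exclude_artifact_channels(rec, config.artifact_z)
    sub = rec.pick(retained)
    windows, labels = training_windows(sub, cues, config.window_s)
    if config.optimize_band:
        band, report = optimize_band(windows, labels, sub.rate, config)
    else:
        band = config.band
        X0, _ = windows_to_features(windows, sub.rate, band, config.bin_width)
        report = crossvalidate(X0, labels, config)
    X, edges = windows_to_features(windows, sub.rate, band, config.bin_width)
    pipe = fit_pipeline(X, labels, config)
    return PredictionModel(
        band=band,
        bin_edges=edges,
        retained_channels=retained,
        pipeline=pipe,
        config=config,
        cv_report=report,
    )
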