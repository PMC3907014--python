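"""Data model, file I/O, cue-locked epoching, and PSD feature extraction.

The on-disk formats are plain EDF (see :mod:`gaitbci.edf`) and a delimited
numeric matrix: first header row = channel names, one column per channel,
one row per sample, tab-separated, with the sampling rate supplied either
directly or via a sidecar key-value config (YAML/JSON with a ``rate_hz``
key).  Cue schedules are CSV (``label,onset_s,duration_s``) or JSON.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import signal as sps
from scipy import stats

from gaitbci import edf as edfmod
from gaitbci.errors import FormatError, ParameterError, RangeError

logger = logging.getLogger(__name__)

IDLE = "IDLE"
WALK = "WALK"
LABELS = (IDLE, WALK)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """Multichannel time series (channels x time, µV) with channel names."""

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise FormatError(f"rate must be positive, got {self.rate}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channel rows"
            )
        self.channel_names = [str(c) for c in self.channel_names]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate

    def pick(self, names: Sequence[str]) -> "EEGRecording":
        """Sub-recording restricted to ``names`` (kept in the given order)."""
        idx = [self.channel_names.index(n) for n in names]
        return EEGRecording(
            self.samples[idx], self.rate, [self.channel_names[i] for i in idx],
            self.start_time,
        )

    def slice_seconds(self, t0: float, t1: float) -> "EEGRecording":
        """Sample-accurate half-open slice [t0, t1) on the session clock."""
        i0 = int(round((t0 - self.start_time) * self.rate))
        i1 = int(round((t1 - self.start_time) * self.rate))
        if i0 < 0 or i1 > self.n_samples:
            raise RangeError(
                f"slice [{t0}, {t1}) s falls outside the recording "
                f"[{self.start_time}, {self.start_time + self.duration}) s"
            )
        return EEGRecording(
            self.samples[:, i0:i1], self.rate, list(self.channel_names), t0
        )


@dataclass(frozen=True)
class CueEntry:
    label: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class CueSchedule:
    """Ordered, non-overlapping labeled intervals over a session timeline."""

    entries: list[CueEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries = [
            e if isinstance(e, CueEntry) else CueEntry(*e) for e in self.entries
        ]
        for e in self.entries:
            if e.label not in LABELS:
                raise FormatError(f"cue label {e.label!r} not in {LABELS}")
            if e.duration <= 0:
                raise FormatError(f"cue at {e.onset}s has non-positive duration")
        onsets = [e.onset for e in self.entries]
        if onsets != sorted(onsets):
            raise FormatError("cue entries are not sorted by onset")
        for a, b in zip(self.entries, self.entries[1:]):
            if b.onset < a.end - 1e-9:
                raise FormatError(
                    f"cues overlap: [{a.onset},{a.end}) and [{b.onset},{b.end})"
                )
            if b.label == a.label:
                warnings.warn("cue labels do not alternate", stacklevel=2)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def span(self) -> float:
        """End time of the last cue (0 for an empty schedule)."""
        return self.entries[-1].end if self.entries else 0.0

    def label_at(self, t: float) -> str | None:
        for e in self.entries:
            if e.onset <= t < e.end:
                return e.label
        return None

    # -- persistence --------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "CueSchedule":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    CueEntry(
                        row["label"].strip().upper(),
                        float(row["onset_s"]),
                        float(row["duration_s"]),
                    )
                )
        return cls(entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "onset_s", "duration_s"])
            for e in self.entries:
                w.writerow([e.label, repr(e.onset), repr(e.duration)])

    @classmethod
    def from_json(cls, path) -> "CueSchedule":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            [CueEntry(d["label"], d["onset_s"], d["duration_s"]) for d in data]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"label": e.label, "onset_s": e.onset, "duration_s": e.duration}
                    for e in self.entries
                ],
                fh,
                indent=1,
            )


@dataclass
class SpectralFeatures:
    """Integrated band power per frequency bin and channel for one window."""

    values: np.ndarray  # B x C, non-negative
    bin_edges: np.ndarray  # Hz, length B+1, strictly increasing
    channel_names: list[str]
    window_onset: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise FormatError("bin_edges must be strictly increasing")
        if self.values.shape != (len(self.bin_edges) - 1, len(self.channel_names)):
            raise FormatError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.bin_edges) - 1} bins x {len(self.channel_names)} channels"
            )
        if np.any(self.values < 0):
            raise FormatError("integrated power must be non-negative")

    def flatten(self) -> np.ndarray:
        """B*C feature vector (bin-major)."""
        return self.values.ravel()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        return config
    text = Path(config).read_text()
    if str(config).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def read_recording(path, format=None, rate=None, config=None) -> EEGRecording:
    """Load an :class:`EEGRecording` from EDF or a delimited matrix.

    ``format`` is ``"edf"`` or ``"tsv"``; inferred from the extension when
    omitted.  For delimited matrices the rate comes from ``rate`` or the
    ``rate_hz`` key of ``config`` (dict or path to a YAML/JSON sidecar).
    ``config`` may also set ``nan_policy`` to ``"reject"`` (default) or
    ``"impute"`` (per-channel linear interpolation).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording file: {path}")
    cfg = _load_config(config)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("tsv", "txt", "csv", "delimited", "delimited-matrix"):
        rate = rate if rate is not None else cfg.get("rate_hz")
        if rate is None:
            raise FormatError(
                f"{path}: delimited matrix needs a sampling rate "
                "(rate argument or 'rate_hz' config key)"
            )
        delim = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            names = header.split(delim)
            try:
                mat = np.loadtxt(fh, delimiter=delim, ndmin=2)
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable numeric body: {exc}") from exc
        if mat.size and mat.shape[1] != len(names):
            raise FormatError(
                f"{path}: header names {len(names)} channels but rows have "
                f"{mat.shape[1]} columns"
            )
        samples = mat.T if mat.size else np.empty((len(names), 0))
    elif fmt == "edf":
        samples, rate, names = edfmod.read_edf(path)
    else:
        raise FormatError(f"unknown recording format {fmt!r} for {path}")

    if np.isnan(samples).any():
        policy = cfg.get("nan_policy", "reject")
        if policy == "impute":
            for row in samples:
                bad = np.isnan(row)
                if bad.all():
                    raise FormatError(f"{path}: channel of all NaN cannot be imputed")
                row[bad] = np.interp(
                    np.flatnonzero(bad), np.flatnonzero(~bad), row[~bad]
                )
        else:
            raise FormatError(
                f"{path}: NaN samples present and nan_policy is 'reject'"
            )
    return EEGRecording(samples, float(rate), list(names))


def write_recording(rec: EEGRecording, path, format=None) -> None:
    """Write a recording as EDF or a tab-delimited matrix with header row."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        edfmod.write_edf(path, rec.samples, rec.rate, rec.channel_names)
    elif fmt in ("tsv", "txt"):
        with open(path, "w") as fh:
            fh.write("\t".join(rec.channel_names) + "\n")
            np.savetxt(fh, rec.samples.T, delimiter="\t", fmt="%.10g")
    else:
        raise FormatError(f"unknown recording format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# artifact-channel exclusion
# ---------------------------------------------------------------------------


def _robust_z(x: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); zero-MAD deviations map to ±inf."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    dev = x - med
    if mad == 0:
        with np.errstate(invalid="ignore"):
            return np.where(dev == 0, 0.0, np.inf * np.sign(dev))
    return dev / (1.4826 * mad)


def exclude_artifact_channels(rec: EEGRecording, z_thresh: float = 3.0) -> list[str]:
    """Channels whose robust z of log-variance and of kurtosis stay below
    ``z_thresh``.

    High-variance or high-kurtosis outliers (relative to the channel
    population, median/MAD scaled) are flagged as artifact-contaminated.
    Deterministic; at least one channel is always retained.
    """
    if z_thresh <= 0:
        raise ParameterError(f"z_thresh must be positive, got {z_thresh}")
    if rec.n_channels == 1:
        logger.warning("single-channel recording: retaining the only channel")
        return list(rec.channel_names)
    var = rec.samples.var(axis=1)
    logvar = np.log(np.maximum(var, np.finfo(float).tiny))
    kurt = stats.kurtosis(rec.samples, axis=1, fisher=True, bias=True)
    keep = (_robust_z(logvar) < z_thresh) & (_robust_z(kurt) < z_thresh)
    if not keep.any():
        raise ParameterError(
            "all channels excluded as artifactual; raise z_thresh or inspect data"
        )
    return [n for n, k in zip(rec.channel_names, keep) if k]


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def epoch_by_cues(
    rec: EEGRecording, cues: CueSchedule
) -> list[tuple[str, EEGRecording]]:
    """One sample-accurate half-open slice per cue entry, labels attached."""
    out = []
    for i, e in enumerate(cues):
        try:
            out.append((e.label, rec.slice_seconds(e.onset, e.end)))
        except RangeError as exc:
            raise RangeError(f"cue #{i} ({e.label} @ {e.onset}s): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# PSD features
# ---------------------------------------------------------------------------


def make_bin_edges(band, bin_width: float = 2.0) -> np.ndarray:
    """Half-open [lo, hi) bin edges of width ``bin_width`` covering ``band``.

    The first bin may be narrower when ``band[0]`` is not on the grid
    (e.g. a 0.5 Hz floor)."""
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise ParameterError(f"band must satisfy F_L < F_H, got [{lo}, {hi})")
    first = np.ceil(lo / bin_width) * bin_width
    if first <= lo:
        first = lo + bin_width
    inner = np.arange(first, hi, bin_width)
    edges = np.concatenate([[lo], inner, [hi]])
    return np.unique(edges)


def band_power_matrix(
    x: np.ndarray, rate: float, bin_edges: np.ndarray
) -> np.ndarray:
    """Integrated band power for stacked segments.

    ``x`` has time on the last axis; a single detrended Hamming-windowed
    periodogram per segment is integrated over half-open frequency bins.
    Returns an array shaped like ``x`` without the time axis plus a leading
    bin axis moved to position -2: for a (C, T) input the result is (B, C);
    for (N, C, T) it is (N, B, C).
    """
    x = np.asarray(x, dtype=np.float64)
    freqs, psd = sps.periodogram(
        x, fs=rate, window="hamming", detrend="constant", scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    bins = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (freqs >= lo) & (freqs < hi)
        bins.append(psd[..., mask].sum(axis=-1) * df)
    out = np.stack(bins, axis=-1)  # (..., C, B)
    return np.swapaxes(out, -1, -2)  # (..., B, C)


def compute_psd_features(
    segment: EEGRecording, band=(8.0, 12.0), bin_width: float = 2.0
) -> SpectralFeatures:
    """Periodogram band power of one segment, integrated over 2-Hz bins.

    Uses a single detrended Hamming-windowed periodogram (segments are too
    short for Welch averaging) and half-open [lo, hi) bins covering
    ``band``.
    """
    nyquist = segment.rate / 2.0
    if band[1] > nyquist + 1e-9:
        raise ParameterError(
            f"band upper edge {band[1]} Hz exceeds Nyquist {nyquist} Hz"
        )
    edges = make_bin_edges(band, bin_width)
    values = band_power_matrix(segment.samples, segment.rate, edges)
    return SpectralFeatures(
        values, edges, list(segment.channel_names), segment.start_time
    )
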