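"""Minimal EDF (European Data Format) reader/writer.

Supports the plain-EDF subset this package needs: a common sampling rate for
all signals, 1-second data records, 16-bit little-endian samples with linear
physical scaling.  Recordings whose length is not a whole number of seconds
are zero-padded on write; the true sample count is stored in the reserved
header field so a round-trip is exact.
"""

from __future__ import annotations

import math

import numpy as np

from gaitbci.errors import FormatError

_HDR = 256  # fixed header bytes
_SIG_HDR = 256  # per-signal header bytes

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, samples: np.ndarray, rate: float, channel_names) -> None:
    """Write ``samples`` (channels x time, physical units) as plain EDF."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise FormatError("samples must be a 2-D channels x time matrix")
    n_ch, n_t = samples.shape
    if len(channel_names) != n_ch:
        raise FormatError(
            f"channel_names has {len(channel_names)} entries for {n_ch} rows"
        )
    if rate <= 0 or abs(rate - round(rate)) > 1e-9:
        raise FormatError(f"EDF writer requires a positive integer rate, got {rate}")
    spr = int(round(rate))  # samples per 1-s record
    n_rec = max(1, math.ceil(n_t / spr)) if n_t else 0

    phys_min = samples.min(axis=1) if n_t else np.zeros(n_ch)
    phys_max = samples.max(axis=1) if n_t else np.ones(n_ch)
    # avoid a zero physical span (flat channel)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field(f"Startdate X nsamples={n_t}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HDR + _SIG_HDR * n_ch), 8),
            _field("EDF", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b""
    for block, width in (
        (channel_names, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV" for _ in range(n_ch)], 8),
        ([f"{v:.8g}"[:8] for v in phys_min], 8),
        ([f"{v:.8g}"[:8] for v in phys_max], 8),
        ([str(_DIG_MIN)] * n_ch, 8),
        ([str(_DIG_MAX)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([str(spr)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ):
        sig += b"".join(_field(v, width) for v in block)

    # re-read the physical extrema exactly as the 8-char header will store them
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_t] = samples
    dig = np.round((padded - pmin[:, None]) / gain[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path):
    """Read a plain EDF file.

    Returns ``(samples, rate, channel_names)`` with samples in physical
    units (channels x time).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise FormatError(f"{path}: truncated EDF header")
    try:
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        n_ch = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable EDF header field: {exc}") from exc
    recording_id = raw[88:168].decode("ascii", "replace")

    off = _HDR
    total_sig = _SIG_HDR * n_ch
    if len(raw) < off + total_sig:
        raise FormatError(f"{path}: truncated EDF signal headers")

    def block(width):
        nonlocal off
        out = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(n_ch)
        ]
        off += width * n_ch
        return out

    labels = block(16)
    block(80)  # transducer
    block(8)  # dimension
    pmin = np.array([float(v) for v in block(8)])
    pmax = np.array([float(v) for v in block(8)])
    dmin = np.array([float(v) for v in block(8)])
    dmax = np.array([float(v) for v in block(8)])
    block(80)  # prefilter
    spr = [int(v) for v in block(8)]
    block(32)  # reserved

    if len(set(spr)) != 1:
        raise FormatError(f"{path}: signals have differing sampling rates {set(spr)}")
    spr = spr[0]
    rate = spr / rec_dur

    data = np.frombuffer(raw, dtype="<i2", offset=off)
    expected = n_rec * n_ch * spr
    if data.size < expected:
        raise FormatError(
            f"{path}: data section holds {data.size} samples, header claims {expected}"
        )
    data = data[:expected].reshape(n_rec, n_ch, spr)
    samples = np.concatenate([data[r] for r in range(n_rec)], axis=1).astype(np.float64)

    gain = (pmax - pmin) / (dmax - dmin)
    samples = (samples - dmin[:, None]) * gain[:, None] + pmin[:, None]

    # recover the true (pre-padding) sample count if this writer produced it
    if "nsamples=" in recording_id:
        try:
            n_t = int(recording_id.split("nsamples=")[1].split()[0])
            samples = samples[:, :n_t]
        except ValueError:
            pass
    return samples, rate, labels
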