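"""Minimal single-channel EDF (European Data Format) reader and writer.

EDF stores signals as 16-bit integers with a per-signal linear mapping
between the digital range and a physical range declared in the header, so a
write/read round trip is exact up to one quantization step of that range.

Only what the pipeline needs is implemented: one signal per file, one
continuous recording. The writer picks an integral record duration ``d``
(seconds) such that ``d * fs`` is an integer, which makes the sampling rate
recoverable exactly as ``samples_per_record / d``. The last data record is
zero-padded; the true sample count is stored in the recording-identification
header field (``NSAMP=<n>``) so this reader can trim the padding. Foreign
EDF readers see a valid file with trailing zeros in the final record.
"""

from __future__ import annotations

import math
import os
import struct

import numpy as np

from .exceptions import CorruptSignal, PpgIoError

_DIGITAL_MAX = 32767
_DIGITAL_MIN = -32767  # symmetric so that 0.0 maps to digital 0


def _fit_record_duration(fs: float, max_d: int = 100) -> int:
    """Smallest integer duration d (s) with d*fs integral, else raise."""
    for d in range(1, max_d + 1):
        if abs(d * fs - round(d * fs)) < 1e-6 * fs:
            return d
    raise PpgIoError(
        f"sampling rate {fs} Hz has no integral record duration <= {max_d} s; "
        "write the record as CSV instead"
    )


def _phys_limit(x: np.ndarray) -> float:
    """Symmetric physical range: |x| max rounded UP to 2 significant digits.

    Two significant digits always fit the 8-character EDF header field (worst
    case ``-1.3e-05``), so the declared range round-trips exactly through the
    header and the quantization bound range/2**15 holds.
    """
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak == 0.0 or not math.isfinite(peak):
        return 1.0
    exp = math.floor(math.log10(peak))
    scale = 10.0 ** (exp - 1)
    return math.ceil(peak / scale) * scale


def _field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise PpgIoError(f"EDF header field {value!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | os.PathLike, samples: np.ndarray, fs: float,
              label: str = "PPG", patient_id: str = "X") -> str:
    """Write one channel to *path*; returns the path written."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise PpgIoError("EDF writer needs a non-empty 1-D signal")
    if not np.all(np.isfinite(x)):
        raise CorruptSignal("non-finite samples cannot be written to EDF")

    d = _fit_record_duration(fs)
    spr = round(d * fs)
    n_records = math.ceil(x.size / spr)
    phys_max = _phys_limit(x)
    gain = _DIGITAL_MAX / phys_max
    padded = np.zeros(n_records * spr)
    padded[: x.size] = x
    digital = np.clip(np.round(padded * gain), _DIGITAL_MIN, _DIGITAL_MAX)
    digital = digital.astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field(patient_id[:80], 80),
        _field(f"NSAMP={x.size}", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * 2, 8),              # header bytes: fixed + 1 signal
        _field("", 44),
        _field(n_records, 8),
        _field(d, 8),
        _field(1, 4),
        # per-signal fields
        _field(label[:16], 16),
        _field("", 80),
        _field("au", 8),
        _field(f"{-phys_max:.2g}", 8),
        _field(f"{phys_max:.2g}", 8),
        _field(_DIGITAL_MIN, 8),
        _field(_DIGITAL_MAX, 8),
        _field("", 80),
        _field(spr, 8),
        _field("", 32),
    ])
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(digital.tobytes())
    except OSError as exc:
        raise PpgIoError(f"cannot write EDF to {path}: {exc}") from exc
    return os.fspath(path)


def read_edf(path: str | os.PathLike, channel: int | str = 0):
    """Read one channel; returns (samples, fs, channel_label)."""
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise PpgIoError(f"cannot read EDF {path}: {exc}") from exc
    if len(raw) < 256:
        raise PpgIoError(f"{path}: truncated EDF header")

    def ascii_at(off, width):
        return raw[off: off + width].decode("ascii", "replace").strip()

    recording_id = ascii_at(88, 80)
    n_records = int(ascii_at(236, 8))
    duration = float(ascii_at(244, 8))
    n_signals = int(ascii_at(252, 4))
    if n_signals < 1:
        raise PpgIoError(f"{path}: EDF file declares no signals")

    def sig_fields(off, width):
        base = 256 + off * n_signals
        return [ascii_at(base + i * width, width) for i in range(n_signals)]

    labels = sig_fields(0, 16)
    phys_min = [float(v) for v in sig_fields(16 + 80 + 8, 8)]
    phys_max = [float(v) for v in sig_fields(16 + 80 + 8 + 8, 8)]
    dig_min = [int(v) for v in sig_fields(16 + 80 + 8 + 16, 8)]
    dig_max = [int(v) for v in sig_fields(16 + 80 + 8 + 24, 8)]
    spr = [int(v) for v in sig_fields(16 + 80 + 8 + 32 + 80, 8)]

    if isinstance(channel, str):
        from .exceptions import ChannelNotFound
        if channel not in labels:
            raise ChannelNotFound(
                f"{path}: channel {channel!r} not in {labels}")
        ch = labels.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < n_signals:
            from .exceptions import ChannelNotFound
            raise ChannelNotFound(f"{path}: channel index {ch} out of range")

    header_bytes = 256 + 256 * n_signals
    rec_words = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes,
                         count=n_records * rec_words)
    data = data.reshape(n_records, rec_words)
    start = sum(spr[:ch])
    digital = data[:, start: start + spr[ch]].reshape(-1).astype(float)

    scale = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
    samples = phys_min[ch] + (digital - dig_min[ch]) * scale
    fs = spr[ch] / duration

    if recording_id.startswith("NSAMP="):
        n_true = int(recording_id.split("=", 1)[1])
        samples = samples[:n_true]
    return samples, fs, labels[ch]
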