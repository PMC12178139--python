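"""Minimal 16-bit EDF writer.

Writes a plain (continuous) European Data Format file: one fixed-width
ASCII header block plus little-endian 16-bit integer data records.  Only
the subset of the format needed to round-trip multichannel EEG through
``mne.io.read_raw_edf`` is produced: identical sampling rate on every
channel, one-second data records, symmetric physical scaling per channel.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["write_edf", "edf_quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value of one digital unit for a 16-bit EDF channel."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(path, data: np.ndarray, fs: float, channel_names,
              patient_id: str = "X", recording_id: str = "X") -> None:
    """Write ``data`` (channels x samples, physical units) as 16-bit EDF.

    The total number of samples must be an integer multiple of ``fs``
    (whole one-second records); ``fs`` must itself be a positive integer.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    if fs <= 0 or fs != int(fs):
        raise ValueError("fs must be a positive integer for EDF export")
    fs = int(fs)
    if n_samp % fs:
        raise ValueError("sample count must be a whole number of seconds")
    n_rec = n_samp // fs

    # symmetric physical range per channel; degenerate flat channels get +-1
    absmax = np.abs(data).max(axis=1)
    absmax[absmax == 0] = 1.0
    phys_min, phys_max = -absmax, absmax
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),           # record duration, seconds
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),       # transducer
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(n_ch)),
        b"".join(_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(n_ch)),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),       # prefiltering
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    # phys_min printed with 8 chars loses precision; recompute scaling from
    # the *printed* values so reader and writer agree exactly
    pmin = np.array([float(f"{phys_min[i]:.8g}"[:8]) for i in range(n_ch)])
    pmax = np.array([float(f"{phys_max[i]:.8g}"[:8]) for i in range(n_ch)])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)

    digital = np.rint((data - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]   # channel-major record
            fh.write(block.tobytes())
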