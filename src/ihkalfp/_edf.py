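"""Minimal EDF (European Data Format) writing, plus an MNE-backed reader.

Writing supports the plain 16-bit EDF variant with one-second data records,
which is sufficient for round-tripping LFP sessions: integer sampling rate,
all channels at the same rate, physical dimension microvolts. Reading is
delegated to :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["write_edf", "read_edf", "edf_quantization_step"]

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # Fit a number into a fixed-width ASCII field, trimming precision as needed.
    for fmt in (f"{{:.{p}g}}" for p in range(10, 0, -1)):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise FormatError(f"cannot encode {value} in {width} ASCII bytes")


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical amplitude represented by one digital unit."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    fs: float,
    channel_ids: list[str],
    units: str = "uV",
) -> Path:
    """Write ``samples`` (n_channels x n_samples) to a plain EDF file.

    Requires an integer sampling rate and a whole number of seconds of data
    (EDF stores fixed-duration data records; this writer uses 1 s records).
    """
    path = Path(path)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise FormatError("samples must be a 2-D (channels x samples) array")
    n_ch, n_samp = samples.shape
    if n_samp == 0:
        raise FormatError("cannot write an empty recording to EDF")
    spr = int(round(fs))
    if spr <= 0 or abs(fs - spr) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    if n_samp % spr != 0:
        raise FormatError(
            f"EDF writer requires whole seconds of data: {n_samp} samples at {spr} Hz"
        )
    n_rec = n_samp // spr

    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for c in range(n_ch):
        amp = float(np.max(np.abs(samples[c]))) if n_samp else 0.0
        amp = math.ceil(amp) if amp > 0 else 1.0
        phys_min[c], phys_max[c] = -amp, amp
        scale = edf_quantization_step(-amp, amp)
        digital[c] = np.clip(
            np.round(samples[c] / scale), _DIG_MIN, _DIG_MAX
        ).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field("X", 80),
            _field("X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(cid, 16) for cid in channel_ids),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(units, 8) for _ in range(n_ch)),
            b"".join(_num(phys_min[c], 8) for c in range(n_ch)),
            b"".join(_num(phys_max[c], 8) for c in range(n_ch)),
            b"".join(_num(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_num(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-major layout: per record, one contiguous block per channel
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (samples in uV, fs, channel ids)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # MNE converts recognized physical dimensions to SI (volts); LFP channels
    # are reported back in microvolts, the package-wide amplitude unit.
    samples = raw.get_data() * 1e6
    return samples, float(raw.info["sfreq"]), list(raw.ch_names)
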