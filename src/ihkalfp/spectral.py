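"""Banded spectral power (sliding Hanning-window FFT) and the coastline.

Band power uses a 10 s Hann-tapered periodogram slid along the signal
(default step 1 s). Powers are in microvolts squared with the standard
window-power correction, so that for a stationary signal the sum over the
full spectrum matches the signal's mean-square amplitude (Parseval, up to
taper leakage). Band edges are half-open ``[low, high)``: a bin on a shared
edge counts toward the upper band only.

The coastline (line length) is the sum of absolute first differences, an
aggregate amplitude-frequency measure commonly used in seizure detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "BandPowerSeries",
    "band_power",
    "mean_band_power",
    "coastline",
]


class Band(NamedTuple):
    name: str
    low_hz: float
    high_hz: float


#: rodent-standard scheme: delta, theta, alpha, beta, gamma
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 80.0),
)


def _validate_scheme(scheme: tuple[Band, ...]) -> None:
    prev_high = -np.inf
    for band in scheme:
        if band.low_hz >= band.high_hz:
            raise ParameterError(f"band {band.name}: low >= high")
        if band.low_hz < prev_high:
            raise ParameterError(f"band {band.name} overlaps its predecessor")
        prev_high = band.high_hz


@dataclass
class BandPowerSeries:
    """Per-window band powers (uV^2) on a sliding-window grid."""

    window_centers_s: np.ndarray
    powers: dict[str, np.ndarray]
    window_s: float
    step_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_center_s": self.window_centers_s, **self.powers}
        )


def band_power(
    x: np.ndarray,
    fs: float,
    scheme: tuple[Band, ...] = DEFAULT_BANDS,
    window_s: float = 10.0,
    step_s: float = 1.0,
    start_time: float = 0.0,
) -> BandPowerSeries:
    """Sliding Hann-window FFT band power.

    Windows start at the first sample and advance by ``step_s``; the number
    of windows is ``floor((T - window_s)/step_s) + 1``. Per window, the
    Hann-tapered periodogram is integrated over the bins of each band
    (half-open edges). Requires ``fs >= 2 x`` the highest band edge and at
    least one full window of signal.
    """
    _validate_scheme(scheme)
    x = np.asarray(x, dtype=float)
    top = max(b.high_hz for b in scheme)
    if fs < 2 * top:
        raise ParameterError(f"fs={fs} below 2x the top band edge ({top} Hz)")
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    if nwin < 2 or nstep < 1:
        raise ParameterError("window_s and step_s too small for this fs")
    if x.size < nwin:
        raise InsufficientDataError(
            f"signal ({x.size / fs:.2f} s) shorter than the {window_s} s window"
        )
    n_windows = (x.size - nwin) // nstep + 1

    taper = np.hanning(nwin)
    # density normalization: sum(psd) * df == mean square of the tapered
    # segment corrected by the window power
    norm = 1.0 / (fs * np.sum(taper**2))
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    df = fs / nwin

    band_bins = {
        band.name: (band.low_hz <= freqs) & (freqs < band.high_hz)
        for band in scheme
    }
    powers = {band.name: np.empty(n_windows) for band in scheme}

    chunk = max(1, int(2**26 // max(nwin, 1)))  # bound peak memory
    starts = np.arange(n_windows) * nstep
    for lo in range(0, n_windows, chunk):
        idx = starts[lo : lo + chunk]
        segs = x[idx[:, None] + np.arange(nwin)] * taper
        spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2 * norm
        spec[:, 1:] *= 2.0
        if nwin % 2 == 0:
            spec[:, -1] /= 2.0
        for name, mask in band_bins.items():
            powers[name][lo : lo + len(idx)] = spec[:, mask].sum(axis=1) * df

    centers = start_time + starts / fs + window_s / 2.0
    return BandPowerSeries(
        window_centers_s=centers, powers=powers, window_s=window_s, step_s=step_s
    )


def mean_band_power(
    series: BandPowerSeries, window: tuple[float, float]
) -> dict[str, float]:
    """Mean band power over sliding windows centered inside ``[t0, t1)``."""
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError(f"window end {t1} must exceed start {t0}")
    mask = (series.window_centers_s >= t0) & (series.window_centers_s < t1)
    if not mask.any():
        raise InsufficientDataError(
            f"no sliding windows centered in [{t0}, {t1})"
        )
    return {name: float(values[mask].mean()) for name, values in series.powers.items()}


def coastline(
    x: np.ndarray, fs: float | None = None, window: tuple[float, float] | None = None
) -> float:
    """Sum of absolute differences between successive samples (uV).

    With ``window`` given (seconds, half-open), only samples inside the
    window are used; ``fs`` is then required. At least two samples must
    remain.
    """
    x = np.asarray(x, dtype=float)
    if window is not None:
        if fs is None:
            raise ParameterError("fs is required when windowing the coastline")
        t0, t1 = window
        i0 = max(0, int(np.ceil(t0 * fs)))
        i1 = min(x.size, int(np.ceil(t1 * fs)))
        x = x[i0:i1]
    if x.size < 2:
        raise InsufficientDataError("coastline needs at least 2 samples")
    # exactly rounded sum, so the result is independent of summation order
    return math.fsum(np.abs(np.diff(x)))
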