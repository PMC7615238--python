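"""Bandpass filtering, spike-polarity detection and the mode baseline.

The detector's adaptive amplitude threshold is anchored to the *mode* of the
per-second signal extrema: the recording is cut into complete 1 s intervals,
the extremum of each interval is taken (maximum or minimum depending on
spike polarity), and the most frequent value — after quantization, since the
mode of a continuous variable requires binning — becomes the baseline
amplitude. Epileptiform spikes are then defined relative to this mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ParameterError
from .io import Recording

__all__ = [
    "FilterSpec",
    "BaselineStats",
    "design_sos",
    "filter_signal",
    "bandpass_filter",
    "filter_response",
    "detect_polarity",
    "per_second_extrema",
    "compute_baseline",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (defaults: 0.5–70 Hz, 2nd order).

    ``zero_phase=False`` applies the filter forward-only (causal, matching
    on-line acquisition); ``True`` applies it forward–backward for zero
    phase distortion at the cost of non-causality.
    """

    low_hz: float = 0.5
    high_hz: float = 70.0
    order: int = 2
    zero_phase: bool = False
    design: str = "butterworth"

    def validate(self, fs: float) -> None:
        if self.design != "butterworth":
            raise ParameterError(f"unsupported filter design {self.design!r}")
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
            )
        if self.high_hz >= fs / 2:
            raise ParameterError(
                f"high_hz={self.high_hz} must be below the Nyquist rate {fs / 2}"
            )
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    return sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs,
        output="sos",
    )


def filter_signal(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Bandpass one channel; same length as the input."""
    sos = design_sos(spec, fs)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Bandpass all channels of a recording; metadata is preserved."""
    filtered = np.vstack(
        [filter_signal(recording.samples[i], recording.fs, spec)
         for i in range(recording.n_channels)]
    )
    return Recording(
        filtered, recording.fs, list(recording.channel_ids),
        recording.start_time, recording.units,
    )


def filter_response(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Analytic magnitude response |H(f)| of the designed filter.

    For ``zero_phase=True`` the effective response is |H|^2 (the filter is
    applied twice).
    """
    sos = design_sos(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def _samples_per_second(fs: float) -> int:
    spp = int(round(fs))
    if spp <= 0:
        raise ParameterError(f"sampling rate must be positive, got {fs}")
    return spp


def per_second_extrema(x: np.ndarray, fs: float, polarity: str) -> np.ndarray:
    """Extremum of each complete 1 s interval, folded to the spike polarity.

    Positive polarity takes per-second maxima; negative polarity takes the
    negated per-second minima, so spike-ward deflections are positive in the
    returned series either way. A trailing partial second is dropped.
    """
    x = np.asarray(x, dtype=float)
    spp = _samples_per_second(fs)
    n_sec = x.size // spp
    if n_sec == 0:
        return np.empty(0)
    chunks = x[: n_sec * spp].reshape(n_sec, spp)
    if polarity == "positive":
        return chunks.max(axis=1)
    if polarity == "negative":
        return -chunks.min(axis=1)
    raise ParameterError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def detect_polarity(x: np.ndarray, fs: float) -> str:
    """Determine epileptiform spike polarity from per-second extrema.

    Returns "positive" when the mean per-second maximum exceeds the mean
    absolute per-second minimum, else "negative" (ties break to "negative").
    Requires at least 10 s of signal.
    """
    x = np.asarray(x, dtype=float)
    spp = _samples_per_second(fs)
    if x.size < 10 * spp:
        raise InsufficientDataError(
            f"polarity detection needs >= 10 s of signal, got {x.size / fs:.2f} s"
        )
    up = per_second_extrema(x, fs, "positive")
    down = per_second_extrema(x, fs, "negative")
    return "positive" if up.mean() > down.mean() else "negative"


@dataclass(frozen=True)
class BaselineStats:
    """Per-second extrema and their quantized mode (the threshold anchor)."""

    extrema: np.ndarray = field(repr=False)
    polarity: str = "negative"
    mode_value: float = 0.0
    quantization_step: float = 1.0

    def scaled(self, c: float) -> "BaselineStats":
        return replace(
            self,
            extrema=self.extrema * c,
            mode_value=self.mode_value * c,
            quantization_step=self.quantization_step * c,
        )


def compute_baseline(
    x: np.ndarray,
    fs: float,
    polarity: str = "negative",
    quantization_step: float = 1.0,
) -> BaselineStats:
    """Mode of the quantized per-second extrema.

    Extrema are quantized to the nearest multiple of ``quantization_step``
    (bins centered on the multiples, half-up at the midpoint); the mode is
    the center of the most populated bin. Tied bins resolve to the smallest
    amplitude (the conservative choice: a lower detection threshold). At
    least 3 complete 1 s intervals are required; >= 60 s is recommended for
    a stable mode.
    """
    if quantization_step <= 0:
        raise ParameterError("quantization_step must be positive")
    extrema = per_second_extrema(x, fs, polarity)
    if extrema.size < 3:
        raise InsufficientDataError(
            f"baseline needs >= 3 complete 1 s intervals, got {extrema.size}"
        )
    bins = np.floor(extrema / quantization_step + 0.5).astype(np.int64)
    values, counts = np.unique(bins, return_counts=True)
    tied = values[counts == counts.max()]
    mode_value = tied.min() * quantization_step
    return BaselineStats(
        extrema=extrema,
        polarity=polarity,
        mode_value=float(mode_value),
        quantization_step=float(quantization_step),
    )
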