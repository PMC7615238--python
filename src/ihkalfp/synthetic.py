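"""Seeded synthetic LFP sessions with ground-truth epileptiform events.

No public recordings exist for the chronic IHKA model sessions this package
quantifies, so this module generates statistically matched stand-ins: a
1/f-type background at a few hundred Hz sampling, biphasic epileptiform
spikes well above the 2x-mode detection threshold, spike trains and HPDs
whose counts, durations and inter-spike intervals bracket the 1 s and 10 s
class boundaries, and a per-epoch multiplicative modulation of event rates
emulating a treatment effect. The generator emits both the rendered
recording and the exact event schedule, so every pipeline stage can be
scored against ground truth.

Default rates follow the pre-treatment activity reported for chronic IHKA
mice (roughly 55 spike trains/h and 9 HPDs/h, cumulative durations of order
140 and 160 s/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .events import SpikeEvent, TrainClass
from .io import Recording, empty_annotations
from .pipeline import EpochScheme
from .preprocessing import compute_baseline

__all__ = [
    "SimConfig",
    "PlannedTrain",
    "EventSchedule",
    "make_background",
    "make_schedule",
    "render_session",
    "simulate_session",
    "reference_baseline",
    "spike_template",
    "score_detection",
    "cohort_configs",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    The session timeline places the injection at ``injection_time_s``
    (``None`` simulates a single uninterrupted segment at pre-treatment
    rates). ``rate_multipliers`` scale both train classes per epoch,
    emulating a multiplicative treatment effect on event rates.
    ``background_sigma_uV = 0`` renders events on a silent background for
    detector-oracle work; spike amplitudes are then referenced to
    ``reference_mode_uV`` instead of the empirical background mode.
    """

    fs: float = 500.0
    duration_s: float = 6000.0
    injection_time_s: float | None = 3900.0
    background_exponent: float = 1.0
    background_sigma_uV: float = 50.0
    reference_mode_uV: float = 50.0
    spike_width_ms: float = 40.0
    polarity: str = "negative"
    amplitude_factor_range: tuple[float, float] = (3.0, 6.0)
    spiketrain_rate_per_h: float = 55.0
    hpd_rate_per_h: float = 9.0
    rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "pre": 1.0, "excluded": 1.0, "post_early": 1.0, "post_late": 1.0
        }
    )
    spiketrain_duration_range: tuple[float, float] = (1.2, 4.0)
    hpd_duration_range: tuple[float, float] = (10.5, 25.0)
    isi_range_s: tuple[float, float] = (0.15, 0.50)
    min_gap_s: float = 2.0
    channel_id: str = "CA1"
    epochs: EpochScheme = field(default_factory=EpochScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 160:
            raise ParameterError("fs must be >= 160 Hz (gamma band Nyquist)")
        if self.background_sigma_uV < 0:
            raise ParameterError("background_sigma_uV must be >= 0")
        if any(m < 0 for m in self.rate_multipliers.values()):
            raise ParameterError("rate multipliers must be >= 0")
        if self.polarity not in {"positive", "negative"}:
            raise ParameterError("polarity must be 'positive' or 'negative'")
        lo, hi = self.spiketrain_duration_range
        if not (1.0 <= lo < hi < 10.0):
            raise ParameterError("spike-train durations must lie within [1, 10) s")
        lo, hi = self.hpd_duration_range
        if not (10.0 <= lo < hi):
            raise ParameterError("HPD durations must be >= 10 s")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class PlannedTrain:
    """Ground truth for one planned train."""

    spike_times_s: np.ndarray = field(repr=False)
    amplitude_factor: float
    intended_class: TrainClass

    @property
    def onset_s(self) -> float:
        return float(self.spike_times_s[0])

    @property
    def offset_s(self) -> float:
        return float(self.spike_times_s[-1])

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)


@dataclass
class EventSchedule:
    """Planned trains plus the epoch rate plan they were drawn from."""

    trains: list[PlannedTrain]
    rates_per_h: dict[str, dict[str, float]]

    @property
    def spike_times_s(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.concatenate([t.spike_times_s for t in self.trains])

    def counts(self, window: tuple[float, float] | None = None) -> dict[str, int]:
        """Ground-truth train/HPD/spike counts (by onset, if windowed)."""
        trains = self.trains
        if window is not None:
            t0, t1 = window
            trains = [t for t in trains if t0 <= t.onset_s < t1]
        return {
            "spike_trains": sum(
                t.intended_class is TrainClass.SPIKE_TRAIN for t in trains
            ),
            "hpds": sum(t.intended_class is TrainClass.HPD for t in trains),
            "spikes": sum(t.n_spikes for t in trains),
        }


def make_background(cfg: SimConfig) -> np.ndarray:
    """Seeded 1/f^alpha background noise, exact RMS ``background_sigma_uV``.

    The spectrum is shaped as f^(-alpha/2) above 0.5 Hz and held flat below,
    so the slow drift that a real amplifier's highpass would remove does not
    dominate the trace.
    """
    n = cfg.n_samples
    if cfg.background_sigma_uV == 0:
        return np.zeros(n)
    rng = np.random.default_rng(cfg.seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    f_shaped = np.maximum(f, 0.5)
    shape = f_shaped ** (-cfg.background_exponent / 2.0)
    shape[0] = 0.0  # no DC offset
    x = np.fft.irfft(spectrum * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (cfg.background_sigma_uV / rms)


def _epoch_plan(cfg: SimConfig) -> dict[str, tuple[float, float]]:
    if cfg.injection_time_s is None:
        return {"pre": (0.0, cfg.duration_s)}
    windows = cfg.epochs.windows(cfg.injection_time_s)
    clipped = {}
    for name, (t0, t1) in windows.items():
        t0, t1 = max(t0, 0.0), min(t1, cfg.duration_s)
        if t1 > t0:
            clipped[name] = (t0, t1)
    return clipped


def _draw_train(
    rng: np.random.Generator, cfg: SimConfig, onset: float, klass: TrainClass
) -> PlannedTrain:
    lo, hi = (
        cfg.spiketrain_duration_range
        if klass is TrainClass.SPIKE_TRAIN
        else cfg.hpd_duration_range
    )
    target = rng.uniform(lo, hi)
    times = [0.0]
    while times[-1] < target:
        times.append(times[-1] + rng.uniform(*cfg.isi_range_s))
    times = np.asarray(times) + onset
    duration = float(times[-1] - times[0])
    intended = TrainClass.HPD if duration >= 10.0 else TrainClass.SPIKE_TRAIN
    return PlannedTrain(
        spike_times_s=times,
        amplitude_factor=float(rng.uniform(*cfg.amplitude_factor_range)),
        intended_class=intended,
    )


def make_schedule(cfg: SimConfig) -> EventSchedule:
    """Poisson train onsets at epoch-scaled rates; overlap-free by rejection.

    Onset counts per epoch and class are Poisson with mean
    rate x multiplier x epoch length; train bodies (duration, ISIs,
    amplitude factor) are drawn to satisfy the train invariants, and the
    intended class is re-derived from the realized duration against the
    10 s boundary. Deterministic under the config seed.
    """
    rng = np.random.default_rng((cfg.seed, 1))
    occupied: list[tuple[float, float]] = []
    trains: list[PlannedTrain] = []
    rates: dict[str, dict[str, float]] = {}

    for name, (t0, t1) in _epoch_plan(cfg).items():
        mult = cfg.rate_multipliers.get(name, 1.0)
        hours = (t1 - t0) / 3600.0
        rates[name] = {
            "spike_trains": cfg.spiketrain_rate_per_h * mult,
            "hpds": cfg.hpd_rate_per_h * mult,
        }
        for klass, rate in (
            (TrainClass.SPIKE_TRAIN, cfg.spiketrain_rate_per_h),
            (TrainClass.HPD, cfg.hpd_rate_per_h),
        ):
            n = rng.poisson(rate * mult * hours)
            for _ in range(n):
                for _attempt in range(200):
                    onset = rng.uniform(t0, t1)
                    train = _draw_train(rng, cfg, onset, klass)
                    span = (
                        train.onset_s - cfg.min_gap_s,
                        train.offset_s + cfg.min_gap_s,
                    )
                    if train.offset_s >= t1 or train.onset_s < t0 + 0.5:
                        continue
                    if any(a0 < span[1] and span[0] < a1 for a0, a1 in occupied):
                        continue
                    occupied.append(span)
                    trains.append(train)
                    break
    trains.sort(key=lambda t: t.onset_s)
    return EventSchedule(trains=trains, rates_per_h=rates)


def spike_template(fs: float, width_ms: float = 40.0) -> tuple[np.ndarray, int]:
    """Biphasic epileptiform spike template, unit peak amplitude.

    A sharp deflection (FWHM ``width_ms``, spectral content well inside the
    0.5-70 Hz passband) followed by a smaller, slower rebound of opposite
    sign. Returns (waveform, index of the peak sample).
    """
    w = width_ms / 1000.0
    sigma = w / 2.355
    t = np.arange(-1.5 * w, 4.0 * w, 1.0 / fs)
    y = np.exp(-(t**2) / (2 * sigma**2))
    y -= 0.35 * np.exp(-((t - 1.2 * w) ** 2) / (2 * (1.5 * sigma) ** 2))
    peak = int(np.argmax(y))
    return y / y[peak], peak


def reference_baseline(cfg: SimConfig, background: np.ndarray | None = None):
    """The baseline stats a detector should use for this config.

    With background noise, the empirical mode of the rendered background;
    on a silent background, the declared ``reference_mode_uV``.
    """
    from .preprocessing import BaselineStats

    if cfg.background_sigma_uV > 0:
        if background is None:
            background = make_background(cfg)
        return compute_baseline(background, cfg.fs, cfg.polarity, 1.0)
    return BaselineStats(
        extrema=np.empty(0),
        polarity=cfg.polarity,
        mode_value=cfg.reference_mode_uV,
        quantization_step=1.0,
    )


def render_session(
    background: np.ndarray, schedule: EventSchedule, cfg: SimConfig
) -> tuple[Recording, pd.DataFrame]:
    """Add scheduled spikes to the background; emit ground-truth annotations.

    Each spike is the biphasic template scaled to
    ``amplitude_factor x mode`` of the background (polarity-signed), peak
    aligned to the scheduled time rounded to the nearest sample. With an
    empty schedule the recording equals the background exactly.
    """
    x = np.asarray(background, dtype=float).copy()
    mode = reference_baseline(cfg, background).mode_value
    template, peak = spike_template(cfg.fs, cfg.spike_width_ms)
    sign = 1.0 if cfg.polarity == "positive" else -1.0
    for train in schedule.trains:
        scale = sign * train.amplitude_factor * mode
        for t_spike in train.spike_times_s:
            center = int(round(t_spike * cfg.fs))
            i0 = center - peak
            i1 = i0 + template.size
            j0, j1 = max(i0, 0), min(i1, x.size)
            if j0 < j1:
                x[j0:j1] += scale * template[j0 - i0 : j1 - i0]

    recording = Recording(
        x[np.newaxis, :], cfg.fs, [cfg.channel_id], start_time=0.0, units="uV"
    )
    rows = [
        {
            "channel_id": cfg.channel_id,
            "onset_s": t.onset_s,
            "offset_s": t.offset_s + 1.0 / cfg.fs,
            "label": "hpd" if t.intended_class is TrainClass.HPD else "spike_train",
        }
        for t in schedule.trains
    ]
    annotations = pd.DataFrame(rows) if rows else empty_annotations()
    return recording, annotations


def simulate_session(cfg: SimConfig) -> tuple[Recording, EventSchedule, pd.DataFrame]:
    """Background + schedule + rendering in one seeded call."""
    background = make_background(cfg)
    schedule = make_schedule(cfg)
    recording, annotations = render_session(background, schedule, cfg)
    return recording, schedule, annotations


def score_detection(
    schedule: EventSchedule,
    detected: list[SpikeEvent],
    tol_s: float,
) -> dict[str, float]:
    """Match detected spikes to the schedule within ``tol_s``.

    Greedy one-to-one matching in time order; returns sensitivity (matched
    fraction of planned spikes), precision (matched fraction of detections)
    and the worst matched timing error in seconds.
    """
    truth = np.sort(schedule.spike_times_s)
    found = np.array(sorted(s.time_s for s in detected))
    matched = 0
    worst = 0.0
    i = j = 0
    while i < truth.size and j < found.size:
        dt = found[j] - truth[i]
        if abs(dt) <= tol_s + 1e-12:
            matched += 1
            worst = max(worst, abs(dt))
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    sensitivity = matched / truth.size if truth.size else 1.0
    precision = matched / found.size if found.size else 1.0
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "max_matched_error_s": worst,
        "n_true": int(truth.size),
        "n_detected": int(found.size),
    }


def cohort_configs(base: SimConfig, n_sessions: int, seed: int) -> list[SimConfig]:
    """n session configs differing only by derived seeds (all < 2^31)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_sessions) % (2**31)
    return [replace(base, seed=int(s)) for s in seeds]
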