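"""Epileptiform spike detection and train / HPD segmentation.

Spikes are local extrema of the polarity-folded signal exceeding a multiple
(default 2x) of the mode baseline, with a refractory minimum distance
(default 70 ms) resolved largest-first. Consecutive spikes closer than the
maximum inter-spike interval (default 1/1.33 s) chain into candidate trains;
a chain qualifies as a spike train when it has >= 3 spikes, lasts >= 1 s and
sustains a mean rate >= 1.33 Hz. Trains lasting >= 10 s are classed as
hippocampal paroxysmal discharges (HPDs) rather than discarded: the 1-10 s
and >= 10 s ranges partition the duration axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError
from .preprocessing import BaselineStats

__all__ = [
    "SpikeEvent",
    "TrainClass",
    "Train",
    "DetectorParams",
    "EventSummary",
    "detect_spikes",
    "group_trains",
    "summarize_events",
    "trains_to_annotations",
]


class TrainClass(str, enum.Enum):
    SPIKE_TRAIN = "SPIKE_TRAIN"
    HPD = "HPD"


@dataclass(frozen=True)
class SpikeEvent:
    """A detected epileptiform spike (peak time and folded amplitude)."""

    time_s: float
    amplitude_uV: float


@dataclass(frozen=True)
class DetectorParams:
    """Spike and train detection parameters.

    threshold_factor
        Spike amplitude threshold as a multiple of the baseline mode.
    min_distance_s
        Minimum distance between spikes; closer candidates are suppressed
        largest-first.
    min_spikes, min_rate_hz, min_train_s
        A chain of spikes qualifies as a train only with >= min_spikes
        spikes, duration >= min_train_s and mean rate >= min_rate_hz.
    hpd_min_s
        Trains of at least this duration are classed HPD.
    max_isi_s
        Chaining bound: consecutive spikes further apart start a new chain.
        Defaults to 1/min_rate_hz so chaining and the rate criterion agree.
    """

    threshold_factor: float = 2.0
    min_distance_s: float = 0.070
    min_spikes: int = 3
    min_rate_hz: float = 1.33
    min_train_s: float = 1.0
    hpd_min_s: float = 10.0
    max_isi_s: float = 1.0 / 1.33

    def __post_init__(self) -> None:
        for name in (
            "threshold_factor", "min_distance_s", "min_spikes",
            "min_rate_hz", "min_train_s", "hpd_min_s", "max_isi_s",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.min_train_s >= self.hpd_min_s:
            raise ParameterError("min_train_s must be below hpd_min_s")


@dataclass(frozen=True)
class Train:
    """A detected spike train or HPD."""

    spikes: tuple[SpikeEvent, ...]
    klass: TrainClass

    @property
    def onset_s(self) -> float:
        return self.spikes[0].time_s

    @property
    def offset_s(self) -> float:
        return self.spikes[-1].time_s

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)

    @property
    def mean_rate_hz(self) -> float:
        return (self.n_spikes - 1) / self.duration_s if self.duration_s > 0 else 0.0


def detect_spikes(
    x: np.ndarray,
    fs: float,
    baseline: BaselineStats,
    params: DetectorParams = DetectorParams(),
    start_time: float = 0.0,
) -> list[SpikeEvent]:
    """Detect spikes as threshold-crossing local maxima of the folded signal.

    The signal is folded by polarity (negated for negative-going spikes), and
    local maxima with amplitude >= threshold_factor x mode are kept. Among
    candidates closer than ``min_distance_s`` only the largest survives,
    resolved iteratively largest-first. Returns spikes sorted by time; an
    empty signal yields an empty list.
    """
    if baseline.mode_value <= 0:
        raise ParameterError(
            f"baseline mode must be positive, got {baseline.mode_value}"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return []
    folded = x if baseline.polarity == "positive" else -x
    threshold = params.threshold_factor * baseline.mode_value
    distance = max(1, int(round(params.min_distance_s * fs)))
    peaks, _ = find_peaks(folded, height=threshold, distance=distance)
    return [
        SpikeEvent(time_s=start_time + p / fs, amplitude_uV=float(folded[p]))
        for p in peaks
    ]


def group_trains(
    spikes: list[SpikeEvent], params: DetectorParams = DetectorParams()
) -> list[Train]:
    """Segment spikes into trains by ISI chaining, then apply the criteria.

    Spikes chain while consecutive inter-spike intervals stay within
    ``max_isi_s``. Each chain becomes a train iff it satisfies the spike
    count, duration and mean-rate minima; qualifying chains with duration
    >= ``hpd_min_s`` are classed HPD. Chains failing any criterion are
    discarded. Output trains are disjoint and time-ordered.
    """
    trains: list[Train] = []
    chain: list[SpikeEvent] = []

    def close_chain() -> None:
        if len(chain) < params.min_spikes:
            return
        duration = chain[-1].time_s - chain[0].time_s
        if duration < params.min_train_s:
            return
        if (len(chain) - 1) / duration < params.min_rate_hz:
            return
        klass = TrainClass.HPD if duration >= params.hpd_min_s else TrainClass.SPIKE_TRAIN
        trains.append(Train(spikes=tuple(chain), klass=klass))

    for spike in spikes:
        if chain and spike.time_s - chain[-1].time_s > params.max_isi_s:
            close_chain()
            chain = []
        chain.append(spike)
    if chain:
        close_chain()
    return trains


@dataclass(frozen=True)
class EventSummary:
    """Counts and cumulative durations per train class in a time window.

    Absolute counts/durations refer to trains whose *onset* lies in the
    half-open window; durations are not clipped at window edges. The
    per-hour fields rescale by 3600 / window length.
    """

    window: tuple[float, float]
    spike_train_count: int = 0
    spike_train_duration_s: float = 0.0
    hpd_count: int = 0
    hpd_duration_s: float = 0.0

    @property
    def hours(self) -> float:
        return (self.window[1] - self.window[0]) / 3600.0

    @property
    def spike_train_count_per_h(self) -> float:
        return self.spike_train_count / self.hours

    @property
    def spike_train_s_per_h(self) -> float:
        return self.spike_train_duration_s / self.hours

    @property
    def hpd_count_per_h(self) -> float:
        return self.hpd_count / self.hours

    @property
    def hpd_s_per_h(self) -> float:
        return self.hpd_duration_s / self.hours

    def rates(self) -> dict[str, float]:
        return {
            "spike_train_count_per_h": self.spike_train_count_per_h,
            "spike_train_s_per_h": self.spike_train_s_per_h,
            "hpd_count_per_h": self.hpd_count_per_h,
            "hpd_s_per_h": self.hpd_s_per_h,
        }


def summarize_events(trains: list[Train], window: tuple[float, float]) -> EventSummary:
    """Count trains with onset in ``[t0, t1)`` and sum their durations."""
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError(f"window end {t1} must exceed start {t0}")
    counts = {TrainClass.SPIKE_TRAIN: 0, TrainClass.HPD: 0}
    durations = {TrainClass.SPIKE_TRAIN: 0.0, TrainClass.HPD: 0.0}
    for train in trains:
        if t0 <= train.onset_s < t1:
            counts[train.klass] += 1
            durations[train.klass] += train.duration_s
    return EventSummary(
        window=(float(t0), float(t1)),
        spike_train_count=counts[TrainClass.SPIKE_TRAIN],
        spike_train_duration_s=durations[TrainClass.SPIKE_TRAIN],
        hpd_count=counts[TrainClass.HPD],
        hpd_duration_s=durations[TrainClass.HPD],
    )


def trains_to_annotations(trains: list[Train], channel_id: str, fs: float) -> pd.DataFrame:
    """Export detected trains as an annotation table.

    Offsets extend one sample past the last spike so the half-open interval
    contains every spike of the train.
    """
    rows = [
        {
            "channel_id": channel_id,
            "onset_s": t.onset_s,
            "offset_s": t.offset_s + 1.0 / fs,
            "label": "hpd" if t.klass is TrainClass.HPD else "spike_train",
        }
        for t in trains
    ]
    from .io import empty_annotations

    return pd.DataFrame(rows) if rows else empty_annotations()
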