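import numpy as np
import pytest
from hypothesis import given, strategies as st

from ihkalfp.errors import ParameterError
from ihkalfp.events import (
    DetectorParams,
    SpikeEvent,
    TrainClass,
    detect_spikes,
    group_trains,
    summarize_events,
    trains_to_annotations,
)
from ihkalfp.io import validate_annotations
from ihkalfp.preprocessing import BaselineStats
from oracles import brute_force_peaks, brute_force_trains


def baseline(mode=50.0, polarity="positive"):
    return BaselineStats(np.empty(0), polarity, mode, 1.0)


def spikes_at(times):
    return [SpikeEvent(t, 150.0) for t in times]


def bump(x, fs, t, amplitude, width_s=0.02):
    """Add a smooth unimodal bump peaking exactly at sample round(t*fs)."""
    center = int(round(t * fs))
    idx = np.arange(max(0, center - 50), min(x.size, center + 51))
    x[idx] += amplitude * np.exp(-(((idx - center) / fs) ** 2) / (2 * width_s**2))


class TestDetectSpikes:
    fs = 500.0

    def test_subthreshold_signal_yields_nothing(self):
        x = np.sin(np.arange(5000) / 20.0) * 40.0  # never exceeds 2 x 50
        assert detect_spikes(x, self.fs, baseline()) == []

    def test_empty_signal_yields_nothing(self):
        assert detect_spikes(np.empty(0), self.fs, baseline()) == []

    def test_clean_spikes_found_at_template_peaks(self):
        x = np.zeros(5000)
        times = [1.0, 1.1, 1.2, 1.3, 1.4]
        for t in times:
            bump(x, self.fs, t, 150.0)
        found = detect_spikes(x, self.fs, baseline())
        assert len(found) == 5
        for spike, t in zip(found, times):
            assert abs(spike.time_s - t) <= 1.0 / self.fs
            assert spike.amplitude_uV >= 100.0

    def test_largest_first_suppression_within_min_distance(self):
        x = np.zeros(2000)
        bump(x, self.fs, 1.00, 200.0, width_s=0.008)
        bump(x, self.fs, 1.05, 150.0, width_s=0.008)  # 50 ms away, smaller
        found = detect_spikes(x, self.fs, baseline())
        assert len(found) == 1
        assert abs(found[0].time_s - 1.00) <= 1.0 / self.fs

    def test_negative_polarity_folds_signal(self):
        x = np.zeros(2000)
        bump(x, self.fs, 2.0, 150.0)
        found = detect_spikes(-x, self.fs, baseline(polarity="negative"))
        assert len(found) == 1 and found[0].amplitude_uV > 0

    def test_nonpositive_mode_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            detect_spikes(np.zeros(100), self.fs, baseline(mode=0.0))

    def test_matches_brute_force_peak_oracle(self, pink_noise):
        bl = BaselineStats(np.empty(0), "positive", 10.0, 1.0)
        params = DetectorParams()
        found = detect_spikes(pink_noise, self.fs, bl, params)
        oracle = brute_force_peaks(
            pink_noise, params.threshold_factor * 10.0,
            int(round(params.min_distance_s * self.fs)),
        )
        assert [int(round(s.time_s * self.fs)) for s in found] == oracle

    def test_raising_threshold_never_adds_spikes(self, pink_noise):
        bl = BaselineStats(np.empty(0), "positive", 5.0, 1.0)
        counts = [
            len(detect_spikes(pink_noise, self.fs, bl, DetectorParams(threshold_factor=f)))
            for f in (1.5, 2.0, 3.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGroupTrains:
    def test_four_spikes_make_a_spike_train(self):
        trains = group_trains(spikes_at([0.0, 0.5, 1.0, 1.5]))
        assert len(trains) == 1
        t = trains[0]
        assert t.duration_s == 1.5
        assert t.n_spikes == 4
        assert t.mean_rate_hz == pytest.approx(2.0)
        assert t.klass is TrainClass.SPIKE_TRAIN

    def test_long_train_classified_hpd(self):
        times = list(np.arange(0.0, 10.5 + 1e-9, 0.5))  # 22 spikes, 10.5 s
        trains = group_trains(spikes_at(times))
        assert len(trains) == 1
        assert trains[0].n_spikes == 22
        assert trains[0].duration_s == pytest.approx(10.5)
        assert trains[0].klass is TrainClass.HPD

    def test_short_chain_rejected_by_duration(self):
        assert group_trains(spikes_at([0.0, 0.3, 0.6])) == []

    def test_sparse_spikes_never_chain(self):
        assert group_trains(spikes_at([0.0, 2.0, 4.0])) == []

    def test_two_spikes_never_a_train(self):
        assert group_trains(spikes_at([0.0, 0.5])) == []

    def test_hpd_boundary_is_inclusive_at_ten_seconds(self):
        on_boundary = group_trains(spikes_at(list(np.linspace(0.0, 10.0, 21))))
        below = group_trains(spikes_at(list(np.linspace(0.0, 9.99, 21))))
        assert on_boundary[0].klass is TrainClass.HPD
        assert below[0].klass is TrainClass.SPIKE_TRAIN

    def test_empty_input_empty_output(self):
        assert group_trains([]) == []

    @given(
        st.lists(
            st.floats(0.0, 60.0, allow_nan=False).map(lambda t: round(t, 3)),
            min_size=0, max_size=60, unique=True,
        )
    )
    def test_matches_brute_force_segmentation(self, times):
        trains = group_trains(spikes_at(sorted(times)))
        oracle = brute_force_trains(times)
        assert [
            (tuple(s.time_s for s in t.spikes), t.klass.value) for t in trains
        ] == oracle

    @given(
        st.lists(
            st.floats(0.0, 120.0, allow_nan=False), min_size=3, max_size=80,
            unique=True,
        )
    )
    def test_trains_disjoint_and_sorted(self, times):
        trains = group_trains(spikes_at(sorted(times)))
        for a, b in zip(trains, trains[1:]):
            assert a.offset_s < b.onset_s


class TestSummarizeEvents:
    def test_no_trains(self):
        summary = summarize_events([], (0.0, 3600.0))
        assert summary.spike_train_count == 0
        assert summary.hpd_s_per_h == 0.0

    def test_hpd_rates_scale_to_per_hour(self):
        trains = group_trains(
            spikes_at(
                [t for onset in np.arange(100.0, 1100.0, 200.0)
                 for t in np.arange(onset, onset + 20.0 + 1e-9, 0.5)]
            )
        )
        assert len(trains) == 5
        summary = summarize_events(trains, (0.0, 1800.0))
        assert summary.hpd_count == 5
        assert summary.hpd_count_per_h == pytest.approx(10.0)
        assert summary.hpd_s_per_h == pytest.approx(200.0)

    def test_membership_by_onset_with_full_duration(self):
        trains = group_trains(spikes_at(list(np.arange(99.0, 110.0, 0.5))))
        summary = summarize_events(trains, (0.0, 100.0))
        assert summary.hpd_count == 1
        assert summary.hpd_duration_s == pytest.approx(10.5)
        # same train not counted again in the next window
        later = summarize_events(trains, (100.0, 200.0))
        assert later.hpd_count == 0

    def test_degenerate_window_rejected(self):
        with pytest.raises(ParameterError):
            summarize_events([], (10.0, 10.0))


class TestParamsAndExport:
    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            DetectorParams(threshold_factor=0.0)
        with pytest.raises(ParameterError):
            DetectorParams(min_train_s=10.0, hpd_min_s=10.0)

    def test_trains_export_as_valid_annotations(self):
        trains = group_trains(spikes_at([0.0, 0.5, 1.0, 1.5]))
        table = validate_annotations(trains_to_annotations(trains, "CA1", 500.0))
        assert list(table["label"]) == ["spike_train"]
        assert table.loc[0, "offset_s"] > table.loc[0, "onset_s"]
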