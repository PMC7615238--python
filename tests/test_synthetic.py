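import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from ihkalfp.errors import ParameterError
from ihkalfp.events import TrainClass, detect_spikes, group_trains
from ihkalfp.io import read_annotations, validate_annotations, write_annotations
from ihkalfp.preprocessing import FilterSpec, compute_baseline, filter_signal
from ihkalfp.synthetic import (
    SimConfig,
    cohort_configs,
    make_background,
    make_schedule,
    reference_baseline,
    render_session,
    score_detection,
    simulate_session,
    spike_template,
)


def short_cfg(**kw) -> SimConfig:
    defaults = dict(duration_s=120.0, injection_time_s=None, seed=7)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestBackground:
    def test_seed_determinism(self):
        a = make_background(short_cfg())
        b = make_background(short_cfg())
        assert np.array_equal(a, b)
        c = make_background(short_cfg(seed=8))
        assert not np.array_equal(a, c)

    def test_rms_tracks_sigma(self):
        x1 = make_background(short_cfg(background_sigma_uV=30.0))
        x2 = make_background(short_cfg(background_sigma_uV=60.0))
        assert np.sqrt(np.mean(x1**2)) == pytest.approx(30.0, rel=1e-9)
        assert np.sqrt(np.mean(x2**2)) == pytest.approx(60.0, rel=1e-9)
        assert np.allclose(x2, 2.0 * x1)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_spectral_slope_matches_exponent(self, alpha):
        cfg = short_cfg(duration_s=600.0, background_exponent=alpha)
        x = make_background(cfg)
        freqs, psd = sps.welch(x, fs=cfg.fs, nperseg=int(20 * cfg.fs))
        band = (freqs >= 1.0) & (freqs <= 80.0)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(psd[band]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=0.2)


class TestSchedule:
    def test_zero_rates_empty_schedule(self):
        cfg = short_cfg(spiketrain_rate_per_h=0.0, hpd_rate_per_h=0.0)
        assert make_schedule(cfg).trains == []

    def test_seed_determinism(self):
        a = make_schedule(short_cfg(duration_s=1200.0))
        b = make_schedule(short_cfg(duration_s=1200.0))
        assert len(a.trains) == len(b.trains)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta.spike_times_s, tb.spike_times_s)
            assert ta.amplitude_factor == tb.amplitude_factor

    def test_train_invariants_hold(self):
        schedule = make_schedule(short_cfg(duration_s=3600.0, seed=5))
        assert len(schedule.trains) > 10
        for train in schedule.trains:
            isis = np.diff(train.spike_times_s)
            assert train.n_spikes >= 3
            assert train.duration_s >= 1.0
            assert (train.n_spikes - 1) / train.duration_s >= 1.33
            assert isis.min() >= 0.07
            assert isis.max() <= 1.0 / 1.33
            expected = (
                TrainClass.HPD if train.duration_s >= 10.0 else TrainClass.SPIKE_TRAIN
            )
            assert train.intended_class is expected

    def test_trains_disjoint_and_sorted(self):
        schedule = make_schedule(short_cfg(duration_s=3600.0, seed=9))
        for a, b in zip(schedule.trains, schedule.trains[1:]):
            assert b.onset_s - a.offset_s >= 2.0  # min_gap default

    def test_poisson_rate_suppression(self):
        # post_early multiplier 0.2: pooled onset counts across seeds stay
        # within 3 sqrt(lambda) of the scaled expectation
        lam_one = 0.2 * (55.0 + 9.0) * 0.5  # both classes, 30 min epoch
        total = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=seed,
                rate_multipliers={"pre": 1.0, "excluded": 1.0,
                                  "post_early": 0.2, "post_late": 1.0},
            )
            schedule = make_schedule(cfg)
            counts = schedule.counts((3900 + 300.0, 3900 + 2100.0))
            total += counts["spike_trains"] + counts["hpds"]
        lam = n_rep * lam_one
        assert abs(total - lam) <= 3 * np.sqrt(lam)


class TestRendering:
    def test_empty_schedule_renders_background_exactly(self):
        cfg = short_cfg(spiketrain_rate_per_h=0.0, hpd_rate_per_h=0.0)
        background = make_background(cfg)
        recording, annotations = render_session(background, make_schedule(cfg), cfg)
        assert np.array_equal(recording.channel(), background)
        assert len(annotations) == 0

    def test_rendered_peaks_match_planned_amplitude(self):
        cfg = short_cfg(seed=3)
        background = make_background(cfg)
        schedule = make_schedule(cfg)
        assert schedule.trains
        recording, _ = render_session(background, schedule, cfg)
        mode = reference_baseline(cfg, background).mode_value
        spikes_only = recording.channel() - background
        folded = -spikes_only  # negative default polarity
        for train in schedule.trains:
            for t in train.spike_times_s:
                peak = folded[int(round(t * cfg.fs))]
                assert peak == pytest.approx(train.amplitude_factor * mode, rel=0.10)

    def test_annotations_roundtrip_through_io(self, tmp_path):
        _, _, annotations = simulate_session(short_cfg(seed=4))
        table = validate_annotations(annotations)
        back = read_annotations(write_annotations(table, tmp_path / "truth.csv"))
        assert len(back) == len(table)
        assert set(back["label"]) <= {"spike_train", "hpd"}

    def test_positive_polarity_renders_upward(self):
        cfg = short_cfg(polarity="positive", background_sigma_uV=0.0, seed=6)
        recording, schedule, _ = simulate_session(cfg)
        if schedule.trains:
            assert recording.channel().max() > 0
            assert recording.channel().max() > -recording.channel().min()


class TestEndToEndDetection:
    def test_noise_free_sessions_recover_schedule_exactly(self):
        for seed in range(5):
            cfg = short_cfg(background_sigma_uV=0.0, seed=seed)
            recording, schedule, _ = simulate_session(cfg)
            spikes = detect_spikes(recording.channel(), cfg.fs, reference_baseline(cfg))
            trains = group_trains(spikes)
            detected = {
                "spike_trains": sum(t.klass is TrainClass.SPIKE_TRAIN for t in trains),
                "hpds": sum(t.klass is TrainClass.HPD for t in trains),
                "spikes": len(spikes),
            }
            assert detected == schedule.counts()
            score = score_detection(schedule, spikes, tol_s=1.0 / cfg.fs + 1e-9)
            assert score["sensitivity"] == 1.0 and score["precision"] == 1.0

    def test_realistic_noise_sensitivity_and_precision(self):
        cfg = short_cfg(duration_s=600.0, seed=1)
        recording, schedule, _ = simulate_session(cfg)
        xf = filter_signal(recording.channel(), cfg.fs, FilterSpec(zero_phase=True))
        baseline = compute_baseline(xf, cfg.fs, cfg.polarity, 1.0)
        spikes = detect_spikes(xf, cfg.fs, baseline)
        score = score_detection(schedule, spikes, tol_s=0.01)
        assert score["sensitivity"] >= 0.9
        assert score["precision"] >= 0.9


class TestConfigs:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(fs=100.0)
        with pytest.raises(ParameterError):
            SimConfig(spiketrain_duration_range=(0.5, 4.0))
        with pytest.raises(ParameterError):
            SimConfig(hpd_duration_range=(5.0, 20.0))
        with pytest.raises(ParameterError):
            SimConfig(rate_multipliers={"pre": -1.0})

    def test_cohort_configs_derive_distinct_seeds(self):
        base = short_cfg()
        cohort = cohort_configs(base, 8, seed=42)
        seeds = [c.seed for c in cohort]
        assert len(set(seeds)) == 8
        assert all(0 <= s < 2**31 for s in seeds)
        assert all(
            dataclasses.replace(c, seed=base.seed) == base for c in cohort
        )

    def test_template_peak_is_unit_and_biphasic(self):
        template, peak = spike_template(500.0)
        assert template[peak] == pytest.approx(1.0)
        assert template.min() < -0.05  # opposite-sign rebound exists
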