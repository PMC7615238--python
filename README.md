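# ihkalfp

Quantification of epileptiform activity in local field potential (LFP)
recordings from the intrahippocampal kainic-acid (IHKA) mouse model of
chronic temporal lobe epilepsy, built for solvent/drug crossover experiments
where each animal's post-injection activity is compared to its own
pre-injection baseline.

The package is aimed at epilepsy researchers who record chronic hippocampal
LFP around an acute treatment (e.g., a solvent such as DMSO, or a drug
candidate) and need reproducible, scriptable versions of the standard
analysis steps:

- **Adaptive spike detection.** The recording is bandpassed 0.5–70 Hz
  (2nd-order Butterworth), divided into 1 s intervals, and the extremum of
  each interval (minimum or maximum, depending on spike polarity) is
  collected; the *mode* of these extrema is the baseline amplitude *M*.
  Epileptiform spikes are local extrema with amplitude ≥ 2·*M*, at least
  70 ms apart (largest-first within the refractory distance).
- **Train / HPD segmentation.** Spikes chain while consecutive inter-spike
  intervals stay ≤ 1/1.33 s. A chain is a *spike train* if it has ≥ 3
  spikes, lasts 1–10 s and sustains a mean rate ≥ 1.33 Hz; trains lasting
  ≥ 10 s are *hippocampal paroxysmal discharges* (HPDs), the model's
  hallmark electrographic event.
- **Spectral features.** Band power by 10 s sliding Hanning-window FFT in
  the rodent-standard delta (1–4 Hz), theta (4–8), alpha (8–13), beta
  (13–30) and gamma (30–80 Hz) bands, plus the coastline (line length)
  Σ|xᵢ₊₁ − xᵢ|.
- **Injection-anchored epochs and normalization.** Metrics are computed for
  the pre-treatment hour [−65, −5) min, the early post epoch [+5, +35) min
  and the late post epoch [+35, +95) min (±5 min around the injection are
  excluded), expressed as per-hour rates, screened by the pre-treatment
  inclusion rule (< 100 s/h spike trains and < 50 s/h HPDs ⇒ excluded;
  manual generalized-seizure annotation ⇒ excluded), and normalized as
  percent-of-pre (100 × post/pre). Output is a tidy table ready for any
  mixed-model/ANOVA package.
- **Dose arithmetic.** DMSO mass dose from % v/v concentration, injection
  volume (µL/g) and density (1.1004 mg/µL), and the PTZ seizure-threshold
  dose from infused volume relative to body weight.
- **Synthetic sessions with ground truth.** A seeded generator renders
  1/f-background LFP with biphasic spikes at scheduled times and
  programmable post-injection rate suppression, so the whole pipeline can
  be validated without animal data.

## Worked example

```python
from ihkalfp import SimConfig, analyze_session, simulate_session

# a 100-minute session, injection at t = 3900 s, post-injection event
# rates suppressed to 20% of baseline in the early post epoch
cfg = SimConfig(
    seed=11,
    rate_multipliers={"pre": 1.0, "excluded": 1.0,
                      "post_early": 0.2, "post_late": 1.0},
)
recording, schedule, truth = simulate_session(cfg)
result = analyze_session(recording, cfg.injection_time_s)

print(result.included, result.polarity, round(result.baseline.mode_value, 1))
print(round(result.epoch_metrics["pre"]["hpd_count_per_h"], 1),
      round(result.percent_of_pre["post_early"]["hpd_count_per_h"], 1))
```

prints

```
True negative 101.0
9.0 22.2
```

i.e., the session passes the pre-treatment inclusion screen, spikes are
negative-going, the adaptive threshold anchor (mode of the per-second
extrema) is 101 µV, the pre-treatment hour contains 9 HPDs, and the early
post epoch retains 22.2% of the pre-treatment HPD rate — consistent with
the programmed 20% suppression up to Poisson sampling of a ~0.9-event
expectation.

The same chain is available from the shell: `ihkalfp simulate | detect |
spectra | analyze | dose | ptz` (see `ihkalfp --help`). The numbered
scripts under `analysis/` run the full study-style workflow (cohort plan →
detection demo → cohort percent-of-pre tables → dose tables) and write
their tables under `results/`.

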