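# Methods

This note documents the models, conventions and numerical choices behind
`ihkalfp`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic validation does and does not
demonstrate about real recordings.

## Signal model and preprocessing

An LFP session is one or more equally sampled amplitude series in
microvolts. All amplitudes are normalized to µV at read time because the
spike threshold is amplitude-relative (2× a baseline statistic); mixed units
would silently shift detection. All times are seconds from recording start;
annotation intervals are half-open `[onset, offset)`.

**Bandpass.** A 2nd-order Butterworth bandpass, 0.5–70 Hz by default
(`scipy.signal.butter(N=2, btype="bandpass")`, i.e. two poles per band
edge — the conventional reading of "second-order bandpass"). The filter is
applied forward-only (causal) by default, matching what an on-line
acquisition system would do; `FilterSpec(zero_phase=True)` switches to
forward–backward filtering when peak-time accuracy matters more than
causality (the causal filter delays spike peaks by a small, constant group
delay — irrelevant for counts and rates, relevant when comparing detected
spike times to external timestamps at millisecond precision).

**Polarity.** Epileptiform spikes in this preparation deflect predominantly
in one direction, but which direction depends on electrode position. The
automatic rule compares the mean per-second maximum with the mean absolute
per-second minimum over ≥ 10 s; the larger side wins, ties break to
"negative" (the common case for hippocampal depth electrodes). The result
can always be overridden in configuration.

**Mode baseline.** The signal is cut into complete 1 s intervals (a
trailing partial second is dropped) and the polarity-folded extremum of each
interval collected. The mode of a continuous quantity requires binning: the
extrema are quantized to the nearest multiple of `quantization_step`
(default 1 µV — of the order of an acquisition system's effective amplitude
resolution; configurable because hardware differs), and the mode is the
most populated bin's center. Ties resolve to the smallest-amplitude tied
bin, the conservative direction: a lower mode gives a lower detection
threshold, favoring sensitivity. The estimator needs ≥ 3 complete seconds
to run and ≥ 60 s to be stable; the pipeline computes it over the full
pre-treatment hour.

The mode is computed **on the pre-treatment epoch only and reused for the
post epochs**. A threshold re-estimated after treatment would move with the
treatment effect, biasing percent-of-pre toward 100%.

## Event detection

**Spikes.** Local maxima of the polarity-folded, filtered signal with
amplitude ≥ `threshold_factor × mode` (default 2.0) and a refractory
minimum distance of 70 ms. Among candidates closer than the minimum
distance, the largest is kept, resolved iteratively largest-first (this is
exactly `scipy.signal.find_peaks`' distance rule; the test suite checks it
against an independent brute-force implementation).

**Trains and HPDs.** A rate criterion alone cannot segment a spike sequence
into events, so the rate bound is operationalized as a chaining rule:
consecutive spikes chain while their interval is ≤ `max_isi_s = 1/1.33 s`.
A chain qualifies as a train iff it has ≥ 3 spikes, lasts ≥ 1 s
(first-spike-to-last-spike; trains are defined by their spikes, so no
padding is added) and sustains a mean rate `(n−1)/duration ≥ 1.33 Hz`.
With the default `max_isi` the chaining bound already implies the rate
bound; both are kept independently configurable so either reading (per-chain
rate vs. ISI bound) can be reproduced. Duration classifies the event:
`< 10 s` spike train, `≥ 10 s` HPD — a partition, not a filter, so long
trains are reclassified rather than discarded. The boundary is inclusive:
exactly 10.0 s is an HPD.

**Windowed summaries.** A train belongs to a window iff its *onset* lies in
the half-open window, and contributes its full duration there (durations
are not clipped at window edges); this is the simplest convention that
never double-counts an event across adjacent epochs. Counts and cumulative
durations are rescaled to per-hour rates so epochs of different lengths are
comparable.

## Spectral features

Band power uses a 10 s sliding Hann window (step 1 s by default — the step
is a display/averaging granularity, not a scientific parameter; results
are means over windows). Per window, the tapered periodogram with the
standard window-power correction, in µV², so that the sum over the full
band set approximates the signal's mean-square amplitude (Parseval holds to
within Hann leakage; the suite requires 5%). Band edges are half-open
`[low, high)`; a bin that falls exactly on a shared edge counts toward the
upper band only, so nothing is double-counted. Per-epoch values are
arithmetic means over the sliding windows whose centers fall inside the
epoch.

The coastline is the exactly rounded sum (`math.fsum`) of absolute
first differences — summation order cannot perturb the last bits, so equal
segments give bit-equal coastlines. It is reported both as the raw sum and
per second; only percent-of-pre is used downstream, where the two differ
only when epoch lengths differ.

## Epochs, inclusion, normalization

Epochs relative to the injection: pre `[−65, −5)` min, exclusion zone
`[−5, +5)` min (handling and injection artifacts), early post `[+5, +35)`
min, late post `[+35, +95)` min. Placing the pre-treatment hour at
`[−65, −5)` rather than `[−60, 0)` reconciles "one hour of pre-treatment
baseline" with the ±5 min exclusion: the baseline hour ends where the
exclusion zone begins. The placement is configurable.

Inclusion: sessions whose pre-treatment hour shows `< 100 s/h` of spike
trains **and** `< 50 s/h` of HPDs are excluded (too little baseline
epileptiform activity for a within-animal comparison), as are sessions with
a manual generalized-seizure annotation anywhere in the analyzed span. The
exclusion rule's literal "and" and the stricter "or" reading are both
implemented behind a switch (`combine`), defaulting to the literal "and";
the truth table of both variants is pinned by tests.

Percent-of-pre is `100 × post/pre` per metric, defined only for positive
pre values; a zero pre rate flags the metric as undefined-baseline on the
session rather than silently dropping or zeroing it. Group summaries report
mean, sample SD (ddof = 1; a single session reports SD as missing) and n
per treatment × sex, in a long-format table intended for external
mixed-model fitting — no inference is done in-package.

The channel to analyze is named in configuration (recordings may carry
ipsi-/contralateral hippocampal and cortical channels); the default is the
first channel.

## Dosing

`dose_mg_per_kg = conc%/100 × volume_µL/g × density_mg/µL × 1000`, with DMSO
density 1.1004 mg/µL (20 °C literature value) and concentration interpreted
as % v/v — the only interpretation under which one density reproduces the
conventional dose series (16.5 / 165.1 / 495.2 / 1651 mg/kg at 1.5 µL/g and
1100 mg/kg for a 10% solution at 10 µL/g). Printed doses are rounded to one
decimal below 1000 mg/kg and to integers above, matching reporting
convention; full precision is always available. The PTZ threshold is
`infused_volume_mL × conc_mg/mL / (weight_g/1000)` for a constant-rate
tail-vein infusion (10 mg/mL at 100 µL/min by default) stopped at seizure
onset.

## Synthetic sessions

The generator emulates the statistical structure the pipeline cares about,
not hippocampal biophysics:

- **Background:** seeded Gaussian noise spectrally shaped to `1/f^α`
  (α = 1 by default) above 0.5 Hz and flat below (a real front-end's
  highpass would remove slower drift), scaled to an exact RMS (50 µV
  default), at 500 Hz sampling.
- **Events:** Poisson train onsets per epoch at 55 spike trains/h and
  9 HPDs/h by default — the order of pre-treatment activity reported for
  chronic IHKA mice (with cumulative durations of order 140–160 s/h, so
  default sessions pass the inclusion screen). Spike-train durations are
  uniform on [1.2, 4] s and HPD durations on [10.5, 25] s; intra-train ISIs
  uniform on [0.15, 0.5] s (rates 2–6.7 Hz, comfortably above 1.33 Hz and
  the 70 ms refractory bound). Trains are kept ≥ 2 s apart by rejection
  sampling so adjacent trains cannot chain. The intended class is
  re-derived from the realized duration against the 10 s boundary.
- **Spikes:** a biphasic template — a sharp deflection of 40 ms FWHM
  (spectral content ≈ 10 Hz, inside the passband) with a smaller
  opposite-sign rebound — scaled to `amplitude_factor × mode` of the
  background (factors uniform on [3, 6], safely above the 2× threshold)
  and signed by polarity (negative by default).
- **Treatment:** per-epoch multiplicative rate suppression applied to both
  event classes, emulating an anti-seizure effect.

With `background_sigma_uV = 0` the generator renders events on a silent
background and references amplitudes to a declared mode (50 µV); these
noise-free sessions are the detector oracle: detection must reproduce the
schedule's spike/train/HPD counts and classes exactly, with spike times
within one sample.

**What passing tests show — and don't.** Exact recovery on noise-free
sessions validates the detector/segmentation logic; ≥ 0.9
sensitivity/precision on 1/f-noise sessions shows the adaptive threshold
works when events clear it by design (factors ≥ 3 vs. threshold 2).
Real recordings contain artifacts, state-dependent background
nonstationarity, waveform variability and near-threshold events, none of
which the generator models — so these results bound the pipeline's
correctness, not its in-vivo operating characteristics. Cohort-level
checks run 8 sessions per arm (100 min each at 500 Hz) with programmed
post-injection suppression; at the default 9 HPDs/h baseline, the
percent-of-pre of a 30 min post epoch is a ratio of small Poisson counts
and correspondingly heavy-tailed — group means are compared within
standard-error bands, never pointwise.

## Degenerate inputs and edge rules

- Empty signal → no spikes (not an error); empty spike list → no trains.
- Fewer than 3 complete seconds → the baseline refuses; < 10 s → polarity
  refuses; < 1 window → band power refuses; < 2 samples → coastline
  refuses. A non-positive mode makes detection a parameter error rather
  than a silent all-pass.
- Recording coverage is checked against the pre and early-post epochs
  (errors name the missing epochs); the late post epoch is analyzed only
  when fully covered.
- EDF writing uses 1 s records, 16-bit, symmetric physical range per
  channel (round-trip error ≤ one quantization step); it requires integer
  sampling rates and whole seconds of data. Delimited text round-trips
  exactly at full precision.
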