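"""Session-level orchestration around a treatment injection.

A session is analyzed in epochs relative to the injection time: a one-hour
pre-treatment baseline, a +/- 5 min peri-injection exclusion zone (handling
artifacts), an early post epoch (labeled "5-34 min") and a late post epoch
("35-94 min"). Event and spectral metrics are computed per epoch as per-hour
rates, sessions are screened by the pre-treatment activity inclusion rule,
and post-epoch metrics are normalized to the pre-treatment hour
(percent-of-pre). The output is a tidy table ready for external mixed-model
or ANOVA fitting; no inference is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError, UndefinedBaselineError
from .events import (
    DetectorParams,
    EventSummary,
    detect_spikes,
    group_trains,
    summarize_events,
)
from .io import Recording
from .preprocessing import (
    BaselineStats,
    FilterSpec,
    compute_baseline,
    detect_polarity,
    filter_signal,
)
from .spectral import DEFAULT_BANDS, Band, band_power, coastline, mean_band_power

__all__ = [
    "EpochScheme",
    "InclusionRule",
    "AnalysisConfig",
    "SessionResult",
    "analyze_session",
    "apply_inclusion",
    "percent_of_pre",
    "summarize_group",
]


@dataclass(frozen=True)
class EpochScheme:
    """Analysis epochs in seconds relative to the injection time.

    The pre-treatment hour is placed at [-65, -5) min so that, together with
    the [-5, +5) min peri-injection exclusion, the "1 h pre-treatment"
    baseline ends where the exclusion zone begins. Post epochs are the
    half-open [5, 35) and [35, 95) min intervals (the "5-34 min" and
    "35-94 min" windows).
    """

    pre: tuple[float, float] = (-65 * 60.0, -5 * 60.0)
    excluded: tuple[float, float] = (-5 * 60.0, 5 * 60.0)
    post_early: tuple[float, float] = (5 * 60.0, 35 * 60.0)
    post_late: tuple[float, float] = (35 * 60.0, 95 * 60.0)

    def __post_init__(self) -> None:
        names = self.epoch_names()
        spans = [getattr(self, n) for n in names]
        for (a0, a1) in spans:
            if a1 <= a0:
                raise ParameterError("epoch end must exceed epoch start")
        for i, (a0, a1) in enumerate(spans):
            for (b0, b1) in spans[i + 1 :]:
                if a0 < b1 and b0 < a1:
                    raise ParameterError("epochs must be pairwise disjoint")
        if not math.isclose(self.pre[1] - self.pre[0], 3600.0):
            raise ParameterError("the pre-treatment epoch must span one hour")

    @staticmethod
    def epoch_names() -> tuple[str, ...]:
        return ("pre", "excluded", "post_early", "post_late")

    def windows(self, injection_time_s: float) -> dict[str, tuple[float, float]]:
        """Absolute half-open windows for a given injection time."""
        return {
            name: (
                injection_time_s + getattr(self, name)[0],
                injection_time_s + getattr(self, name)[1],
            )
            for name in self.epoch_names()
        }


@dataclass(frozen=True)
class InclusionRule:
    """Pre-treatment activity screening.

    With ``combine="and"`` (the literal reading of "<100 s spike trains and
    <50 s HPDs ... were excluded") a session is excluded only when *both*
    cumulative durations fall below threshold; ``combine="or"`` excludes
    when either does. A manual generalized-seizure annotation anywhere in
    the analyzed period always excludes.
    """

    min_spiketrain_s_per_h: float = 100.0
    min_hpd_s_per_h: float = 50.0
    combine: str = "and"
    exclude_on_generalized_seizure: bool = True

    def __post_init__(self) -> None:
        if self.min_spiketrain_s_per_h < 0 or self.min_hpd_s_per_h < 0:
            raise ParameterError("inclusion thresholds must be >= 0")
        if self.combine not in {"and", "or"}:
            raise ParameterError("combine must be 'and' or 'or'")


@dataclass
class AnalysisConfig:
    """Everything a session analysis needs besides the recording itself."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    detector: DetectorParams = field(default_factory=DetectorParams)
    epochs: EpochScheme = field(default_factory=EpochScheme)
    inclusion: InclusionRule = field(default_factory=InclusionRule)
    bands: tuple[Band, ...] = DEFAULT_BANDS
    spectral_window_s: float = 10.0
    spectral_step_s: float = 1.0
    baseline_quantization_uV: float = 1.0
    polarity: str = "auto"  # auto | positive | negative
    channel: str | int | None = None


@dataclass
class SessionResult:
    """Per-epoch metrics of one session, absolute and percent-of-pre."""

    session_id: str
    subject_id: str
    sex: str
    treatment: str
    dose_mg_per_kg: float
    injection_time_s: float
    polarity: str
    baseline: BaselineStats
    included: bool
    exclusion_reason: str
    epoch_metrics: dict[str, dict[str, float]]
    percent_of_pre: dict[str, dict[str, float]]
    undefined_baseline_metrics: list[str]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (epoch, metric)."""
        rows = []
        for epoch, metrics in self.epoch_metrics.items():
            for metric, value in metrics.items():
                rows.append(
                    {
                        "session_id": self.session_id,
                        "subject_id": self.subject_id,
                        "sex": self.sex,
                        "treatment": self.treatment,
                        "dose_mg_per_kg": self.dose_mg_per_kg,
                        "included": self.included,
                        "epoch": epoch,
                        "metric": metric,
                        "value": value,
                        "percent_of_pre": self.percent_of_pre.get(epoch, {}).get(
                            metric, np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def percent_of_pre(pre_rate: float, post_rate: float) -> float:
    """Post metric as a percentage of the pre-treatment hour."""
    if pre_rate <= 0:
        raise UndefinedBaselineError(
            f"percent-of-pre undefined for pre rate {pre_rate}"
        )
    return 100.0 * post_rate / pre_rate


def apply_inclusion(
    pre_summary: EventSummary,
    rule: InclusionRule = InclusionRule(),
    annotations: pd.DataFrame | None = None,
    analyzed_windows: list[tuple[float, float]] | None = None,
) -> tuple[bool, str]:
    """Evaluate the pre-treatment inclusion rule; returns (included, reason)."""
    if rule.exclude_on_generalized_seizure and annotations is not None and len(annotations):
        seizures = annotations[annotations["label"] == "generalized_seizure"]
        windows = analyzed_windows or [(-np.inf, np.inf)]
        for _, row in seizures.iterrows():
            if any(row.onset_s < t1 and row.offset_s > t0 for t0, t1 in windows):
                return False, "generalized seizure during the analyzed period"

    st_low = pre_summary.spike_train_s_per_h < rule.min_spiketrain_s_per_h
    hpd_low = pre_summary.hpd_s_per_h < rule.min_hpd_s_per_h
    excluded = (st_low and hpd_low) if rule.combine == "and" else (st_low or hpd_low)
    if excluded:
        parts = []
        if st_low:
            parts.append(
                f"spike trains {pre_summary.spike_train_s_per_h:.1f} s/h < "
                f"{rule.min_spiketrain_s_per_h:g}"
            )
        if hpd_low:
            parts.append(
                f"HPDs {pre_summary.hpd_s_per_h:.1f} s/h < {rule.min_hpd_s_per_h:g}"
            )
        return False, "pre-treatment activity below threshold: " + "; ".join(parts)
    return True, ""


def _slice_indices(
    window: tuple[float, float], start_time: float, fs: float, n: int
) -> tuple[int, int]:
    i0 = int(np.ceil((window[0] - start_time) * fs - 1e-9))
    i1 = int(np.ceil((window[1] - start_time) * fs - 1e-9))
    return max(0, i0), min(n, i1)


def analyze_session(
    recording: Recording,
    injection_time_s: float,
    config: AnalysisConfig | None = None,
    manual_annotations: pd.DataFrame | None = None,
    session_meta: dict | None = None,
) -> SessionResult:
    """Run the full single-session analysis chain.

    Filtering, polarity and mode baseline (both computed on the
    pre-treatment hour and held fixed, so the detection threshold cannot
    drift with a treatment effect), spike/train/HPD detection over all
    epochs, banded power and coastline per epoch, inclusion screening, and
    percent-of-pre normalization of every post-epoch metric.

    The recording must cover the pre-treatment hour and the early post
    epoch; the late post epoch is analyzed only when fully covered.
    """
    config = config or AnalysisConfig()
    meta = {
        "session_id": "session",
        "subject_id": "subject",
        "sex": "",
        "treatment": "",
        "dose_mg_per_kg": float("nan"),
        **(session_meta or {}),
    }
    fs = recording.fs
    x = recording.channel(config.channel)
    t_lo = recording.start_time
    t_hi = recording.start_time + recording.duration_s
    windows = config.epochs.windows(injection_time_s)

    required = ("pre", "post_early")
    missing = [
        name for name in required
        if windows[name][0] < t_lo - 1e-9 or windows[name][1] > t_hi + 1e-9
    ]
    if missing:
        raise CoverageError(
            f"recording [{t_lo:.0f}, {t_hi:.0f}) s does not cover epoch(s) "
            + ", ".join(f"{m} [{windows[m][0]:.0f}, {windows[m][1]:.0f}) s"
                        for m in missing)
        )
    analyzed = ["pre", "post_early"]
    if windows["post_late"][0] >= t_lo - 1e-9 and windows["post_late"][1] <= t_hi + 1e-9:
        analyzed.append("post_late")

    xf = filter_signal(x, fs, config.filter)

    i0, i1 = _slice_indices(windows["pre"], t_lo, fs, xf.size)
    pre_signal = xf[i0:i1]
    polarity = (
        detect_polarity(pre_signal, fs) if config.polarity == "auto" else config.polarity
    )
    baseline = compute_baseline(
        pre_signal, fs, polarity, config.baseline_quantization_uV
    )

    spikes = detect_spikes(xf, fs, baseline, config.detector, start_time=t_lo)
    trains = group_trains(spikes, config.detector)

    epoch_metrics: dict[str, dict[str, float]] = {}
    for name in analyzed:
        window = windows[name]
        summary = summarize_events(trains, window)
        j0, j1 = _slice_indices(window, t_lo, fs, xf.size)
        seg = xf[j0:j1]
        series = band_power(
            seg, fs, config.bands, config.spectral_window_s,
            config.spectral_step_s, start_time=window[0],
        )
        means = mean_band_power(series, window)
        coast = coastline(seg)
        seg_s = (j1 - j0) / fs
        metrics = dict(summary.rates())
        metrics.update({f"power_{b}_uV2": p for b, p in means.items()})
        metrics["coastline_uV"] = coast
        metrics["coastline_uV_per_s"] = coast / seg_s
        epoch_metrics[name] = metrics

    analyzed_span = [
        (windows["pre"][0], windows[analyzed[-1]][1])
    ]
    included, reason = apply_inclusion(
        summarize_events(trains, windows["pre"]),
        config.inclusion,
        manual_annotations,
        analyzed_span,
    )

    pct: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    pre_metrics = epoch_metrics["pre"]
    for name in analyzed:
        if name == "pre":
            continue
        pct[name] = {}
        for metric, post_value in epoch_metrics[name].items():
            if pre_metrics[metric] > 0:
                pct[name][metric] = percent_of_pre(pre_metrics[metric], post_value)
            else:
                pct[name][metric] = float("nan")
                undefined.append(f"{name}:{metric}")

    return SessionResult(
        session_id=str(meta["session_id"]),
        subject_id=str(meta["subject_id"]),
        sex=str(meta["sex"]),
        treatment=str(meta["treatment"]),
        dose_mg_per_kg=float(meta["dose_mg_per_kg"]),
        injection_time_s=float(injection_time_s),
        polarity=polarity,
        baseline=baseline,
        included=included,
        exclusion_reason=reason,
        epoch_metrics=epoch_metrics,
        percent_of_pre=pct,
        undefined_baseline_metrics=undefined,
    )


def summarize_group(
    results: list[SessionResult] | pd.DataFrame,
    group_by: tuple[str, ...] = ("treatment", "sex"),
    included_only: bool = True,
) -> pd.DataFrame:
    """Mean, sample SD and n per metric per group, in tidy long format.

    Accepts SessionResults or an already-tidy table. Groups with a single
    session report SD as missing (0 degrees of freedom); empty groups are
    omitted. The table is ready for external mixed-model / ANOVA fitting.
    """
    if isinstance(results, pd.DataFrame):
        tidy = results
    else:
        tidy = pd.concat([r.to_tidy() for r in results], ignore_index=True)
    if included_only and "included" in tidy.columns:
        tidy = tidy[tidy["included"]]
    if tidy.empty:
        return pd.DataFrame()
    grouped = tidy.groupby([*group_by, "epoch", "metric"], dropna=False)
    out = grouped.agg(
        n=("value", "count"),
        mean_value=("value", "mean"),
        sd_value=("value", lambda v: v.std(ddof=1)),
        mean_percent_of_pre=("percent_of_pre", "mean"),
        sd_percent_of_pre=("percent_of_pre", lambda v: v.std(ddof=1)),
    )
    return out.reset_index()
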