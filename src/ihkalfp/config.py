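"""YAML configuration loading for the CLI and batch analyses.

The file mirrors the library's parameter dataclasses, e.g.::

    filter:    {low_hz: 0.5, high_hz: 70, order: 2, zero_phase: false}
    baseline:  {quantization_uV: 1.0, polarity: auto}
    detector:  {threshold_factor: 2.0, min_distance_s: 0.070}
    inclusion: {combine: and}
    spectral:  {window_s: 10, step_s: 1}
    channel:   CA1

Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ParameterError
from .events import DetectorParams
from .pipeline import AnalysisConfig, EpochScheme, InclusionRule
from .preprocessing import FilterSpec

__all__ = ["load_config", "config_from_dict"]


def _build(cls, data: dict, rename: dict[str, str] | None = None):
    rename = rename or {}
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        name = rename.get(key, key)
        if name not in known:
            raise ParameterError(f"unknown {cls.__name__} key {key!r}")
        kwargs[name] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> AnalysisConfig:
    data = dict(data or {})
    cfg = AnalysisConfig()
    if "filter" in data:
        cfg.filter = _build(FilterSpec, data.pop("filter"))
    if "detector" in data:
        cfg.detector = _build(DetectorParams, data.pop("detector"))
    if "epochs" in data:
        epochs = {k: tuple(v) for k, v in data.pop("epochs").items()}
        cfg.epochs = _build(EpochScheme, epochs)
    if "inclusion" in data:
        cfg.inclusion = _build(InclusionRule, data.pop("inclusion"))
    if "baseline" in data:
        baseline = data.pop("baseline")
        known = {"quantization_uV", "polarity"}
        unknown = set(baseline) - known
        if unknown:
            raise ParameterError(f"unknown baseline key(s) {sorted(unknown)}")
        cfg.baseline_quantization_uV = baseline.get(
            "quantization_uV", cfg.baseline_quantization_uV
        )
        cfg.polarity = baseline.get("polarity", cfg.polarity)
    if "spectral" in data:
        spectral = data.pop("spectral")
        known = {"window_s", "step_s"}
        unknown = set(spectral) - known
        if unknown:
            raise ParameterError(f"unknown spectral key(s) {sorted(unknown)}")
        cfg.spectral_window_s = spectral.get("window_s", cfg.spectral_window_s)
        cfg.spectral_step_s = spectral.get("step_s", cfg.spectral_step_s)
    if "channel" in data:
        cfg.channel = data.pop("channel")
    if data:
        raise ParameterError(f"unknown config section(s) {sorted(data)}")
    return cfg


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; ``None`` gives the defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
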