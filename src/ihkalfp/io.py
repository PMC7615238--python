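"""Recording and annotation I/O.

Two recording formats are supported: EDF/EDF+ and a delimited-text format
(one CSV column per channel, with a JSON sidecar ``<file>.json`` carrying the
sampling rate, units and start time). All amplitudes are normalized to
microvolts at read time so that the amplitude-relative spike threshold is
unit-safe throughout the pipeline.

Annotation tables are CSV with the fixed header
``channel_id,onset_s,offset_s,label``; intervals are half-open
``[onset, offset)`` in seconds from recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .errors import DataError, FormatError, ValidationError

__all__ = [
    "Recording",
    "ANNOTATION_LABELS",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "empty_annotations",
]

#: admissible event labels in an annotation table
ANNOTATION_LABELS = frozenset(
    {"spike", "spike_train", "hpd", "generalized_seizure", "artifact"}
)

_ANNOTATION_COLUMNS = ["channel_id", "onset_s", "offset_s", "label"]


@dataclass
class Recording:
    """A multi-channel LFP recording.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_channels, n_samples)``, amplitudes in ``units``.
    fs
        Sampling rate in Hz (> 0).
    channel_ids
        One label per channel.
    start_time
        Offset of the first sample in seconds (timestamps are
        ``start_time + i / fs``).
    units
        Amplitude unit; the package normalizes to microvolts ("uV").
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    start_time: float = 0.0
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs is None or self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite sample at channel {self.channel_ids[ch]!r}, index {idx}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str | int | None = None) -> np.ndarray:
        """Return one channel's samples (default: first channel)."""
        if channel_id is None:
            return self.samples[0]
        if isinstance(channel_id, (int, np.integer)):
            return self.samples[int(channel_id)]
        try:
            return self.samples[self.channel_ids.index(channel_id)]
        except ValueError:
            raise KeyError(
                f"channel {channel_id!r} not in {self.channel_ids}"
            ) from None


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".csv", ".txt", ".tsv"}:
        return "csv"
    raise FormatError(f"cannot infer recording format from {path.name!r}")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_recording(
    path: str | Path,
    format_hint: str | None = None,
    fs: float | None = None,
    units: str = "uV",
) -> Recording:
    """Read an LFP recording from EDF or delimited text.

    For delimited text the sampling rate comes from the JSON sidecar written
    by :func:`write_recording`, or from the ``fs`` argument if no sidecar
    exists. Amplitudes are returned in microvolts. The reader never
    resamples: output length equals the stored length.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such recording file: {path}")
    fmt = _infer_format(path, format_hint)
    if fmt == "edf":
        samples, fs_file, channel_ids = _edf.read_edf(path)
        return Recording(samples, fs_file, channel_ids)
    if fmt == "csv":
        start_time = 0.0
        if _sidecar(path).exists():
            meta = json.loads(_sidecar(path).read_text())
            fs = meta.get("fs", fs)
            units = meta.get("units", units)
            start_time = meta.get("start_time", 0.0)
        if fs is None:
            raise FormatError(
                f"no sampling rate for {path.name!r}: provide fs or a sidecar"
            )
        if fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {fs}")
        frame = pd.read_csv(path, float_precision="round_trip")
        samples = frame.to_numpy(dtype=float).T
        rec = Recording(
            samples, float(fs), [str(c) for c in frame.columns], start_time, units
        )
        return _to_microvolts(rec)
    raise FormatError(f"unknown recording format {fmt!r}")


_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "nv": 1e-3}


def _to_microvolts(rec: Recording) -> Recording:
    factor = _UNIT_TO_UV.get(rec.units.lower())
    if factor is None:
        raise FormatError(f"unknown amplitude unit {rec.units!r}")
    if factor != 1.0:
        rec.samples = rec.samples * factor
    rec.units = "uV"
    return rec


def write_recording(
    recording: Recording, path: str | Path, format_hint: str | None = None
) -> Path:
    """Write a Recording to EDF or delimited text (with JSON sidecar).

    Delimited text round-trips exactly at full float precision; EDF
    round-trips within its 16-bit quantization step.
    """
    path = Path(path)
    if recording.n_samples == 0:
        raise FormatError("cannot write an empty recording")
    fmt = _infer_format(path, format_hint)
    if fmt == "edf":
        return _edf.write_edf(
            path, recording.samples, recording.fs, recording.channel_ids,
            recording.units,
        )
    if fmt == "csv":
        frame = pd.DataFrame(
            {cid: recording.samples[i] for i, cid in enumerate(recording.channel_ids)}
        )
        frame.to_csv(path, index=False)
        _sidecar(path).write_text(
            json.dumps(
                {
                    "fs": recording.fs,
                    "units": recording.units,
                    "start_time": recording.start_time,
                    "channel_ids": recording.channel_ids,
                }
            )
        )
        return path
    raise FormatError(f"unknown recording format {fmt!r}")


def empty_annotations() -> pd.DataFrame:
    """An empty annotation table with the canonical columns."""
    return pd.DataFrame(
        {
            "channel_id": pd.Series(dtype=str),
            "onset_s": pd.Series(dtype=float),
            "offset_s": pd.Series(dtype=float),
            "label": pd.Series(dtype=str),
        }
    )


def validate_annotations(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort an annotation table.

    Rows are sorted by onset within channel; intervals are half-open
    ``[onset, offset)``. Raises :class:`ValidationError` naming the first
    offending row.
    """
    missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns {missing}")
    table = table[_ANNOTATION_COLUMNS].copy()
    table["onset_s"] = table["onset_s"].astype(float)
    table["offset_s"] = table["offset_s"].astype(float)
    bad = table.index[table["onset_s"] >= table["offset_s"]]
    if len(bad):
        raise ValidationError(
            f"annotation row {bad[0]}: onset_s >= offset_s"
        )
    unknown = set(table["label"]) - ANNOTATION_LABELS
    if unknown:
        raise ValidationError(f"unknown annotation labels {sorted(unknown)}")
    return table.sort_values(
        ["channel_id", "onset_s"], kind="stable"
    ).reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such annotation file: {path}")
    return validate_annotations(pd.read_csv(path))


def write_annotations(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_annotations(table).to_csv(path, index=False)
    return path
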