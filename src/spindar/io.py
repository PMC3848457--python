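"""Recording / event-list / summary file I/O.

Recordings travel as CSV matrices (one column per channel, microvolts)
with a YAML sidecar holding the sampling rate and metadata, or as EDF
(read via :mod:`mne`, converted to microvolts).  Event lists are BED-like
TSV with ``onset_s``/``offset_s``/``duration_s``/``source`` columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EventList

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "write_summary",
]


@dataclass
class Recording:
    """Multichannel recording: (channels x samples) microvolt matrix."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select(self, channels: list[str]) -> "Recording":
        idx = [self.channel_labels.index(c) for c in channels]
        return Recording(self.data[idx], self.fs, list(channels), dict(self.meta))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_recording(path, fmt: str | None = None, fs: float | None = None) -> Recording:
    """Read a recording from EDF or CSV.

    CSV needs a sampling rate, from the ``<file>.csv.yaml`` sidecar or
    the ``fs`` argument.  EDF channel data are converted to microvolts.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        meta: dict = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
        if fs is None:
            fs = meta.get("fs")
        if fs is None:
            raise ValueError(
                f"sampling rate missing: pass fs= or provide {sidecar.name} with an 'fs' key"
            )
        return Recording(df.to_numpy().T, float(fs), list(df.columns), meta)
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF reading requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # Volts -> microvolts
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                         {"format": "edf"})
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(recording: Recording, path) -> Path:
    """Write a recording as CSV plus a YAML sidecar with fs and metadata."""
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=recording.channel_labels)
    df.to_csv(path, index=False)
    sidecar = _sidecar_path(path)
    meta = dict(recording.meta)
    meta["fs"] = float(recording.fs)
    sidecar.write_text(yaml.safe_dump(meta))
    return path


def read_events(path) -> EventList:
    df = pd.read_csv(path, sep="\t")
    return EventList.from_dataframe(df)


def write_events(events: EventList, path) -> Path:
    path = Path(path)
    events.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
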