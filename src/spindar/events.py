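"""Ordered, disjoint event intervals in seconds (half-open)."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EventList"]


class EventList:
    """A sorted list of pairwise-disjoint ``[onset_s, offset_s)`` intervals.

    ``source`` records provenance (a channel id, or ``"voted"`` for the
    channel-voted consensus).
    """

    def __init__(self, intervals: Iterable[Sequence[float]] = (), source: str = ""):
        arr = np.asarray(sorted(tuple(map(float, iv)) for iv in intervals), dtype=float)
        if arr.size == 0:
            arr = np.empty((0, 2))
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("intervals must be (onset, offset) pairs")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("every offset must exceed its onset")
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("intervals must be pairwise disjoint")
        self.intervals = arr
        self.source = source

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventList)
            and self.intervals.shape == other.intervals.shape
            and np.allclose(self.intervals, other.intervals)
        )

    def __repr__(self) -> str:
        return f"EventList(n={len(self)}, source={self.source!r})"

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def to_mask(self, fs: float, n_samples: int) -> np.ndarray:
        """Rasterise onto a boolean sample grid at rate ``fs``."""
        mask = np.zeros(n_samples, dtype=bool)
        for onset, offset in self.intervals:
            i0 = int(round(onset * fs))
            i1 = int(round(offset * fs))
            mask[max(i0, 0): min(i1, n_samples)] = True
        return mask

    @classmethod
    def from_mask(cls, mask: np.ndarray, fs: float, source: str = "") -> "EventList":
        """Maximal runs of True become half-open intervals in seconds."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0:
            return cls(source=source)
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        return cls(
            [(s / fs, e / fs) for s, e in zip(starts, stops)], source=source
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.intervals[:, 0],
                "offset_s": self.intervals[:, 1],
                "duration_s": self.durations,
                "source": self.source or "",
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventList":
        source = ""
        if "source" in df.columns and len(df):
            source = str(df["source"].iloc[0])
        return cls(zip(df["onset_s"], df["offset_s"]), source=source)
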