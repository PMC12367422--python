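"""Core in-memory containers for multichannel intracranial EEG.

A :class:`Recording` holds a channels x samples matrix in microvolts together
with the sampling rate and a per-sample wake mask.  A :class:`ChannelRecord`
carries the per-contact metadata the analysis needs: 3-D position (mm) and the
gray-matter / seizure-onset-zone / resected flags.  Detected events travel as
pandas DataFrames (see :mod:`spikewave.ied` and :mod:`spikewave.lows`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns every event table carries.
EVENT_COLUMNS = ["channel", "kind", "peak_t"]


@dataclass
class Recording:
    """Multichannel signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel names, one per row of ``data``.
    t0 : float
        Time of the first sample in seconds.
    segment_kind : str
        One of ``interictal``, ``preictal``, ``ictal``.
    wake_mask : ndarray of bool or None
        Per-sample wakefulness flag.  ``None`` means "all samples eligible".
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    t0: float = 0.0
    segment_kind: str = "interictal"
    wake_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match number of rows")
        if not np.isfinite(self.data).all():
            raise ValueError("signal contains NaN or infinite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.wake_mask is not None:
            self.wake_mask = np.asarray(self.wake_mask, dtype=bool)
            if self.wake_mask.shape != (self.data.shape[1],):
                raise ValueError("wake_mask must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (s), clipped into the recording."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n_samples - 1)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def wake(self) -> np.ndarray:
        """Wake mask, defaulting to all-true."""
        if self.wake_mask is None:
            return np.ones(self.n_samples, dtype=bool)
        return self.wake_mask

    def wake_segments(self) -> list[tuple[float, float]]:
        """Contiguous wake runs as half-open ``[start, end)`` intervals in s."""
        mask = self.wake().astype(int)
        edges = np.flatnonzero(np.diff(np.r_[0, mask, 0]))
        starts, ends = edges[::2], edges[1::2]
        return [
            (self.t0 + s / self.fs, self.t0 + e / self.fs)
            for s, e in zip(starts, ends)
        ]

    def wake_minutes(self) -> float:
        return float(self.wake().sum()) / self.fs / 60.0

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            wake_mask=None if self.wake_mask is None else self.wake_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ChannelRecord:
    """Per-contact metadata: position and clinical flags."""

    name: str
    xyz: tuple[float, float, float]
    gray: bool = True
    soz: bool = False
    resected: bool = False

    def __post_init__(self) -> None:
        if len(self.xyz) != 3 or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be three finite coordinates (mm)")


def channels_to_frame(channels: list[ChannelRecord]) -> pd.DataFrame:
    rows = [
        {
            "name": c.name,
            "x": c.xyz[0],
            "y": c.xyz[1],
            "z": c.xyz[2],
            "gray": bool(c.gray),
            "soz": bool(c.soz),
            "resected": bool(c.resected),
        }
        for c in channels
    ]
    return pd.DataFrame(rows, columns=["name", "x", "y", "z", "gray", "soz", "resected"])


def frame_to_channels(df: pd.DataFrame) -> list[ChannelRecord]:
    required = {"name", "x", "y", "z", "gray", "soz", "resected"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"channel table missing columns: {sorted(missing)}")
    return [
        ChannelRecord(
            name=str(r["name"]),
            xyz=(float(r["x"]), float(r["y"]), float(r["z"])),
            gray=bool(r["gray"]),
            soz=bool(r["soz"]),
            resected=bool(r["resected"]),
        )
        for _, r in df.iterrows()
    ]


def empty_events() -> pd.DataFrame:
    """Empty event table with the canonical columns."""
    return pd.DataFrame(
        {
            "channel": pd.Series(dtype=str),
            "kind": pd.Series(dtype=str),
            "peak_t": pd.Series(dtype=float),
        }
    )


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    return events.sort_values(["channel", "peak_t"], kind="mergesort").reset_index(drop=True)
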