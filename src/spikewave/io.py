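"""Reading, writing and preprocessing of recordings and metadata tables.

Signals travel as EDF (16-bit European Data Format); metadata as
tab-separated tables in the BIDS-iEEG dialect (``channels.tsv``,
``events.tsv``, ``participants.tsv``).  EDF reading goes through MNE-Python;
writing uses a minimal EDF writer (one data record per second, 16-bit).

Preprocessing covers the 60-Hz notch (zero-phase, so event peak latencies are
preserved), artifact-channel exclusion, and the alpha/delta wake mask.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .recording import ChannelRecord, Recording, frame_to_channels, channels_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "write_edf",
    "read_recording",
    "notch_filter",
    "wake_mask",
    "drop_artifact_channels",
    "write_events_tsv",
    "read_events_tsv",
    "load_config",
]

ACCEPTED_FS_MIN = 500.0

CHANNEL_COLUMNS = ["name", "x", "y", "z", "gray", "soz", "resected"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt8(value: float) -> str:
    """A float in at most 8 ASCII characters (EDF header numeric field)."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    return ("%.1g" % value)[:8]


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (microvolt units, 1-s data records).

    The sampling rate must be a whole number of samples per second; the
    signal is truncated to whole seconds (EDF stores complete data records).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    pmins, pmaxs, digital = [], [], []
    for ch in range(nch):
        x = data[ch]
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        margin = 0.01 * (hi - lo)
        # round the printed limits first, then scale with the printed values,
        # so reader and writer use identical calibration
        pmin = float(_fmt8(lo - margin))
        pmax = float(_fmt8(hi + margin))
        if pmax <= pmin:
            pmax = pmin + 1.0
        scale = 65535.0 / (pmax - pmin)
        d = np.round((x - pmin) * scale - 32768.0)
        digital.append(np.clip(d, -32768, 32767).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (nch + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(nch), 4),
        ]
    )
    fields = [
        (16, [f"EEG {name}"[:16] for name in rec.ch_names]),
        (80, [""] * nch),
        (8, ["uV"] * nch),
        (8, [_fmt8(p) for p in pmins]),
        (8, [_fmt8(p) for p in pmaxs]),
        (8, ["-32768"] * nch),
        (8, ["32767"] * nch),
        (80, [""] * nch),
        (8, [str(spr)] * nch),
        (32, [""] * nch),
    ]
    sig_header = b"".join(b"".join(_pad(v, w) for v in vals) for w, vals in fields)

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for ch in range(nch):
                fh.write(digital[ch][r * spr : (r + 1) * spr].tobytes())
    return path


def read_recording(
    signal_path: str | Path, channels_path: str | Path, drop_non_gray: bool = True
) -> tuple[Recording, list[ChannelRecord]]:
    """Read an EDF signal file plus its ``channels.tsv``.

    Channel names in the TSV must match the EDF header.  Channels flagged
    non-gray-matter are dropped.  Sampling frequencies below 500 Hz are
    rejected (low-rate recordings, e.g. 256 Hz, cannot support the 45-130 Hz
    analyses and are excluded to harmonise the pipeline).
    """
    import mne

    raw = mne.io.read_raw_edf(str(signal_path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if fs < ACCEPTED_FS_MIN:
        raise ValueError(
            f"sampling frequency {fs:g} Hz rejected: below {ACCEPTED_FS_MIN:g} Hz "
            "(e.g. 256 Hz recordings are excluded)"
        )
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    table = pd.read_csv(channels_path, sep="\t")
    missing = set(CHANNEL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"channels.tsv missing columns: {sorted(missing)}")
    tsv_names = [str(n) for n in table["name"]]
    if set(tsv_names) != set(names):
        raise ValueError("channel names in channels.tsv do not match the EDF header")
    channels = frame_to_channels(table)
    by_name = {c.name: c for c in channels}
    keep = [n for n in names if (by_name[n].gray or not drop_non_gray)]
    dropped = [n for n in names if n not in keep]
    if dropped:
        logger.info("read_recording: dropped non-gray channels %s", dropped)
    data = raw.get_data(picks=[names.index(n) for n in keep]) * 1e6  # V -> uV
    if np.isnan(data).any():
        raise ValueError("signal contains NaN after ingest")
    rec = Recording(data=data, fs=fs, ch_names=keep)
    return rec, [by_name[n] for n in keep]


def write_channels_tsv(channels: list[ChannelRecord], path: str | Path) -> Path:
    path = Path(path)
    channels_to_frame(channels).to_csv(path, sep="\t", index=False)
    return path


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    """Events in the BIDS dialect: onset (s), duration, channel, kind + extras."""
    path = Path(path)
    out = events.copy()
    out.insert(0, "onset", out.pop("peak_t"))
    if "duration" not in out.columns:
        out.insert(1, "duration", 0.0)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def write_participants_tsv(patients: pd.DataFrame, path: str | Path) -> Path:
    """Patient-level table: id, Engel/ILAE outcome, lesional status, therapy."""
    path = Path(path)
    cols = [c for c in ("patient", "engel_class", "engel_linear", "ilae", "good",
                        "lesional", "therapy") if c in patients.columns]
    patients[cols].to_csv(path, sep="\t", index=False)
    return path


def read_participants_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    df = df.rename(columns={"onset": "peak_t"})
    return df


def notch_filter(rec: Recording, line_hz: float = 60.0, q: float = 30.0) -> Recording:
    """Zero-phase second-order IIR notch at the line frequency.

    Zero-phase (forward-backward) filtering preserves event peak latencies,
    on which all delay statistics depend.
    """
    if rec.fs <= 2 * line_hz:
        raise ValueError(f"fs={rec.fs:g} Hz too low for a {line_hz:g} Hz notch")
    b, a = sps.iirnotch(line_hz, q, fs=rec.fs)
    out = rec.copy()
    out.data = sps.filtfilt(b, a, out.data, axis=1)
    return out


def _window_bandpowers(data: np.ndarray, fs: float, lo: float, hi: float) -> float:
    f, psd = sps.periodogram(data, fs=fs, axis=-1)
    sel = (f >= lo) & (f <= hi)
    return float(psd[..., sel].sum(axis=-1).mean())


def wake_mask(
    rec: Recording, win_s: float = 10.0, ratio_threshold: float = 1.0
) -> np.ndarray:
    """Alpha/delta wakefulness mask, constant within windows.

    A window is wake when bandpower(8-12 Hz) / bandpower(0.5-4 Hz), averaged
    over channels, exceeds ``ratio_threshold``.
    """
    if win_s < 2.0:
        raise ValueError("wake-mask window must be at least 2 s")
    n_win = int(round(win_s * rec.fs))
    if n_win > rec.n_samples:
        raise ValueError("wake-mask window longer than the recording")
    mask = np.zeros(rec.n_samples, dtype=bool)
    for start in range(0, rec.n_samples, n_win):
        seg = rec.data[:, start : start + n_win]
        if seg.shape[1] < int(2 * rec.fs):
            # trailing stub shorter than the minimum window: copy the
            # previous decision
            mask[start:] = mask[start - 1] if start else False
            break
        alpha = _window_bandpowers(seg, rec.fs, 8.0, 12.0)
        delta = _window_bandpowers(seg, rec.fs, 0.5, 4.0)
        ratio = np.inf if delta == 0 else alpha / delta
        mask[start : start + n_win] = ratio > ratio_threshold
    return mask


def drop_artifact_channels(
    rec: Recording,
    channels: list[ChannelRecord] | None = None,
    flat_frac: float = 0.2,
    huge_uv: float = 1000.0,
    huge_frac: float = 0.01,
):
    """Drop channels with a flatline fraction > ``flat_frac`` or amplitude
    above ``huge_uv`` microvolts for more than ``huge_frac`` of samples."""
    keep_idx = []
    dropped = []
    for ci, name in enumerate(rec.ch_names):
        x = rec.data[ci]
        flat = np.mean(np.diff(x) == 0)
        huge = np.mean(np.abs(x) > huge_uv)
        if flat > flat_frac or huge > huge_frac:
            dropped.append(name)
        else:
            keep_idx.append(ci)
    if dropped:
        logger.info("drop_artifact_channels: dropped %s", dropped)
    out = Recording(
        data=rec.data[keep_idx],
        fs=rec.fs,
        ch_names=[rec.ch_names[i] for i in keep_idx],
        t0=rec.t0,
        segment_kind=rec.segment_kind,
        wake_mask=None if rec.wake_mask is None else rec.wake_mask.copy(),
        meta=dict(rec.meta),
    )
    if channels is None:
        return out, dropped
    kept_names = set(out.ch_names)
    return out, [c for c in channels if c.name in kept_names], dropped


def load_config(path: str | Path) -> dict:
    """Load a YAML parameter file holding pipeline thresholds."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping of parameters")
    return cfg
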