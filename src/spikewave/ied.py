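"""Interictal epileptiform discharge (IED) detection.

Hilbert-envelope detector: the signal is band-passed to 20-80 Hz, candidate
events are supra-threshold excursions of the Hilbert envelope (3.5x its mean
over the wake portion of the recording), and candidates are discarded when
their amplitude in the 5-Hz high-passed raw signal falls below 4x that
signal's mean envelope.  Sequences of IEDs closer than 0.2 s form bursts, of
which only the first event is retained.

All thresholds are ratios to per-channel mean envelopes, so detection is
invariant to global signal rescaling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording, empty_events, sort_events

logger = logging.getLogger(__name__)

__all__ = ["detect_ieds", "collapse_bursts"]

BAND_HZ = (20.0, 80.0)
HP_HZ = 5.0
ENV_FACTOR = 3.5
RAW_FACTOR = 4.0
MERGE_GAP_S = 0.04
BURST_GAP_S = 0.2
#: moving-average smoothing of the envelope before thresholding; an IED's
#: envelope is sustained over its ~60 ms core, while band-limited noise
#: excursions last ~1/bandwidth (~15 ms) and are strongly attenuated
ENV_SMOOTH_S = 0.015


def _excursions(above: np.ndarray, merge_gap: int):
    """Supra-threshold runs; runs separated by < merge_gap samples merged."""
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    starts, ends = list(edges[::2]), list(edges[1::2])
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def detect_ieds(
    rec: Recording,
    env_factor: float = ENV_FACTOR,
    raw_factor: float = RAW_FACTOR,
    merge_gap_s: float = MERGE_GAP_S,
    env_smooth_s: float = ENV_SMOOTH_S,
) -> pd.DataFrame:
    """Detect IED candidates on every channel of a wake-masked recording.

    Returns a DataFrame with columns channel, kind, peak_t, polarity,
    amplitude (microvolts, measured on the 5-Hz high-passed signal) and
    env_ratio (peak envelope over mean envelope).
    """
    if rec.fs < 500:
        raise ValueError("IED detection requires fs >= 500 Hz")
    wake = rec.wake()
    if not wake.any():
        logger.warning("detect_ieds: no wake samples; returning empty result")
        return empty_events()
    sos_band = signal.butter(4, BAND_HZ, btype="bandpass", fs=rec.fs, output="sos")
    sos_hp = signal.butter(4, HP_HZ, btype="highpass", fs=rec.fs, output="sos")
    merge_gap = max(int(round(merge_gap_s * rec.fs)), 1)
    # the candidate's raw amplitude is read peak-to-peak over the discharge:
    # a causal window covering the spike and its after-going wave
    pre_meas = int(round(0.04 * rec.fs))
    post_meas = int(round(0.13 * rec.fs))

    rows = []
    for ci, name in enumerate(rec.ch_names):
        x = rec.data[ci]
        if np.ptp(x) == 0:
            continue  # flat channel: no events
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos_band, x)))
        if env_smooth_s > 0:
            w = max(int(round(env_smooth_s * rec.fs)), 1)
            env = signal.convolve(env, np.ones(w) / w, mode="same")
        mean_env = env[wake].mean()
        if mean_env == 0:
            continue
        hp = signal.sosfiltfilt(sos_hp, x)
        mean_env_hp = np.abs(signal.hilbert(hp))[wake].mean()
        above = (env > env_factor * mean_env) & wake
        for s, e in _excursions(above, merge_gap):
            k = s + int(np.argmax(env[s:e]))  # argmax ties break to the earlier sample
            a, b = max(k - pre_meas, 0), min(k + post_meas + 1, len(x))
            j = a + int(np.argmax(np.abs(hp[a:b])))
            # candidate amplitude: conventional peak-to-peak of the discharge
            raw_amp = float(hp[a:b].max() - hp[a:b].min())
            if raw_amp < raw_factor * mean_env_hp:
                continue
            rows.append(
                {
                    "channel": name,
                    "kind": "IED",
                    "peak_t": rec.t0 + k / rec.fs,
                    "polarity": "+" if hp[j] > 0 else "-",
                    "amplitude": raw_amp,
                    "env_ratio": env[k] / mean_env,
                }
            )
    df = pd.DataFrame(
        rows, columns=["channel", "kind", "peak_t", "polarity", "amplitude", "env_ratio"]
    )
    return sort_events(df)


def collapse_bursts(events: pd.DataFrame, gap_s: float = BURST_GAP_S) -> pd.DataFrame:
    """Collapse each burst to its first event.

    A burst is a chain of same-channel events in which every event follows
    the previous one within ``gap_s`` (gap-based chaining).  Events get a
    ``burst_id`` and only the first per burst is kept.  Idempotent.
    """
    if events.empty:
        out = events.copy()
        out["burst_id"] = pd.Series(dtype=int)
        return out
    events = sort_events(events)
    burst_id = np.zeros(len(events), dtype=int)
    next_id = 0
    prev_ch, prev_t = None, None
    for i, (_, row) in enumerate(events.iterrows()):
        if prev_ch == row["channel"] and (row["peak_t"] - prev_t) <= gap_s:
            burst_id[i] = burst_id[i - 1]
        else:
            burst_id[i] = next_id
            next_id += 1
        prev_ch, prev_t = row["channel"], row["peak_t"]
    out = events.copy()
    out["burst_id"] = burst_id
    first = out.groupby("burst_id", as_index=False).head(1)
    return first.reset_index(drop=True)
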