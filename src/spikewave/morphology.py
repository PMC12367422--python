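"""Morphological separability of detected IEDs and slow waves.

Each event is summarised by three waveform features — amplitude, rising slope
(half-maximum to maximum) and descending slope (maximum to half-maximum) —
measured on the band-limited waveform its detector used (IEDs: 5-Hz
high-passed; LoWS: 0.5-4 Hz).  Per patient, the standardised features are
partitioned into two clusters (k-means, fixed seed, best of 20 restarts) and
separability is summarised as the odds ratio of the cluster x true-kind
table; across patients a one-sample Wilcoxon tests the odds ratios against 1.

The module asserts statistical separability of the detected event sets, not
biological distinctness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal, stats as sst

from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = ["waveform_features", "cluster_separability"]


def _band_limited(rec: Recording, kind: str) -> dict:
    if kind == "IED":
        sos = signal.butter(4, 5.0, btype="highpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(4, [0.5, 4.0], btype="bandpass", fs=rec.fs, output="sos")
    return {ch: signal.sosfiltfilt(sos, rec.channel(ch)) for ch in rec.ch_names}


def _slopes(x: np.ndarray, fs: float, k: int, max_lag: int):
    """Rise and fall slope around sample ``k`` of waveform ``x`` (signed
    peak); None when the half-maximum is not crossed within ``max_lag``."""
    peak = x[k]
    sign = 1.0 if peak >= 0 else -1.0
    half = abs(peak) / 2.0
    xa = sign * x  # positive-peak orientation
    i = k
    while i > max(k - max_lag, 0) and xa[i - 1] >= half:
        i -= 1
    if xa[max(i - 1, 0)] > half and i > 0:
        return None  # never dropped below half-maximum on the ascending limb
    if i == k:
        i = k - 1
    j = k
    hi = min(k + max_lag, len(x) - 1)
    while j < hi and xa[j + 1] >= half:
        j += 1
    if j < len(x) - 1 and xa[j + 1] > half:
        return None
    if j == k:
        j = k + 1
    rise = (abs(peak) - half) / ((k - i) / fs)
    fall = (abs(peak) - half) / ((j - k) / fs)
    return rise, fall


def waveform_features(events: pd.DataFrame, rec: Recording) -> pd.DataFrame:
    """Amplitude and half-maximum slopes for every event.

    Events whose peak lies within 1 s of a recording edge, or whose waveform
    does not cross half-maximum within 1 s of the peak, are skipped (logged).
    Returns patient-agnostic rows: channel, kind, peak_t, amplitude,
    rise_slope, fall_slope.
    """
    max_lag = int(round(1.0 * rec.fs))
    filtered = {k: _band_limited(rec, k) for k in set(events["kind"])}
    rows, n_skip = [], 0
    for _, ev in events.iterrows():
        ch, kind, t = ev["channel"], ev["kind"], float(ev["peak_t"])
        if t - rec.t0 < 1.0 or rec.t0 + rec.duration - t < 1.0:
            n_skip += 1
            continue
        x = filtered[kind][ch]
        i0 = rec.index_of(t)
        # re-locate the extremum on this band-limited waveform
        r = int(round(0.05 * rec.fs)) if kind == "IED" else int(round(0.25 * rec.fs))
        a, b = max(i0 - r, 0), min(i0 + r + 1, len(x))
        k = a + int(np.argmax(np.abs(x[a:b])))
        out = _slopes(x, rec.fs, k, max_lag)
        if out is None:
            n_skip += 1
            continue
        rise, fall = out
        rows.append(
            {
                "channel": ch,
                "kind": kind,
                "peak_t": t,
                "amplitude": float(abs(x[k])),
                "rise_slope": float(rise),
                "fall_slope": float(fall),
            }
        )
    if n_skip:
        logger.info("waveform_features: skipped %d events (edges or no half-crossing)", n_skip)
    return pd.DataFrame(
        rows, columns=["channel", "kind", "peak_t", "amplitude", "rise_slope", "fall_slope"]
    )


def _odds_ratio(table: np.ndarray) -> float:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane-Anscombe correction
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def patient_odds_ratio(
    features: pd.DataFrame, min_events: int = 10, seed: int = 0
) -> float | None:
    """Cluster one patient's features and return the separability odds ratio.

    Returns None for degenerate inputs (too few events of either kind, or a
    zero-variance feature).
    """
    from sklearn.cluster import KMeans

    kinds = features["kind"].to_numpy()
    n_ied = int((kinds == "IED").sum())
    n_lows = int((kinds == "LoWS").sum())
    if n_ied < min_events or n_lows < min_events:
        return None
    X = features[["amplitude", "rise_slope", "fall_slope"]].to_numpy(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        logger.info("patient_odds_ratio: zero-variance feature; patient excluded")
        return None
    X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    labels = km.fit_predict(X)
    # orient cluster 0 onto the kind holding its majority: the OR is then
    # invariant to label swaps
    table = np.zeros((2, 2), dtype=int)
    for c in (0, 1):
        table[c, 0] = int(((labels == c) & (kinds == "IED")).sum())
        table[c, 1] = int(((labels == c) & (kinds == "LoWS")).sum())
    if table[0, 0] + table[1, 1] < table[0, 1] + table[1, 0]:
        table = table[::-1]
    return _odds_ratio(table)


def cluster_separability(
    features: pd.DataFrame, min_events: int = 10, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Per-patient clustering odds ratios plus the cohort-level test.

    ``features`` carries patient, kind, amplitude, rise_slope, fall_slope.
    Returns ``(per_patient, cohort)`` where cohort holds the median and IQR
    of the odds ratios and the one-sample Wilcoxon p against 1.
    """
    rows = []
    for pid, grp in features.groupby("patient"):
        orr = patient_odds_ratio(grp, min_events=min_events, seed=seed)
        if orr is None:
            logger.info("cluster_separability: patient %s excluded", pid)
            continue
        rows.append({"patient": pid, "odds_ratio": orr})
    per_patient = pd.DataFrame(rows, columns=["patient", "odds_ratio"])
    cohort: dict = {"n_patients": len(per_patient)}
    if len(per_patient) >= 2:
        ors = per_patient["odds_ratio"].to_numpy()
        cohort["median_or"] = float(np.median(ors))
        cohort["iqr"] = [float(np.percentile(ors, 25)), float(np.percentile(ors, 75))]
        diffs = ors - 1.0
        if np.all(diffs == 0):
            cohort["p"] = 1.0
        else:
            cohort["p"] = float(sst.wilcoxon(diffs[diffs != 0]).pvalue)
    return per_patient, cohort
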