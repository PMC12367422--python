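"""IED-associated high-gamma excitability and its relation to the delay since
the last slow wave.

High-gamma (45-130 Hz) power is the proxy for local neuronal activity: for
each IED a Hanning-taper spectrogram of the +/-3 s peri-event window is
computed, HG power in the +/-50 ms core is log-transformed and normalised to
the pre-event baseline, and the resulting excitability sample is paired with
the waiting time since the last same-channel LoWS.  The association is
quantified by a mixed model with a per-patient random intercept and slope:

    ied_hg ~ 1 + delay + (1 + delay | patient)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .mixed import LmmResult, fit_mixed_model
from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = ["hg_power_timecourse", "ied_excitability", "fit_delay_excitability"]

HG_BAND = (45.0, 130.0)
HALF_WINDOW_S = 3.0
CORE_HALF_S = 0.05
BASELINE_S = (-3.0, -1.0)  # pre-event, outside the IED and its 1-s LoWS exclusion
TAPER_S = 0.2              # 5-Hz frequency resolution
OVERLAP = 0.9


def hg_power_timecourse(
    rec: Recording,
    channel: str,
    peak_t: float,
    half_window: float = HALF_WINDOW_S,
    taper_s: float = TAPER_S,
    overlap: float = OVERLAP,
    band: tuple[float, float] = HG_BAND,
):
    """Hanning-taper spectrogram of the peri-event window, restricted to the
    high-gamma rows.

    Returns ``(times, freqs, power)`` with ``times`` in seconds relative to
    ``peak_t`` and ``power`` of shape (n_freqs, n_times).  Raises
    ``ValueError`` when the event is closer than ``half_window`` to an edge
    (callers skip and log such events).
    """
    fs = rec.fs
    i0 = int(round((peak_t - rec.t0) * fs))
    half = int(round(half_window * fs))
    if i0 - half < 0 or i0 + half > rec.n_samples:
        raise ValueError("event too close to the recording edge")
    x = rec.channel(channel)[i0 - half : i0 + half]
    nper = int(round(taper_s * fs))
    noverlap = int(round(overlap * nper))
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=fs,
        window=signal.windows.hann(nper, sym=False),
        nperseg=nper,
        noverlap=noverlap,
        detrend=False,
        mode="psd",
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return times - half_window, freqs[sel], sxx[sel]


def ied_excitability(
    rec: Recording,
    ied_events: pd.DataFrame,
    lows_events: pd.DataFrame,
    patient: str = "P000",
    core_half_s: float = CORE_HALF_S,
    baseline_s: tuple[float, float] = BASELINE_S,
) -> pd.DataFrame:
    """Per-IED excitability samples.

    ``ied_hg`` is the natural log of mean HG power over the +/-50 ms core
    minus the log of mean HG power over the baseline interval, so 0 means
    "no change from baseline" and the value is invariant to any positive
    rescaling of the raw signal.  ``delay_since_lows`` is the waiting time
    since the last same-channel LoWS; IEDs with no preceding LoWS in the same
    wake segment are censored.
    """
    lows_by_ch = {
        ch: np.sort(g["peak_t"].to_numpy()) for ch, g in lows_events.groupby("channel")
    }
    segments = rec.wake_segments() or [(rec.t0, rec.t0 + rec.duration)]
    rows, n_edge, n_nolows = [], 0, 0
    for _, ev in ied_events.iterrows():
        ch, t = ev["channel"], float(ev["peak_t"])
        peaks = lows_by_ch.get(ch)
        if peaks is None or len(peaks) == 0:
            n_nolows += 1
            continue
        j = np.searchsorted(peaks, t)
        if j == 0:
            n_nolows += 1
            continue
        t_lows = peaks[j - 1]
        seg = [i for i, (s, e) in enumerate(segments) if s <= t < e]
        seg_l = [i for i, (s, e) in enumerate(segments) if s <= t_lows < e]
        if not seg or seg != seg_l:
            n_nolows += 1  # censored: delay crosses a wake-segment boundary
            continue
        try:
            times, _, power = hg_power_timecourse(rec, ch, t)
        except ValueError:
            n_edge += 1
            continue
        core = np.abs(times) <= core_half_s
        base = (times >= baseline_s[0]) & (times <= baseline_s[1])
        if not core.any() or not base.any():
            n_edge += 1
            continue
        rows.append(
            {
                "patient": patient,
                "channel": ch,
                "ied_peak_t": t,
                "ied_hg": float(np.log(power[:, core].mean()) - np.log(power[:, base].mean())),
                "delay_since_lows": t - t_lows,
            }
        )
    if n_edge:
        logger.info("ied_excitability: skipped %d events near edges", n_edge)
    if n_nolows:
        logger.info("ied_excitability: censored %d events without a preceding LoWS", n_nolows)
    if not rows and len(ied_events):
        logger.warning("ied_excitability: every sample censored")
    return pd.DataFrame(
        rows, columns=["patient", "channel", "ied_peak_t", "ied_hg", "delay_since_lows"]
    )


def fit_delay_excitability(samples: pd.DataFrame, min_per_patient: int = 10) -> LmmResult:
    """Mixed model of excitability on delay with random intercept and slope.

    Falls back to a random-intercept-only fit (flagged in ``notes``) when the
    random-slope fit is singular or fails to converge.
    """
    counts = samples.groupby("patient").size()
    if len(counts) < 2:
        raise ValueError("need samples from at least 2 patients")
    if (counts < min_per_patient).any():
        low = counts[counts < min_per_patient]
        raise ValueError(
            f"need >= {min_per_patient} samples per patient; short: {dict(low)}"
        )
    df = samples.rename(columns={"delay_since_lows": "delay"})
    try:
        res = fit_mixed_model(
            df, "ied_hg ~ delay", groups="patient", re_formula="1 + delay"
        )
        if res.singular or not res.converged:
            raise RuntimeError("singular random-slope fit")
    except (RuntimeError, np.linalg.LinAlgError):
        res = fit_mixed_model(df, "ied_hg ~ delay", groups="patient", re_formula="1")
        res.notes.append("random slope dropped (singular fit)")
    return res
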