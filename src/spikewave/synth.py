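"""Synthetic intracranial EEG with ground-truth event logs.

The generator emulates the features of wake iEEG that the detection and
statistics stages consume:

* per-channel 1/f background with a spectral knee and a wake alpha rhythm
  toggled in blocks, so the alpha/delta wake criterion has something to find;
* injected interictal epileptiform discharges (IEDs): a sharp biphasic
  60-ms core carrying 20-80 Hz energy followed by an after-going slow wave,
  scaled relative to the channel's mean 20-80 Hz Hilbert envelope;
* injected local wake slow waves (LoWS): 0.5-4 Hz half-waves of 0.25-1 s
  whose amplitude lands above the channel's candidate-amplitude percentile,
  optionally accompanied by a high-gamma (45-130 Hz) downstate;
* simulated surgical cohorts with per-channel seizure-onset/resection labels,
  Engel outcomes, and a plantable outcome x resection interaction on the
  incidence-corrected IED-to-LoWS delay.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording, Recording as _Recording  # noqa: F401
from .recording import sort_events

__all__ = [
    "SimConfig",
    "CohortSpec",
    "SchedulingError",
    "make_background",
    "inject_events",
    "inject_at",
    "simulate_cohort",
    "ENGEL_CLASSES",
]

ENGEL_CLASSES = ("I", "II", "III", "IV")

#: minimum spacing between any two injected events (s)
MIN_SPACING_S = 0.5
#: minimum spacing between an injected IED and an injected LoWS (s); keeps the
#: 1-s post-IED exclusion rule from silently eating injected slow waves
IED_LOWS_SPACING_S = 1.2
#: events are kept this far from wake-block edges so downstate flanking
#: baselines stay inside wake
EDGE_MARGIN_S = 1.6


class SchedulingError(RuntimeError):
    """Raised when the requested event rates cannot honour the spacing rules."""


@dataclass
class SimConfig:
    """Parameters of a single simulated recording.

    Rates are per *wake* minute; the defaults reproduce typical clinical
    incidence (IEDs ~0.7/min, LoWS ~3.8/min).
    """

    n_channels: int = 10
    fs: float = 512.0
    duration: float = 600.0
    background_slope: float = 1.0
    knee_hz: float = 80.0
    alpha_power: float = 2.0       # added alpha power / background delta power
    background_rms: float = 50.0   # microvolts
    ied_rate: float = 0.71         # events / wake minute
    lows_rate: float = 3.82        # events / wake minute
    ied_amp_factor: float = 5.0    # x mean 20-80 Hz envelope
    lows_percentile_target: float = 90.0
    lows_amp_margin: float = 1.5   # x that percentile of background half-waves
    downstate_depth: float = 0.8   # fractional HG suppression in [0, 1]
    downstate_prob: float = 1.0
    delay_law: tuple | None = None  # e.g. ("exponential", scale_s)
    wake_block_s: float | None = 30.0  # None -> continuously awake
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.fs < 500:
            raise ValueError(
                f"sampling frequency {self.fs} Hz below 500 Hz is not supported"
            )
        if self.ied_rate < 0 or self.lows_rate < 0:
            raise ValueError("event rates must be non-negative")
        if not 0.0 <= self.downstate_depth <= 1.0:
            raise ValueError("downstate_depth must lie in [0, 1]")
        if (self.ied_rate + self.lows_rate) / 60.0 > 1.0 / MIN_SPACING_S:
            raise SchedulingError(
                "requested rates incompatible with the minimum inter-event "
                f"spacing of {MIN_SPACING_S} s"
            )


# ---------------------------------------------------------------------------
# background


def _spectral_noise(rng, n, fs, slope, knee_hz):
    """Gaussian noise with PSD ~ 1/f^slope below the knee, steeper above."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    f = freqs[nz]
    f_lo = 0.1  # flatten below 0.1 Hz: no unbounded drift
    fe = np.maximum(f, f_lo)
    amp[nz] = fe ** (-slope / 2.0)
    above = f > knee_hz
    amp[nz] = np.where(
        above, knee_hz ** (-slope / 2.0) * (f / knee_hz) ** (-(slope + 2) / 2.0), amp[nz]
    )
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _bandpass_noise(rng, n, fs, lo, hi):
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _bandpower_fraction(slope, knee_hz, fs, lo, hi):
    """Relative power of a 1/f^slope-with-knee PSD inside [lo, hi] Hz."""
    f = np.linspace(0.1, fs / 2, 4096)
    psd = np.where(f <= knee_hz, f ** (-slope), knee_hz ** (-slope) * (f / knee_hz) ** (-(slope + 2)))
    sel = (f >= lo) & (f <= hi)
    return np.trapezoid(psd[sel], f[sel]) / np.trapezoid(psd, f)


def wake_schedule(config: SimConfig) -> np.ndarray:
    """Truth wake mask: alternating blocks starting awake."""
    n = int(round(config.duration * config.fs))
    if config.wake_block_s is None:
        return np.ones(n, dtype=bool)
    t = np.arange(n) / config.fs
    block = np.floor(t / config.wake_block_s).astype(int)
    return block % 2 == 0


def make_background(config: SimConfig) -> Recording:
    """Generate the event-free multichannel background.

    The PSD follows 1/f^slope up to ``knee_hz`` with a steeper roll-off above
    (the high-frequency knee typical of intracranial recordings).  During wake
    blocks an 8-12 Hz alpha rhythm is added with ``alpha_power`` times the
    background delta-band (0.5-4 Hz) power, so the alpha/delta ratio separates
    wake from the alpha-free blocks.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    mask = wake_schedule(config)
    delta_frac = _bandpower_fraction(
        config.background_slope, config.knee_hz, config.fs, 0.5, 4.0
    )
    alpha_sd = math.sqrt(config.alpha_power * delta_frac)
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        bg = _spectral_noise(rng, n, config.fs, config.background_slope, config.knee_hz)
        alpha = _bandpass_noise(rng, n, config.fs, 8.0, 12.0) * alpha_sd
        # soft-edged alpha gate so block transitions do not ring
        gate = signal.convolve(
            mask.astype(float), np.ones(int(config.fs) or 1) / int(config.fs), mode="same"
        )
        data[ch] = (bg + alpha * gate) * config.background_rms
    names = [f"CH{ch:03d}" for ch in range(config.n_channels)]
    return Recording(
        data=data,
        fs=config.fs,
        ch_names=names,
        wake_mask=mask,
        meta={"seed": config.seed, "synthetic": True},
    )


# ---------------------------------------------------------------------------
# event templates


def ied_template(fs: float) -> np.ndarray:
    """Spike-and-wave IED template, unit peak 20-80 Hz Hilbert envelope.

    A Mexican-hat core (60 ms, spectral peak ~28 Hz) carries the 20-80 Hz
    energy; an opposite-polarity after-going slow wave (100 ms, 2.2x the core
    peak) supplies the broadband amplitude seen in clinical spike-wave
    complexes.  Total support 150 ms.
    """
    a = 0.008
    t = np.arange(-0.03, 0.12 + 0.5 / fs, 1.0 / fs)
    core = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    core[t > 0.03] = 0.0
    wave = np.zeros_like(t)
    in_wave = (t >= 0.02) & (t <= 0.12)
    wave[in_wave] = -2.2 * np.sin(np.pi * (t[in_wave] - 0.02) / 0.10)
    tpl = core + wave
    # normalise: unit peak of the 20-80 Hz Hilbert envelope
    pad = np.zeros(int(fs))
    padded = np.concatenate([pad, tpl, pad])
    sos = signal.butter(4, [20, 80], btype="bandpass", fs=fs, output="sos")
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, padded)))
    return tpl / env.max()


def _ied_peak_offset(fs: float) -> int:
    """Sample offset of the core peak inside :func:`ied_template`."""
    return int(round(0.03 * fs))


def lows_template(duration: float, fs: float) -> np.ndarray:
    """Raised half-sine slow half-wave of unit raw amplitude."""
    n = max(int(round(duration * fs)), 3)
    return np.sin(np.pi * np.arange(n) / (n - 1))


def _lows_filter_gain(duration: float, fs: float) -> float:
    """Peak amplitude of the 0.5-4 Hz filtered unit half-wave."""
    tpl = lows_template(duration, fs)
    pad = np.zeros(int(3 * fs))
    padded = np.concatenate([pad, tpl, pad])
    sos = signal.butter(4, [0.5, 4.0], btype="bandpass", fs=fs, output="sos")
    return float(np.abs(signal.sosfiltfilt(sos, padded)).max())


# ---------------------------------------------------------------------------
# scheduling


def _eligible_intervals(rec: Recording) -> list[tuple[float, float]]:
    out = []
    for s, e in rec.wake_segments():
        s2, e2 = s + EDGE_MARGIN_S, e - EDGE_MARGIN_S
        if e2 > s2:
            out.append((s2, e2))
    return out


def _draw_times(rng, intervals, rate_per_min, wake_minutes):
    """Homogeneous Poisson times at `rate_per_min` per wake minute, placed
    uniformly over the eligible intervals."""
    if rate_per_min <= 0 or not intervals:
        return np.empty(0)
    n = rng.poisson(rate_per_min * wake_minutes)
    lengths = np.array([e - s for s, e in intervals])
    total = lengths.sum()
    u = rng.uniform(0, total, size=n)
    edges = np.concatenate([[0], np.cumsum(lengths)])
    idx = np.searchsorted(edges, u, side="right") - 1
    times = np.array([intervals[i][0] + (u_ - edges[i]) for i, u_ in zip(idx, u)])
    return np.sort(times)


def _thin_schedule(ied_t, lows_t):
    """Greedy enforcement of the spacing rules; later violator is dropped."""
    events = sorted(
        [(t, "IED") for t in ied_t] + [(t, "LoWS") for t in lows_t]
    )
    kept: list[tuple[float, str]] = []
    for t, kind in events:
        ok = True
        for tp, kp in reversed(kept):
            if t - tp >= IED_LOWS_SPACING_S:
                break
            if t - tp < MIN_SPACING_S or kp != kind:
                ok = False
                break
        if ok:
            kept.append((t, kind))
    ied = np.array([t for t, k in kept if k == "IED"])
    lows = np.array([t for t, k in kept if k == "LoWS"])
    return ied, lows


def make_schedule(rec: Recording, config: SimConfig, rng) -> pd.DataFrame:
    """Event times honouring wake blocks, refractory spacing and, when a
    ``delay_law`` is configured, IED-to-LoWS coupling."""
    intervals = _eligible_intervals(rec)
    wake_min = rec.wake_minutes()
    ied_t = _draw_times(rng, intervals, config.ied_rate, wake_min)

    coupled = np.empty(0)
    background_rate = config.lows_rate
    if config.delay_law is not None and len(ied_t):
        law = config.delay_law
        if law[0] == "exponential":
            draws = IED_LOWS_SPACING_S + rng.exponential(law[1], size=len(ied_t))
        elif law[0] == "gamma":
            draws = IED_LOWS_SPACING_S + rng.gamma(law[1], law[2], size=len(ied_t))
        else:  # pragma: no cover - config validation
            raise ValueError(f"unknown delay law {law[0]!r}")
        coupled = ied_t + draws
        in_elig = np.zeros(len(coupled), dtype=bool)
        for s, e in intervals:
            in_elig |= (coupled >= s) & (coupled < e)
        coupled = coupled[in_elig]
        background_rate = max(config.lows_rate - config.ied_rate, 0.0)

    lows_bg = _draw_times(rng, intervals, background_rate, wake_min)
    lows_t = np.sort(np.concatenate([lows_bg, coupled]))
    ied_t, lows_t = _thin_schedule(ied_t, lows_t)

    rows = []
    for t in ied_t:
        rows.append({"channel": None, "kind": "IED", "peak_t": t})
    for t in lows_t:
        rows.append(
            {
                "channel": None,
                "kind": "LoWS",
                "peak_t": t,
                "duration": rng.uniform(0.3, 0.9),
                "downstate": bool(rng.uniform() < config.downstate_prob),
            }
        )
    df = pd.DataFrame(rows, columns=["channel", "kind", "peak_t", "duration", "downstate"])
    return df.sort_values("peak_t").reset_index(drop=True)


# ---------------------------------------------------------------------------
# injection


def inject_at(rec: Recording, truth: pd.DataFrame, config: SimConfig, rng) -> Recording:
    """Add the events listed in ``truth`` (channel, kind, peak_t, ...) to a
    copy of ``rec``; amplitudes are set relative to each channel's own
    background statistics."""
    from .lows import halfwave_amplitudes  # local import: avoids a cycle

    out = rec.copy()
    fs = rec.fs
    tpl_ied = ied_template(fs)
    off = _ied_peak_offset(fs)
    sos2080 = signal.butter(4, [20, 80], btype="bandpass", fs=fs, output="sos")
    sos_hg = signal.butter(4, [45, 130], btype="bandpass", fs=fs, output="sos")
    wake = rec.wake()

    for ch_name, grp in truth.groupby("channel"):
        ci = rec.ch_names.index(ch_name)
        bg = rec.data[ci]
        env2080 = np.abs(signal.hilbert(signal.sosfiltfilt(sos2080, bg)))
        mean_env = env2080[wake].mean()
        amps = halfwave_amplitudes(bg, fs, wake_mask=wake)
        if len(amps):
            pct = float(np.percentile(amps, config.lows_percentile_target))
        else:
            pct = bg[wake].std()
        hg = None

        for _, ev in grp.iterrows():
            i0 = int(round(ev.peak_t * fs))
            if ev.kind == "IED":
                start = i0 - off
                seg = tpl_ied[max(0, -start): len(tpl_ied) - max(0, start + len(tpl_ied) - rec.n_samples)]
                a, b = max(start, 0), min(start + len(tpl_ied), rec.n_samples)
                pol = 1.0 if rng.uniform() < 0.5 else -1.0
                out.data[ci, a:b] += pol * config.ied_amp_factor * mean_env * seg[: b - a]
            else:
                dur = float(ev.get("duration", 0.5) or 0.5)
                tpl = lows_template(dur, fs)
                gain = _lows_filter_gain(dur, fs)
                target = config.lows_amp_margin * pct
                start = i0 - len(tpl) // 2
                a, b = max(start, 0), min(start + len(tpl), rec.n_samples)
                pol = 1.0 if rng.uniform() < 0.5 else -1.0
                out.data[ci, a:b] += pol * (target / gain) * tpl[a - start: b - start]
                if bool(ev.get("downstate", False)) and config.downstate_depth > 0:
                    if hg is None:
                        hg = signal.sosfiltfilt(sos_hg, bg)
                    w = signal.windows.tukey(b - a, alpha=0.5)
                    out.data[ci, a:b] -= config.downstate_depth * w * hg[a:b]
    return out


def inject_events(rec: Recording, config: SimConfig) -> tuple[Recording, pd.DataFrame]:
    """Schedule and inject IEDs and LoWS on every channel of ``rec``.

    Returns the modified copy and the truth log (one row per injected event,
    sorted by channel then time).
    """
    if rec.duration <= 10.0:
        raise ValueError("recording must be longer than 10 s to inject events")
    rng = np.random.default_rng(config.seed + 1)
    logs = []
    for ch in rec.ch_names:
        sched = make_schedule(rec, config, rng)
        sched["channel"] = ch
        logs.append(sched)
    truth = pd.concat(logs, ignore_index=True)
    if truth.empty:
        return rec.copy(), truth
    out = inject_at(rec, truth, config, rng)
    return out, sort_events(truth)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """A simulated surgical cohort.

    ``planted_interaction`` is the per-Engel-step shift of the corrected
    IED-to-LoWS delay on resected channels relative to nonresected ones
    (dimensionless corrected-delay units); 0 plants the null.
    """

    n_patients: int = 20
    engel_distribution: dict = field(
        default_factory=lambda: {"I": 0.40, "II": 0.20, "III": 0.20, "IV": 0.20}
    )
    frac_resected: float = 0.3
    planted_interaction: float = 0.20
    patient_jitter_sd: float = 0.1
    preictal_s: float = 110.0
    preictal_rate_factors: dict | None = None  # {(kind, "soz"|"esoz"): mult}
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.engel_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("engel_distribution probabilities must sum to 1")
        if not 0.0 < self.frac_resected < 1.0:
            raise ValueError("frac_resected must lie in (0, 1)")


_ENGEL_LINEAR = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}
ENGEL_CENTER = 2.5


def _assign_engel(spec: CohortSpec, rng) -> list[str]:
    """Largest-remainder apportionment of Engel classes, then shuffle."""
    classes = list(spec.engel_distribution)
    quotas = np.array([spec.engel_distribution[c] * spec.n_patients for c in classes])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for i in np.argsort(-rem)[: spec.n_patients - counts.sum()]:
        counts[i] += 1
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng.shuffle(labels)
    good = sum(1 for c in labels if c in ("I", "II"))
    if good < 2 or spec.n_patients - good < 2:
        raise ValueError("need at least 2 patients per outcome class")
    return labels


def _patient_channels(n_channels, rng):
    """Channel coordinates (mm) with a tight cluster so the 10-mm
    seizure-onset rule has members to find."""
    xyz = rng.uniform(0, 60, size=(n_channels, 3))
    n_cl = min(3, n_channels)
    center = rng.uniform(15, 45, size=3)
    xyz[:n_cl] = center + rng.uniform(-4, 4, size=(n_cl, 3))
    return xyz


def _channel_trains(rng, T, lam_i, lam_l, f):
    """IED train plus a LoWS train whose IED-to-next-LoWS waiting times are
    scaled by ``f``.

    The LoWS train has piecewise-constant intensity: ``lam_l / f`` from each
    IED until the next LoWS, ``lam_l`` otherwise.  By memorylessness every
    IED's waiting time to its next LoWS is exactly Exp(lam_l / f), i.e. the
    corrected delay is exactly f * Exp(1); f = 1 recovers a plain Poisson
    train.
    """
    n_ied = rng.poisson(lam_i * T)
    ied = np.sort(rng.uniform(0, T, size=n_ied))
    if lam_l <= 0:
        return ied, np.empty(0)
    lows = []
    t, j, post = 0.0, 0, False
    while True:
        rate = lam_l / f if post else lam_l
        gap = rng.exponential(1.0 / rate)
        if j < n_ied and ied[j] < t + gap:
            t, post = ied[j], True  # memoryless: redraw at the new intensity
            j += 1
            continue
        t = t + gap
        if t >= T:
            break
        lows.append(t)
        post = False
    return ied, np.asarray(lows)


def simulate_cohort(
    spec: CohortSpec, config: SimConfig, render: bool = False
) -> dict:
    """Simulate a cohort at the event level (optionally rendering signals).

    Returns a dict of DataFrames: ``patients``, ``channels``, ``events`` and
    ``wake_minutes``; with ``render=True`` also ``recordings`` (one
    :class:`Recording` per patient, events injected at the logged times).
    """
    rng = np.random.default_rng(spec.seed)
    engel = _assign_engel(spec, rng)
    lam_i = config.ied_rate / 60.0
    lam_l = config.lows_rate / 60.0
    T = config.duration

    pat_rows, ch_rows, ev_rows, wm_rows = [], [], [], []
    recordings = []
    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        e_cls = engel[p]
        e_lin = _ENGEL_LINEAR[e_cls]
        pat_rows.append(
            {
                "patient": pid,
                "engel_class": e_cls,
                "engel_linear": e_lin,
                "ilae": min(6, int(round(e_lin * 1.4 + rng.integers(0, 2)))),
                "good": e_cls in ("I", "II"),
                "lesional": bool(rng.uniform() < 0.5),
                "therapy": "resection" if rng.uniform() < 0.7 else "ablation",
            }
        )
        xyz = _patient_channels(config.n_channels, rng)
        names = [f"CH{c:03d}" for c in range(config.n_channels)]
        onset = names[0]
        dist = np.linalg.norm(xyz - xyz[0], axis=1)
        soz = dist <= 10.0
        n_res = max(1, int(round(spec.frac_resected * config.n_channels)))
        n_res = min(n_res, config.n_channels - 1)
        order = np.argsort(~soz + rng.uniform(0, 0.1, config.n_channels))
        resected = np.zeros(config.n_channels, dtype=bool)
        resected[order[:n_res]] = True

        f_pat = float(np.exp(rng.normal(0.0, spec.patient_jitter_sd)))
        delta = spec.planted_interaction * (e_lin - ENGEL_CENTER)
        truth_rows = []
        for c, name in enumerate(names):
            ch_rows.append(
                {
                    "patient": pid,
                    "channel": name,
                    "x": xyz[c, 0],
                    "y": xyz[c, 1],
                    "z": xyz[c, 2],
                    "gray": True,
                    "soz": bool(soz[c]),
                    "resected": bool(resected[c]),
                    "onset": name == onset,
                }
            )
            f = f_pat * (1.0 + delta) if resected[c] else f_pat
            f = max(f, 0.05)
            ied, lows = _channel_trains(rng, T, lam_i, lam_l, f)
            for t in ied:
                ev_rows.append(
                    {"patient": pid, "channel": name, "kind": "IED",
                     "peak_t": t, "period": "interictal", "downstate": False}
                )
            for t in lows:
                ev_rows.append(
                    {"patient": pid, "channel": name, "kind": "LoWS",
                     "peak_t": t, "period": "interictal", "downstate": True}
                )
            wm_rows.append(
                {"patient": pid, "channel": name, "period": "interictal",
                 "minutes": T / 60.0}
            )
            if spec.preictal_rate_factors is not None:
                region = "soz" if soz[c] else "esoz"
                fac = spec.preictal_rate_factors
                Tp = spec.preictal_s
                for kind, lam in (("IED", lam_i), ("LoWS", lam_l)):
                    mult = fac.get((kind, region), 1.0)
                    n = rng.poisson(lam * mult * Tp)
                    for t in np.sort(rng.uniform(0, Tp, size=n)):
                        ev_rows.append(
                            {"patient": pid, "channel": name, "kind": kind,
                             "peak_t": t, "period": "preictal",
                             "downstate": kind == "LoWS"}
                        )
                wm_rows.append(
                    {"patient": pid, "channel": name, "period": "preictal",
                     "minutes": Tp / 60.0}
                )
            if render and (len(ied) or len(lows)):
                for t in ied:
                    truth_rows.append({"channel": name, "kind": "IED", "peak_t": t,
                                       "duration": np.nan, "downstate": False})
                for t in lows:
                    truth_rows.append({"channel": name, "kind": "LoWS", "peak_t": t,
                                       "duration": rng.uniform(0.3, 0.9),
                                       "downstate": True})
        if render:
            cfg_p = SimConfig(
                n_channels=config.n_channels,
                fs=config.fs,
                duration=config.duration,
                background_slope=config.background_slope,
                alpha_power=config.alpha_power,
                ied_rate=config.ied_rate,
                lows_rate=config.lows_rate,
                ied_amp_factor=config.ied_amp_factor,
                downstate_depth=config.downstate_depth,
                wake_block_s=None,
                seed=spec.seed * 1009 + p,
            )
            rec = make_background(cfg_p)
            truth_p = pd.DataFrame(
                truth_rows, columns=["channel", "kind", "peak_t", "duration", "downstate"]
            )
            rec = inject_at(rec, truth_p, cfg_p, np.random.default_rng(cfg_p.seed + 1))
            rec.meta["patient"] = pid
            recordings.append(rec)

    out = {
        "patients": pd.DataFrame(pat_rows),
        "channels": pd.DataFrame(ch_rows),
        "events": pd.DataFrame(
            ev_rows,
            columns=["patient", "channel", "kind", "peak_t", "period", "downstate"],
        ).sort_values(["patient", "channel", "peak_t"]).reset_index(drop=True),
        "wake_minutes": pd.DataFrame(wm_rows),
    }
    if render:
        out["recordings"] = recordings
    return out
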