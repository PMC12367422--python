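"""Self-contained simulation studies over the full pipeline.

Each function runs a complete, seeded experiment — generate synthetic data,
run the relevant pipeline stage, measure performance — and returns a dict of
scalar results.  They are shared by the test suite and by the repository's
acceptance script, so the numbers those two report are produced by the same
code paths.

Problem sizes are chosen so every study finishes in minutes on one core; see
the package methods notes for the rationale behind each default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .classify import patient_ratio_metric, train_validate
from .excitability import fit_delay_excitability
from .ied import collapse_bursts, detect_ieds
from .interplay import (
    cohort_outcome_table,
    corrected_delays,
    event_rates,
    pairwise_delays,
)
from .lows import detect_lows
from .stats import fit_outcome_lmm
from .synth import CohortSpec, SimConfig, inject_events, make_background, simulate_cohort

__all__ = [
    "detector_recovery",
    "corrected_delay_calibration",
    "interaction_calibration",
    "excitability_recovery",
    "classifier_evaluation",
    "classifier_null_uniformity",
    "clustering_separability_study",
]


def _match_counts(truth: pd.DataFrame, detected: pd.DataFrame, kind: str, tol_s: float):
    """Hits among injected events of ``kind`` and detector false positives."""
    tk = truth[truth["kind"] == kind]
    det_by_ch = {ch: g["peak_t"].to_numpy() for ch, g in detected.groupby("channel")}
    hits = 0
    for _, ev in tk.iterrows():
        d = det_by_ch.get(ev["channel"])
        if d is not None and len(d) and np.min(np.abs(d - ev["peak_t"])) <= tol_s:
            hits += 1
    truth_by_ch = {ch: g["peak_t"].to_numpy() for ch, g in tk.groupby("channel")}
    fp = 0
    for _, ev in detected.iterrows():
        t = truth_by_ch.get(ev["channel"])
        if t is None or len(t) == 0 or np.min(np.abs(t - ev["peak_t"])) > tol_s:
            fp += 1
    return hits, len(tk), fp


def detector_recovery(
    seed: int, n_channels: int = 10, duration: float = 600.0, ied_amp_factor: float = 5.0
) -> dict:
    """Detector recovery on a simulated recording with ground truth.

    Runs the IED detector and the full LoWS chain on one recording with
    downstates, plus a second recording injected *without* downstates to
    measure how often the gate rejects them.
    """
    cfg = SimConfig(
        n_channels=n_channels, duration=duration, ied_amp_factor=ied_amp_factor, seed=seed
    )
    rec, truth = inject_events(make_background(cfg), cfg)
    ieds = collapse_bursts(detect_ieds(rec))
    lows = detect_lows(rec, ieds)
    ied_hits, ied_n, ied_fp = _match_counts(truth, ieds, "IED", 0.05)
    lows_hits, lows_n, _ = _match_counts(truth, lows, "LoWS", 0.25)
    wake_channel_minutes = rec.wake_minutes() * n_channels

    cfg0 = SimConfig(
        n_channels=n_channels,
        duration=duration,
        ied_amp_factor=ied_amp_factor,
        downstate_prob=0.0,
        seed=seed + 500,
    )
    rec0, truth0 = inject_events(make_background(cfg0), cfg0)
    lows0 = detect_lows(rec0, collapse_bursts(detect_ieds(rec0)))
    nd_hits, nd_n, _ = _match_counts(truth0, lows0, "LoWS", 0.25)
    return {
        "ied_recall": ied_hits / ied_n if ied_n else np.nan,
        "ied_fp_per_min": ied_fp / wake_channel_minutes,
        "lows_recall": lows_hits / lows_n if lows_n else np.nan,
        "nondownstate_rejection": 1.0 - nd_hits / nd_n if nd_n else np.nan,
        "detected_ied_rate_per_min": len(ieds) / wake_channel_minutes,
        "detected_lows_rate_per_min": len(lows) / wake_channel_minutes,
        "n_ied_injected": ied_n,
        "n_lows_injected": lows_n,
    }


def _poisson_trains(rng, T, ied_rate, lows_rate):
    ied = np.sort(rng.uniform(0, T, rng.poisson(ied_rate / 60.0 * T)))
    lows = np.sort(rng.uniform(0, T, rng.poisson(lows_rate / 60.0 * T)))
    ieds = pd.DataFrame({"channel": "A", "kind": "IED", "peak_t": ied})
    lo = pd.DataFrame({"channel": "A", "kind": "LoWS", "peak_t": lows})
    return ieds, lo


def corrected_delay_calibration(
    seed: int,
    n_runs: int = 100,
    duration_s: float = 3600.0,
    ied_rate: float = 0.71,
    lows_rate: float = 3.82,
) -> dict:
    """Calibration of the incidence-corrected delay on independent Poisson
    trains.

    For a homogeneous Poisson target train the corrected delay is Exp(1)
    with median ln 2; the study measures the mean per-run median and, per
    run, tests distributional invariance under 2x thinning of the target
    train (two-sample KS).
    """
    rng = np.random.default_rng(seed)
    medians, ks_pass = [], 0
    for _ in range(n_runs):
        ieds, lo = _poisson_trains(rng, duration_s, ied_rate, lows_rate)
        rates = event_rates(pd.concat([ieds, lo]), duration_s / 60.0)
        corr = corrected_delays(pairwise_delays(ieds, lo), rates)
        if corr.empty:
            continue
        medians.append(float(corr["corrected_delay"].median()))
        keep = rng.uniform(size=len(lo)) < 0.5
        lo2 = lo[keep].reset_index(drop=True)
        rates2 = event_rates(pd.concat([ieds, lo2]), duration_s / 60.0)
        corr2 = corrected_delays(pairwise_delays(ieds, lo2), rates2)
        p = sst.ks_2samp(corr["corrected_delay"], corr2["corrected_delay"]).pvalue
        ks_pass += p > 0.05
    medians = np.asarray(medians)
    return {
        "mean_median_corrected_delay": float(medians.mean()),
        "se": float(medians.std(ddof=1) / np.sqrt(len(medians))),
        "ks_invariance_pass_rate": ks_pass / n_runs,
        "n_runs": len(medians),
        "ln2": float(np.log(2.0)),
    }


def _interaction_p(seed: int, planted: float, n_patients: int, cfg: SimConfig) -> float:
    spec = CohortSpec(n_patients=n_patients, planted_interaction=planted, seed=seed)
    tab = cohort_outcome_table(simulate_cohort(spec, cfg))
    return fit_outcome_lmm(tab, "eq4")["engel:resection"].p


def interaction_calibration(
    seed: int,
    n_null: int = 500,
    n_power: int = 200,
    n_patients: int = 20,
    n_channels: int = 20,
    duration: float = 600.0,
) -> dict:
    """Type-I error and power of the Engel x resection interaction test.

    Null cohorts plant no effect; power cohorts plant the generator's default
    interaction.  Scaled-down cohorts (20 patients x 20 channels) keep the
    study within minutes.
    """
    cfg = SimConfig(n_channels=n_channels, duration=duration)
    base = int(seed) * 100003 % (2**31 - 1)
    null_p = np.array(
        [_interaction_p(base + i, 0.0, n_patients, cfg) for i in range(n_null)]
    )
    planted = CohortSpec().planted_interaction
    pow_p = np.array(
        [_interaction_p(base + 50000 + i, planted, n_patients, cfg) for i in range(n_power)]
    )
    return {
        "type1_error": float(np.mean(null_p < 0.05)),
        "power": float(np.mean(pow_p < 0.05)),
        "planted_interaction": planted,
        "n_null": n_null,
        "n_power": n_power,
    }


def _excitability_samples(rng, beta, n_patients=10, n_per=30, tau=0.01, sigma=0.3):
    rows = []
    for pid in range(n_patients):
        b0 = rng.normal(0.0, 0.3)
        b1 = rng.normal(beta, tau)
        d = rng.exponential(15.0, n_per) + 1.0  # delays exceed the 1-s exclusion
        for x in d:
            rows.append(
                {
                    "patient": f"P{pid:03d}",
                    "delay_since_lows": x,
                    "ied_hg": b0 + b1 * x + rng.normal(0.0, sigma),
                }
            )
    return pd.DataFrame(rows)


def excitability_recovery(
    seed: int, n_sims: int = 100, beta: float = 0.03
) -> dict:
    """Parameter recovery of the delay-excitability mixed model.

    Simulates excitability samples with a planted mean slope and measures
    how often the 95% CI of the fitted fixed slope covers it, plus the
    p-value uniformity when the planted slope is 0.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sims):
        res = fit_delay_excitability(_excitability_samples(rng, beta))
        t = res["delay"]
        half = sst.t.ppf(0.975, t.df_den) * t.se
        covered += (t.estimate - half) <= beta <= (t.estimate + half)
    null_p = []
    for _ in range(n_sims):
        res = fit_delay_excitability(_excitability_samples(rng, 0.0))
        null_p.append(res["delay"].p)
    ks = sst.kstest(np.asarray(null_p), "uniform")
    return {
        "ci_coverage": covered / n_sims,
        "null_p_ks_p": float(ks.pvalue),
        "beta": beta,
        "n_sims": n_sims,
    }


def _cohort_metric_labels(seed: int, planted: float, n_patients: int, cfg: SimConfig):
    spec = CohortSpec(n_patients=n_patients, planted_interaction=planted, seed=seed)
    coh = simulate_cohort(spec, cfg)
    tab = cohort_outcome_table(coh)
    agg = (
        tab.pivot(index="patient", columns="resection", values="value")
        .rename(columns={1: "resected_mean", 0: "nonresected_mean"})
        .reset_index()
    )
    m = patient_ratio_metric(agg)
    good = coh["patients"].set_index("patient")["good"]
    m = m.assign(good=m["patient"].map(good))
    return m["metric"].to_numpy(), m["good"].to_numpy(bool)


def classifier_evaluation(
    seed: int,
    planted: float | None = None,
    n_patients: int = 55,
    n_repeats: int = 500,
    n_permutations: int = 500,
    n_channels: int = 20,
    duration: float = 1200.0,
) -> dict:
    """Train/validate the outcome classifier on one simulated cohort."""
    cfg = SimConfig(n_channels=n_channels, duration=duration)
    if planted is None:
        planted = CohortSpec().planted_interaction
    m, y = _cohort_metric_labels(seed, planted, n_patients, cfg)
    rep = train_validate(
        m, y, n_repeats=n_repeats, n_permutations=n_permutations, seed=seed
    )
    from .classify import roc_evaluate

    roc = roc_evaluate(m, y)
    return {
        "median_accuracy": rep.summary["accuracy"]["median"],
        "median_f1": rep.summary["f1"]["median"],
        "accuracy_perm_p": rep.permutation_p.get("accuracy", np.nan),
        "threshold_sd": rep.threshold_sd,
        "auc": roc["auc"],
        "auc_p": roc["p"],
        "n_patients": len(y),
    }


def classifier_null_uniformity(
    seed: int,
    n_cohorts: int = 40,
    n_patients: int = 40,
    n_repeats: int = 60,
    n_permutations: int = 99,
    n_channels: int = 20,
    duration: float = 600.0,
) -> dict:
    """KS uniformity of classifier permutation p-values over null cohorts."""
    cfg = SimConfig(n_channels=n_channels, duration=duration)
    ps = []
    for i in range(n_cohorts):
        m, y = _cohort_metric_labels(seed + 7000 + i, 0.0, n_patients, cfg)
        rep = train_validate(
            m, y, n_repeats=n_repeats, n_permutations=n_permutations, seed=seed + i
        )
        ps.append(rep.permutation_p["accuracy"])
    ks = sst.kstest(np.asarray(ps), "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(ps)), "n_cohorts": n_cohorts}


def clustering_separability_study(
    seed: int, n_patients: int = 6, n_channels: int = 6, duration: float = 300.0
) -> dict:
    """Morphological separability of detected IEDs vs LoWS on rendered
    recordings (one per simulated patient)."""
    from .morphology import cluster_separability, waveform_features

    feats = []
    for p in range(n_patients):
        cfg = SimConfig(
            n_channels=n_channels, duration=duration, ied_rate=4.0, seed=seed + 100 + p
        )
        rec, _ = inject_events(make_background(cfg), cfg)
        ieds = collapse_bursts(detect_ieds(rec))
        lows = detect_lows(rec, ieds)
        ev = pd.concat(
            [ieds[["channel", "kind", "peak_t"]], lows[["channel", "kind", "peak_t"]]],
            ignore_index=True,
        )
        f = waveform_features(ev, rec)
        f["patient"] = f"P{p:03d}"
        feats.append(f)
    per_patient, cohort = cluster_separability(pd.concat(feats, ignore_index=True), seed=seed)
    return {
        "median_odds_ratio": cohort.get("median_or", np.nan),
        "wilcoxon_p": cohort.get("p", np.nan),
        "n_patients": cohort.get("n_patients", 0),
    }
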