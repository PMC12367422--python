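"""Synthetic-data generator: spectra, injections, cohorts, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from spikewave.lows import halfwave_amplitudes
from spikewave.synth import (
    CohortSpec,
    SchedulingError,
    SimConfig,
    inject_events,
    make_background,
    simulate_cohort,
)


class TestConfigValidation:
    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(duration=0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="500"):
            SimConfig(fs=256.0)

    @pytest.mark.parametrize("field,value", [("ied_rate", -1.0), ("downstate_depth", 1.5)])
    def test_invalid_rates_and_depth(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_infeasible_rate_is_a_scheduling_error(self):
        with pytest.raises(SchedulingError):
            SimConfig(ied_rate=100.0, lows_rate=100.0)


class TestBackground:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_channels=2, duration=20.0, seed=9)
        a = make_background(cfg)
        b = make_background(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_psd_slope_recovered(self):
        """Log-log periodogram fit below the spectral knee recovers -slope."""
        cfg = SimConfig(n_channels=1, duration=60.0, fs=512.0, background_slope=1.0,
                        alpha_power=0.0, wake_block_s=None, seed=3)
        rec = make_background(cfg)
        f, psd = signal.welch(rec.data[0], fs=rec.fs, nperseg=4096)
        sel = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[sel]), np.log(psd[sel]), 1)[0]
        assert abs(slope - (-1.0)) < 0.2

    def test_wake_blocks_alternate(self):
        cfg = SimConfig(n_channels=1, duration=120.0, seed=0)
        rec = make_background(cfg)
        segs = rec.wake_segments()
        assert segs[0][0] == 0.0
        assert all(abs((e - s) - 30.0) < 1e-6 for s, e in segs[:-1])


class TestInjection:
    def test_zero_rates_identity(self):
        cfg = SimConfig(n_channels=1, duration=30.0, ied_rate=0.0, lows_rate=0.0, seed=1)
        rec = make_background(cfg)
        out, truth = inject_events(rec, cfg)
        assert truth.empty
        np.testing.assert_array_equal(out.data, rec.data)

    def test_too_short_recording_rejected(self):
        cfg = SimConfig(n_channels=1, duration=20.0, seed=1)
        rec = make_background(cfg)
        rec.data = rec.data[:, : int(5 * rec.fs)]
        rec.wake_mask = rec.wake_mask[: rec.data.shape[1]]
        with pytest.raises(ValueError):
            inject_events(rec, cfg)

    def test_determinism(self):
        cfg = SimConfig(n_channels=2, duration=60.0, seed=11)
        r1, t1 = inject_events(make_background(cfg), cfg)
        r2, t2 = inject_events(make_background(cfg), cfg)
        np.testing.assert_array_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(t1, t2)

    def test_injected_ied_exceeds_envelope_threshold(self):
        """One IED at 10x the mean 20-80 Hz envelope is supra-threshold."""
        cfg = SimConfig(n_channels=1, duration=60.0, ied_rate=1.0, lows_rate=0.0,
                        ied_amp_factor=10.0, seed=21)
        rec = make_background(cfg)
        out, truth = inject_events(rec, cfg)
        sos = signal.butter(4, [20, 80], btype="bandpass", fs=rec.fs, output="sos")
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, out.data[0])))
        mean_env = env[out.wake()].mean()
        for t in truth[truth["kind"] == "IED"]["peak_t"]:
            k = int(t * rec.fs)
            assert env[k - 30 : k + 30].max() > 3.5 * mean_env

    def test_downstate_suppresses_high_gamma(self):
        """Mean 45-130 Hz power inside the half-wave drops below the flanks."""
        cfg = SimConfig(n_channels=1, duration=120.0, ied_rate=0.0, lows_rate=1.0,
                        downstate_depth=0.8, seed=5)
        rec = make_background(cfg)
        out, truth = inject_events(rec, cfg)
        sos = signal.butter(4, [45, 130], btype="bandpass", fs=rec.fs, output="sos")
        p = np.abs(signal.hilbert(signal.sosfiltfilt(sos, out.data[0]))) ** 2
        assert len(truth)
        for _, ev in truth.iterrows():
            k = int(ev["peak_t"] * rec.fs)
            h = int(ev["duration"] / 2 * rec.fs)
            inside = p[k - h : k + h].mean()
            fl = np.r_[p[k - int(1.5 * rec.fs) : k - int(0.5 * rec.fs)],
                       p[k + int(0.5 * rec.fs) : k + int(1.5 * rec.fs)]].mean()
            assert inside < fl

    def test_injected_lows_amplitude_above_background_percentile(self):
        cfg = SimConfig(n_channels=1, duration=120.0, ied_rate=0.0, lows_rate=2.0, seed=6)
        rec = make_background(cfg)
        out, truth = inject_events(rec, cfg)
        pct = np.percentile(halfwave_amplitudes(rec.data[0], rec.fs, rec.wake()), 90)
        amps = halfwave_amplitudes(out.data[0], out.fs, out.wake())
        # at least one background-beating wave per injection
        assert (amps > pct).sum() >= len(truth)

    def test_poisson_injection_counts(self):
        """Counts stay within 4 sqrt(lambda) of the Poisson expectation."""
        cfg = SimConfig(n_channels=10, duration=600.0, seed=17)
        _, truth = inject_events(make_background(cfg), cfg)
        wake_min = 600.0 / 60.0 / 2.0  # alternating 30-s blocks -> half awake
        for kind, rate in (("IED", cfg.ied_rate), ("LoWS", cfg.lows_rate)):
            lam = rate * wake_min * cfg.n_channels
            n = (truth["kind"] == kind).sum()
            assert abs(n - lam) < 4 * np.sqrt(lam)

    def test_min_event_spacing(self):
        cfg = SimConfig(n_channels=4, duration=300.0, seed=19)
        _, truth = inject_events(make_background(cfg), cfg)
        for _, g in truth.groupby("channel"):
            gaps = np.diff(np.sort(g["peak_t"].to_numpy()))
            assert (gaps >= 0.5 - 1e-9).all()


class TestCohort:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortSpec(engel_distribution={"I": 0.5, "IV": 0.4})

    def test_too_few_patients_per_class(self):
        with pytest.raises(ValueError, match="outcome class"):
            spec = CohortSpec(n_patients=3,
                              engel_distribution={"I": 0.67, "IV": 0.33})
            simulate_cohort(spec, SimConfig(n_channels=4, duration=120.0))

    def test_same_seed_identical(self):
        spec = CohortSpec(n_patients=6, seed=2)
        cfg = SimConfig(n_channels=6, duration=120.0)
        a = simulate_cohort(spec, cfg)
        b = simulate_cohort(spec, cfg)
        pd.testing.assert_frame_equal(a["patients"], b["patients"])
        pd.testing.assert_frame_equal(a["events"], b["events"])

    def test_null_interaction_balanced(self):
        """planted_interaction = 0: resected/nonresected delay ratio ~= 1."""
        spec = CohortSpec(n_patients=20, planted_interaction=0.0,
                          patient_jitter_sd=0.0, seed=3)
        cfg = SimConfig(n_channels=20, duration=1800.0)
        coh = simulate_cohort(spec, cfg)
        from spikewave.interplay import cohort_outcome_table

        tab = cohort_outcome_table(coh)
        res = tab[tab["resection"] == 1]["value"].mean()
        non = tab[tab["resection"] == 0]["value"].mean()
        assert abs(res / non - 1.0) < 0.1

    def test_planted_negative_shift_for_good_outcome(self):
        """Planted negative interaction shortens resected delays in Engel I."""
        spec = CohortSpec(n_patients=12, planted_interaction=0.4,
                          engel_distribution={"I": 0.5, "IV": 0.5},
                          patient_jitter_sd=0.0, seed=4)
        cfg = SimConfig(n_channels=12, duration=3600.0)
        coh = simulate_cohort(spec, cfg)
        good = set(coh["patients"][coh["patients"]["good"]]["patient"])
        ev = coh["events"]
        ch = coh["channels"]
        from spikewave.interplay import pairwise_delays

        res_d, non_d = [], []
        for pid, g in ev.groupby("patient"):
            if pid not in good:
                continue
            flags = ch[ch["patient"] == pid].set_index("channel")["resected"]
            d = pairwise_delays(g[g["kind"] == "IED"], g[g["kind"] == "LoWS"])
            d["resected"] = d["channel"].map(flags)
            res_d += d[d["resected"]]["raw_delay"].tolist()
            non_d += d[~d["resected"]]["raw_delay"].tolist()
        # Engel I -> delta = 0.4 * (1 - 2.5) = -0.6: markedly shorter delays
        assert np.mean(res_d) < np.mean(non_d)

    def test_soz_rule_exercisable(self):
        spec = CohortSpec(n_patients=4, seed=5)
        cfg = SimConfig(n_channels=10, duration=120.0)
        coh = simulate_cohort(spec, cfg)
        for _, g in coh["channels"].groupby("patient"):
            assert g["soz"].sum() >= 2  # the 10-mm rule has members to find
            assert g["resected"].any() and (~g["resected"]).any()
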