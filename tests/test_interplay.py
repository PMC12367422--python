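"""Rates, pairwise delays, incidence correction, SOZ rule, preictal table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from spikewave.interplay import (
    aggregate_by_resection,
    cohort_outcome_table,
    corrected_delays,
    event_rates,
    pairwise_delays,
    preictal_contrast_table,
    preictal_window,
    soz_channels,
)
from spikewave.synth import CohortSpec, SimConfig, simulate_cohort


def ev(times, kind="IED", channel="A"):
    return pd.DataFrame({"channel": channel, "kind": kind, "peak_t": list(times)})


class TestEventRates:
    def test_five_events_in_five_minutes(self):
        r = event_rates(ev(np.linspace(10, 250, 5)), wake_minutes=5.0)
        assert r.loc[0, "rate_ied"] == 1.0
        assert r.loc[0, "rate_lows"] == 0.0

    def test_no_events_zero_rate(self):
        r = event_rates(ev([]), wake_minutes=5.0, channels=["A"])
        assert r.loc[0, "rate_ied"] == 0.0

    def test_zero_wake_channel_excluded(self):
        r = event_rates(ev([1.0]), wake_minutes={"A": 0.0}, channels=["A"])
        assert r.empty

    def test_poisson_rate_recovery(self, rng):
        t = np.sort(rng.uniform(0, 600, rng.poisson(3.8 * 10)))
        r = event_rates(ev(t, kind="LoWS"), wake_minutes=10.0)
        assert abs(r.loc[0, "rate_lows"] - 3.8) < 4 * np.sqrt(38) / 10


class TestPairwiseDelays:
    def test_simple_forward_pair(self):
        d = pairwise_delays(ev([10.0]), ev([13.0], kind="LoWS"))
        assert list(d["raw_delay"]) == [3.0]

    def test_unpaired_source_censored(self):
        d = pairwise_delays(ev([10.0]), ev([8.0], kind="LoWS"))
        assert d.empty

    def test_segment_crossing_censored(self):
        d = pairwise_delays(
            ev([10.0]), ev([40.0], kind="LoWS"), segments=[(0, 30), (30, 60)]
        )
        assert d.empty

    def test_direction_swap(self):
        d = pairwise_delays(ev([10.0]), ev([7.0], kind="LoWS"), direction="lows_to_ied")
        assert list(d["raw_delay"]) == [3.0]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), max_size=20),
        st.lists(st.floats(0, 100, allow_nan=False), max_size=20),
    )
    def test_matches_minimum_forward_gap_oracle(self, src, tgt):
        src, tgt = sorted(set(src)), sorted(set(tgt))
        d = pairwise_delays(ev(src), ev(tgt, kind="LoWS"))
        expected = []
        for s in src:
            later = [t for t in tgt if t > s]
            if later:
                expected.append(min(later) - s)
        assert np.allclose(sorted(d["raw_delay"]), sorted(expected))

    def test_record_counts_bounded_by_sources(self, rng):
        s = np.sort(rng.uniform(0, 100, 30))
        t = np.sort(rng.uniform(0, 100, 50))
        assert len(pairwise_delays(ev(s), ev(t, kind="LoWS"))) <= 30
        assert len(pairwise_delays(ev(s), ev(t, kind="LoWS"), "lows_to_ied")) <= 50


class TestCorrectedDelays:
    def _rates(self, lows_per_min, ied_per_min=1.0):
        return pd.DataFrame(
            {"channel": ["A"], "rate_ied": [ied_per_min], "rate_lows": [lows_per_min],
             "wake_minutes": [10.0]}
        )

    def test_definition(self):
        """Raw delay 15 s at a 4/min target rate (expected wait 15 s) -> 1."""
        d = pairwise_delays(ev([0.0]), ev([15.0], kind="LoWS"))
        c = corrected_delays(d, self._rates(4.0))
        assert np.isclose(c.loc[0, "corrected_delay"], 1.0)

    def test_zero_target_rate_censored(self):
        d = pairwise_delays(ev([0.0]), ev([15.0], kind="LoWS"))
        assert corrected_delays(d, self._rates(0.0)).empty

    def test_median_converges_to_ln2(self, rng):
        """Homogeneous Poisson trains: corrected delay is Exp(1), median ln 2."""
        meds = []
        for _ in range(40):
            T = 3600.0
            s = np.sort(rng.uniform(0, T, rng.poisson(0.012 * T)))
            t = np.sort(rng.uniform(0, T, rng.poisson(0.064 * T)))
            rates = event_rates(pd.concat([ev(s), ev(t, kind="LoWS")]), T / 60)
            c = corrected_delays(pairwise_delays(ev(s), ev(t, kind="LoWS")), rates)
            meds.append(c["corrected_delay"].median())
        se = np.std(meds, ddof=1) / np.sqrt(len(meds))
        assert abs(np.mean(meds) - np.log(2)) < max(3 * se, 0.05)

    def test_scale_free_under_time_rescaling(self, rng):
        s = np.sort(rng.uniform(0, 600, 20))
        t = np.sort(rng.uniform(0, 600, 60))
        rates = event_rates(pd.concat([ev(s), ev(t, kind="LoWS")]), 10.0)
        c1 = corrected_delays(pairwise_delays(ev(s), ev(t, kind="LoWS")), rates)
        k = 3.0
        rates2 = event_rates(pd.concat([ev(s * k), ev(t * k, kind="LoWS")]), 10.0 * k)
        c2 = corrected_delays(pairwise_delays(ev(s * k), ev(t * k, kind="LoWS")), rates2)
        np.testing.assert_allclose(
            np.sort(c1["corrected_delay"]), np.sort(c2["corrected_delay"])
        )

    def test_thinning_invariance(self, rng):
        T = 3600.0
        s = np.sort(rng.uniform(0, T, rng.poisson(0.012 * T)))
        t = np.sort(rng.uniform(0, T, rng.poisson(0.064 * T)))
        rates = event_rates(pd.concat([ev(s), ev(t, kind="LoWS")]), T / 60)
        c1 = corrected_delays(pairwise_delays(ev(s), ev(t, kind="LoWS")), rates)
        t2 = t[rng.uniform(size=len(t)) < 0.5]
        rates2 = event_rates(pd.concat([ev(s), ev(t2, kind="LoWS")]), T / 60)
        c2 = corrected_delays(pairwise_delays(ev(s), ev(t2, kind="LoWS")), rates2)
        p = sst.ks_2samp(c1["corrected_delay"], c2["corrected_delay"]).pvalue
        assert p > 0.01


class TestAggregateByResection:
    def _records(self, values_by_channel):
        rows = []
        for ch, vals in values_by_channel.items():
            for v in vals:
                rows.append({"channel": ch, "direction": "ied_to_lows",
                             "corrected_delay": v})
        return pd.DataFrame(rows)

    def _channels(self, resected):
        return pd.DataFrame(
            {"channel": list(resected), "resected": list(resected.values())}
        )

    def test_identical_channels_equal_means(self):
        rec = self._records({"A": [1.0, 2.0], "B": [1.0, 2.0]})
        agg = aggregate_by_resection(rec, self._channels({"A": True, "B": False}))
        assert agg.loc[0, "resected_mean"] == agg.loc[0, "nonresected_mean"]

    def test_planted_half_ratio(self):
        rec = self._records(
            {"A": [0.5, 0.6, 0.4], "B": [1.0, 1.2, 0.8], "C": [1.0, 0.9, 1.1]}
        )
        agg = aggregate_by_resection(
            rec, self._channels({"A": True, "B": False, "C": False})
        )
        assert agg.loc[0, "resected_mean"] / agg.loc[0, "nonresected_mean"] == pytest.approx(0.5, rel=0.05)

    def test_single_resected_channel_median_passes_through(self):
        rec = self._records({"A": [0.1, 0.9, 0.5], "B": [1.0]})
        agg = aggregate_by_resection(rec, self._channels({"A": True, "B": False}))
        assert agg.loc[0, "resected_mean"] == 0.5

    def test_patient_with_one_group_excluded(self):
        rec = self._records({"A": [1.0]})
        agg = aggregate_by_resection(rec, self._channels({"A": True}))
        assert agg.empty


class TestSozAndPreictal:
    def test_ten_mm_rule(self):
        ch = pd.DataFrame(
            {"name": ["o", "near", "far"], "x": [0.0, 0.0, 0.0],
             "y": [0.0, 0.0, 0.0], "z": [0.0, 9.0, 11.0]}
        )
        out = soz_channels(ch, ["o"])
        assert list(out["soz"]) == [True, True, False]

    def test_preictal_window_cutoff(self):
        assert preictal_window(120.0) == (0.0, 110.0)
        assert preictal_window(5.0) is None

    def test_planted_region_by_period_effect_direction(self):
        """Doubling preictal LoWS outside the SOZ shows up in the table."""
        spec = CohortSpec(
            n_patients=8,
            planted_interaction=0.0,
            preictal_rate_factors={("LoWS", "esoz"): 2.0},
            seed=9,
        )
        cfg = SimConfig(n_channels=10, duration=1200.0)
        coh = simulate_cohort(spec, cfg)
        tab = preictal_contrast_table(coh["events"], coh["channels"], coh["wake_minutes"])
        piv = tab[tab["event"] == "LoWS"].pivot_table(
            index="patient", columns=["region", "period"], values="rate"
        )
        boost_esoz = (piv[("eSOZ", "preictal")] / piv[("eSOZ", "interictal")]).mean()
        boost_soz = (piv[("SOZ", "preictal")] / piv[("SOZ", "interictal")]).mean()
        assert boost_esoz > 1.5
        assert boost_esoz > boost_soz


def test_cohort_outcome_table_shape():
    spec = CohortSpec(n_patients=12, seed=1)
    cfg = SimConfig(n_channels=10, duration=600.0)
    tab = cohort_outcome_table(simulate_cohort(spec, cfg))
    assert set(tab["resection"]) == {0, 1}
    assert tab.groupby("patient").size().eq(2).all()
    assert (tab["value"] > 0).all()
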