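"""Engel linearisation, ROUT, outcome mixed models, paired tests, ANOVAs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from spikewave.stats import (
    ENGEL_LINEAR_MAP,
    engel_linearize,
    fit_outcome_lmm,
    holm,
    preictal_anova,
    rm_anova_within,
    rout_outliers,
    soz_rate_test,
)


class TestEngelLinearize:
    @pytest.mark.parametrize("label,expected", [("I", 1.0), ("IV", 4.0), ("Engel II", 2.0), ("IIIB", 3.25)])
    def test_default_map(self, label, expected):
        assert engel_linearize(label) == expected

    def test_default_map_is_monotone(self):
        vals = [ENGEL_LINEAR_MAP[c] for c in ("I", "II", "III", "IV")]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            engel_linearize("V")

    def test_non_monotone_custom_table_rejected(self):
        with pytest.raises(ValueError):
            engel_linearize("I", table={"I": 2.0, "II": 1.0, "III": 3.0, "IV": 4.0})

    def test_monotone_custom_table_accepted(self):
        table = {"I": 0.0, "II": 10.0, "III": 20.0, "IV": 40.0}
        assert engel_linearize("III", table=table) == 20.0


class TestRoutOutliers:
    def test_identical_values_all_kept(self):
        assert rout_outliers(np.full(20, 3.0)).all()

    def test_extreme_point_flagged(self, rng):
        x = np.r_[rng.normal(0, 1, 20), 50.0]
        keep = rout_outliers(x)
        assert not keep[-1]
        assert keep[:-1].sum() >= 18  # at most FDR-level collateral

    def test_q_zero_limit_keeps_everything(self, rng):
        x = np.r_[rng.normal(0, 1, 20), 50.0]
        assert rout_outliers(x, q=0.0).all()

    def test_small_samples_kept_with_warning(self):
        with pytest.warns(UserWarning):
            keep = rout_outliers([1.0, 2.0, 100.0])
        assert keep.all()


def make_outcome_table(rng, n_patients=14, interaction=0.0, sd=0.2, icc_sd=0.3):
    rows = []
    for p in range(n_patients):
        b = rng.normal(0, icc_sd)
        engel = float(rng.integers(1, 5))
        for res in (0, 1):
            rows.append(
                {
                    "patient": f"P{p:02d}",
                    "value": 1.0 + b - 0.05 * engel + 0.1 * res
                    + interaction * engel * res + rng.normal(0, sd),
                    "engel": engel,
                    "resection": res,
                    "soz": 0.3 * res,
                    "lesion": int(p % 2),
                    "therapy": "resection" if p % 3 else "ablation",
                }
            )
    return pd.DataFrame(rows)


class TestFitOutcomeLmm:
    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_outcome_lmm(make_outcome_table(rng), "eq9")

    def test_too_few_patients_rejected(self, rng):
        with pytest.raises(ValueError, match="10 patients"):
            fit_outcome_lmm(make_outcome_table(rng, n_patients=5), "eq4")

    def test_constant_resection_is_rank_deficient(self, rng):
        tab = make_outcome_table(rng)
        tab["resection"] = 1
        with pytest.raises(ValueError, match="rank"):
            fit_outcome_lmm(tab, "eq4")

    def test_interaction_detected_when_planted(self, rng):
        tab = make_outcome_table(rng, n_patients=30, interaction=0.3)
        res = fit_outcome_lmm(tab, "eq4")
        t = res["engel:resection"]
        assert t.p < 0.01
        assert t.estimate == pytest.approx(0.3, abs=3 * t.se)

    def test_reduces_to_ols_at_variance_boundary(self, rng):
        """With zero between-patient variance the REML fit hits the boundary
        and the interaction F equals the ordinary least-squares F."""
        import statsmodels.formula.api as smf

        tab = make_outcome_table(rng, n_patients=25, icc_sd=0.0, sd=1.0)
        res = fit_outcome_lmm(tab, "eq4")
        if not res.singular:
            pytest.skip("variance did not hit the boundary for this draw")
        ols = smf.ols("value ~ engel * resection", tab).fit()
        t_ols = ols.tvalues["engel:resection"]
        assert res["engel:resection"].F == pytest.approx(t_ols**2, rel=1e-6)

    def test_eq5_variance_components_accepted(self, rng):
        tab = make_outcome_table(rng, n_patients=20)
        res = fit_outcome_lmm(tab, "eq5")
        assert "engel:resection" in res.terms
        assert 0 <= res["engel:resection"].p <= 1


class TestSozRateTest:
    def test_identical_pairs_p_one(self):
        df = pd.DataFrame({"patient": list("abcdefgh"), "rate_in": 1.0, "rate_out": 1.0})
        assert soz_rate_test(df)["p"] == 1.0

    def test_doubled_soz_rate_detected(self, rng):
        rates_out = rng.gamma(4, 0.2, 30)
        df = pd.DataFrame(
            {"patient": [f"p{i}" for i in range(30)],
             "rate_in": rates_out * 2 + rng.normal(0, 0.05, 30),
             "rate_out": rates_out}
        )
        assert soz_rate_test(df)["p"] < 0.05

    def test_sign_flip_symmetry(self, rng):
        rates_out = rng.gamma(4, 0.2, 20)
        d = rng.normal(0.3, 0.2, 20)
        a = soz_rate_test(pd.DataFrame({"patient": range(20), "rate_in": rates_out + d, "rate_out": rates_out}))
        b = soz_rate_test(pd.DataFrame({"patient": range(20), "rate_in": rates_out, "rate_out": rates_out + d}))
        assert a["p"] == pytest.approx(b["p"])

    def test_small_n_uses_exact_null(self):
        df = pd.DataFrame({"patient": list("abcde"), "rate_in": [1.2, 1.5, 1.1, 1.4, 1.3],
                           "rate_out": [1.0, 1.0, 1.0, 1.0, 1.0]})
        out = soz_rate_test(df)
        assert out["p"] == pytest.approx(2 * 0.5**5, rel=1e-9)


class TestRmAnova:
    def _table(self, rng, effect=0.0, n_sub=12):
        rows = []
        for s in range(n_sub):
            b = rng.normal(0, 1)
            for r in ("SOZ", "eSOZ"):
                for p in ("interictal", "preictal"):
                    rows.append(
                        {"patient": f"S{s}", "region": r, "period": p,
                         "rate": b + effect * (r == "SOZ") * (p == "preictal")
                         + rng.normal(0, 0.3)}
                    )
        return pd.DataFrame(rows)

    def test_matches_pingouin_two_way(self, rng):
        import pingouin as pg

        df = self._table(rng, effect=0.5)
        mine = rm_anova_within(df, "rate", ["region", "period"], "patient").set_index("effect")
        ref = pg.rm_anova(data=df, dv="rate", within=["region", "period"],
                          subject="patient", detailed=True).set_index("Source")
        for eff, src in [("region", "region"), ("period", "period"),
                         ("region * period", "region * period")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-6)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[src, "p-unc" if "p-unc" in ref.columns else "p_unc"], rel=1e-6)

    def test_all_equal_cells_no_effects(self):
        rows = [
            {"patient": f"S{s}", "region": r, "period": p, "rate": 1.0}
            for s in range(6) for r in ("A", "B") for p in ("x", "y")
        ]
        out = rm_anova_within(pd.DataFrame(rows), "rate", ["region", "period"], "patient")
        assert (out["p"] >= 0.99).all()

    def test_permuted_labels_nominal_rejection(self, rng):
        rejections = 0
        for _ in range(60):
            df = self._table(rng, effect=0.0, n_sub=8)
            out = rm_anova_within(df, "rate", ["region", "period"], "patient")
            rejections += out.set_index("effect").loc["region * period", "p"] < 0.05
        assert rejections / 60 <= 0.15


class TestPreictalAnova:
    def test_planted_three_way_interaction(self, rng):
        rows = []
        for s in range(12):
            for r in ("SOZ", "eSOZ"):
                for p in ("interictal", "preictal"):
                    for e in ("IED", "LoWS"):
                        rows.append(
                            {"patient": f"S{s}", "region": r, "period": p, "event": e,
                             "rate": rng.normal(0, 0.3)
                             + (e == "LoWS") * (p == "preictal") * (r == "eSOZ") * 1.0}
                        )
        out = preictal_anova(pd.DataFrame(rows))
        tw = out["three_way"].set_index("effect")
        assert tw.loc["region * period * event", "p"] < 0.05
        ph = out["post_hoc"].set_index(["event", "region"])
        assert ph.loc[("LoWS", "eSOZ"), "p_holm"] < 0.05
        assert ph.loc[("IED", "SOZ"), "p_holm"] > 0.05


class TestHolm:
    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 10)
        adj = holm(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
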