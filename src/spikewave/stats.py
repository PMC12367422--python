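"""Outcome statistics: Engel linearisation, robust outlier removal, the
mixed-effects outcome models, paired seizure-onset-zone rate tests, and the
preictal/interictal repeated-measures ANOVAs.

The outcome models relate per-patient resected/nonresected summaries of event
rates or corrected delays to the (linearised) Engel score; their headline
output is the Engel x resection interaction, whose significance indicates
that the quantity differs between removed and spared tissue as a function of
surgical success.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sst

from .mixed import LmmResult, fit_mixed_model

logger = logging.getLogger(__name__)

__all__ = [
    "ENGEL_LINEAR_MAP",
    "engel_linearize",
    "rout_outliers",
    "fit_outcome_lmm",
    "soz_rate_test",
    "rm_anova_within",
    "preictal_anova",
    "holm",
]

#: Default monotone map from Engel class (with subclasses interpolated at
#: quarter steps) to an ordinal covariate.
ENGEL_LINEAR_MAP: dict[str, float] = {
    "I": 1.0, "IA": 1.0, "IB": 1.25, "IC": 1.5, "ID": 1.75,
    "II": 2.0, "IIA": 2.0, "IIB": 2.25, "IIC": 2.5, "IID": 2.75,
    "III": 3.0, "IIIA": 3.0, "IIIB": 3.25,
    "IV": 4.0, "IVA": 4.0, "IVB": 4.25, "IVC": 4.5,
}


def engel_linearize(engel_class: str, table: dict[str, float] | None = None) -> float:
    """Map an Engel class label to its ordinal numeric score.

    Any replacement ``table`` must be monotone in the class ordering
    (asserted).  Unknown labels raise.
    """
    table = ENGEL_LINEAR_MAP if table is None else table
    if table is not ENGEL_LINEAR_MAP:
        base = ["I", "II", "III", "IV"]
        vals = [table[c] for c in base if c in table]
        if any(b >= a for a, b in zip(vals[1:], vals)):
            raise ValueError("Engel linearisation table must be strictly monotone")
    key = str(engel_class).strip().upper().replace("ENGEL", "").strip()
    if key not in table:
        raise ValueError(f"unknown Engel class {engel_class!r}")
    return float(table[key])


def rout_outliers(values, q: float = 0.01, min_n: int = 8) -> np.ndarray:
    """Robust-regression-and-outlier-removal keep mask at coefficient Q.

    Residuals from a robust location (median) are scaled by the RSDR (the
    68.27th percentile of absolute residuals, small-sample corrected); the
    most extreme points are flagged by a false-discovery-rate walk at rate
    ``q``.  Returns a boolean mask, True = keep.  With fewer than ``min_n``
    values everything is kept (warning).
    """
    x = np.asarray(values, float)
    n = len(x)
    keep = np.ones(n, dtype=bool)
    if n < min_n:
        warnings.warn(f"rout_outliers: only {n} values; all kept", stacklevel=2)
        return keep
    if q <= 0:
        return keep
    k_params = 1  # location-only model
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * np.sqrt(n / (n - k_params))
    if rsdr == 0:
        return keep
    t = np.abs(resid) / rsdr
    pvals = 2.0 * sst.t.sf(t, df=n - k_params)
    order = np.argsort(-np.abs(resid))  # most extreme first
    for i, idx in enumerate(order):
        alpha_i = q * (n - i) / n
        if pvals[idx] < alpha_i:
            keep[idx] = False
        else:
            break  # the walk stops at the first non-outlier
    return keep


_OUTCOME_FORMULA = "value ~ engel * resection"


def fit_outcome_lmm(table: pd.DataFrame, model_id: str = "eq4") -> LmmResult:
    """Outcome mixed model on a patient x resection-group table.

    ``table`` columns: patient, value (a rate for the rate models, a
    corrected delay for the delay models), engel (linearised ordinal),
    resection (0/1); the extended model additionally uses soz, lesion and
    therapy columns as per-patient random coefficients.

    ``model_id``: ``"eq2"``/``"eq3"`` (rate models), ``"eq4"`` (corrected
    delay) — all ``value ~ engel * resection + (1 | patient)`` — or
    ``"eq5"`` which adds the SOZ/lesion/therapy variance components.  The
    Engel x resection interaction term (``engel:resection``) is the headline
    output.
    """
    if model_id not in {"eq2", "eq3", "eq4", "eq5"}:
        raise ValueError(f"unknown model id {model_id!r}")
    required = {"patient", "value", "engel", "resection"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if table["patient"].nunique() < 10:
        raise ValueError("need at least 10 patients")
    vc = None
    if model_id == "eq5":
        vc = {}
        for col, spec in (("soz", "0 + soz"), ("lesion", "0 + lesion"), ("therapy", "0 + C(therapy)")):
            if col in table.columns and table[col].nunique() > 1:
                vc[col] = spec
        vc = vc or None
    try:
        return fit_mixed_model(
            table, _OUTCOME_FORMULA, groups="patient", re_formula="1", vc_formula=vc
        )
    except RuntimeError:
        if vc is None:
            raise
        logger.warning("fit_outcome_lmm: %s failed; refitting without variance components", model_id)
        res = fit_mixed_model(table, _OUTCOME_FORMULA, groups="patient", re_formula="1")
        res.notes.append("variance components dropped (non-convergence)")
        return res


def soz_rate_test(rates: pd.DataFrame) -> dict:
    """Two-sided paired Wilcoxon of per-patient rates inside vs outside SOZ.

    ``rates`` columns: patient, rate_in, rate_out.  Below 6 pairs the exact
    null distribution is used.
    """
    d = rates["rate_in"].to_numpy(float) - rates["rate_out"].to_numpy(float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 patients")
    if np.all(d == 0):
        return {"n": n, "statistic": 0.0, "p": 1.0, "median_in": float(np.median(rates["rate_in"])), "median_out": float(np.median(rates["rate_out"]))}
    method = "exact" if n < 6 else "auto"
    res = sst.wilcoxon(d[d != 0], method=method)
    return {
        "n": n,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_in": float(np.median(rates["rate_in"])),
        "median_out": float(np.median(rates["rate_out"])),
    }


# ---------------------------------------------------------------------------
# fully-within repeated-measures ANOVA


def rm_anova_within(
    df: pd.DataFrame, dv: str, within: list[str], subject: str
) -> pd.DataFrame:
    """Repeated-measures ANOVA, all factors within-subject, one observation
    per cell.

    Each effect is tested against its interaction with subject (the standard
    error term for fully-within designs).  Subjects with incomplete cells are
    dropped (logged).  Returns one row per effect with SS, df, F, p.
    """
    levels = {f: sorted(df[f].unique()) for f in within}
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full = wide.dropna()
    if len(full) < len(wide):
        logger.info("rm_anova_within: dropped %d incomplete subjects", len(wide) - len(full))
    if len(full) < 2:
        raise ValueError("need at least 2 complete subjects")
    shape = [len(full)] + [len(levels[f]) for f in within]
    if isinstance(full.columns, pd.MultiIndex):
        full = full.reindex(columns=pd.MultiIndex.from_product([levels[f] for f in within]))
    else:
        full = full.reindex(columns=levels[within[0]])
    data = full.to_numpy(float).reshape(shape)
    n_sub = shape[0]
    axes = {f: i + 1 for i, f in enumerate(within)}

    def marginal_mean(keep_axes):
        """Cell means averaged over all axes except `keep_axes` (0=subject)."""
        drop = tuple(i for i in range(data.ndim) if i not in keep_axes)
        return data.mean(axis=drop, keepdims=True)

    cell_count = int(np.prod(shape[1:]))

    def effect_ss(factors, with_subject):
        keep = [axes[f] for f in factors] + ([0] if with_subject else [])
        total = 0.0
        sub_sets = []
        base = list(factors) + (["__s__"] if with_subject else [])
        for r in range(len(base) + 1):
            for combo in itertools.combinations(base, r):
                f_axes = [axes[f] for f in combo if f != "__s__"]
                if "__s__" in combo:
                    f_axes.append(0)
                sign = (-1) ** (len(base) - r)
                sub_sets.append((sign, f_axes))
        est = np.zeros_like(data)
        for sign, f_axes in sub_sets:
            est = est + sign * marginal_mean(f_axes)
        return float((est**2).sum())

    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            df_eff = int(np.prod([len(levels[f]) - 1 for f in combo]))
            ss_eff = effect_ss(list(combo), with_subject=False)
            ss_err = effect_ss(list(combo), with_subject=True)
            df_err = df_eff * (n_sub - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err if df_err > 0 else np.nan
            F = ms_eff / ms_err if ms_err and ms_err > 0 else np.nan
            p = float(sst.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 1.0
            rows.append(
                {
                    "effect": " * ".join(combo),
                    "SS": ss_eff,
                    "df1": df_eff,
                    "df2": df_err,
                    "F": float(F) if np.isfinite(F) else 0.0,
                    "p": p,
                    "n_subjects": n_sub,
                }
            )
    return pd.DataFrame(rows)


def holm(pvals) -> np.ndarray:
    """Holm-adjusted p-values (monotone, always >= raw)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="holm")[1]


def preictal_anova(long_table: pd.DataFrame) -> dict:
    """Seizure analysis ANOVAs on the region x period rate table.

    Runs a 2-way repeated-measures ANOVA (region x period) per event kind,
    the 3-way ANOVA with event kind as the third factor, and Holm-corrected
    paired post hoc contrasts of the preictal-minus-interictal rate change
    per (event, region) cell.
    """
    out: dict = {"two_way": {}, "post_hoc": None}
    for kind, grp in long_table.groupby("event"):
        out["two_way"][kind] = rm_anova_within(
            grp, dv="rate", within=["region", "period"], subject="patient"
        )
    out["three_way"] = rm_anova_within(
        long_table, dv="rate", within=["region", "period", "event"], subject="patient"
    )

    wide = long_table.pivot_table(
        index="patient", columns=["event", "region", "period"], values="rate"
    ).dropna()
    rows = []
    for event in sorted(long_table["event"].unique()):
        for region in sorted(long_table["region"].unique()):
            try:
                diff = wide[(event, region, "preictal")] - wide[(event, region, "interictal")]
            except KeyError:
                continue
            if len(diff) < 2 or np.allclose(diff, diff.iloc[0]):
                t, p = 0.0, 1.0
            else:
                t, p = sst.ttest_rel(
                    wide[(event, region, "preictal")], wide[(event, region, "interictal")]
                )
            rows.append(
                {"event": event, "region": region, "mean_diff": float(diff.mean()), "t": float(t), "p_raw": float(p)}
            )
    if rows:
        ph = pd.DataFrame(rows)
        ph["p_holm"] = holm(ph["p_raw"])
        out["post_hoc"] = ph
    return out
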