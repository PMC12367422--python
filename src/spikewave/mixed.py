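"""Linear mixed models with Satterthwaite denominator degrees of freedom.

Fitting is delegated to statsmodels' ``MixedLM`` (REML).  statsmodels does
not provide Satterthwaite approximations, so they are computed here from the
REML variance-parameter Hessian by finite differences: for a contrast ``l``
of the fixed effects,

    df = 2 * (l' C(theta) l)^2 / (g' A g)

where ``C(theta)`` is the GLS covariance of the fixed effects at the REML
estimate, ``g`` the gradient of ``l' C(theta) l`` with respect to the
variance parameters, and ``A`` the asymptotic covariance of the variance
parameters (inverse negative Hessian of the profiled REML log-likelihood).
Each fixed-effect term is reported as an omnibus F (t squared for the 1-df
contrasts used throughout) with fractional denominator df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

logger = logging.getLogger(__name__)

__all__ = ["TermTest", "LmmResult", "fit_mixed_model"]


@dataclass
class TermTest:
    """One fixed-effect term: estimate, Wald/Satterthwaite F test."""

    estimate: float
    se: float
    F: float
    df_num: float
    df_den: float
    p: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
        }


@dataclass
class LmmResult:
    """Fit summary: per-term tests plus convergence diagnostics."""

    terms: dict[str, TermTest]
    formula: str
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> TermTest:
        return self.terms[term]

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "singular": self.singular,
            "notes": list(self.notes),
            "terms": {k: v.to_dict() for k, v in self.terms.items()},
        }


def _vech(a: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(a.shape[0])
    return a[idx]


def _unvech(v: np.ndarray, k: int) -> np.ndarray:
    a = np.zeros((k, k))
    idx = np.tril_indices(k)
    a[idx] = v
    a = a + a.T - np.diag(np.diag(a))
    return a


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    w, q = np.linalg.eigh((a + a.T) / 2.0)
    return (q * np.clip(w, 0.0, None)) @ q.T


class _RemlMachinery:
    """Direct dense evaluation of the profiled REML criterion and the GLS
    fixed-effect covariance as functions of the variance parameters."""

    def __init__(self, model):
        self.X = np.asarray(model.exog, float)
        self.y = np.asarray(model.endog, float)
        groups = np.asarray(model.groups)
        self.labels = list(pd.unique(groups))
        self.rows = [np.flatnonzero(groups == g) for g in self.labels]
        self.k_re = 0
        self.Z = None
        if model.exog_re is not None:
            Zfull = np.asarray(model.exog_re, float)
            self.k_re = Zfull.shape[1]
            self.Z = [Zfull[r] for r in self.rows]
        self.vc_mats = []
        if getattr(model, "exog_vc", None) is not None and getattr(model.exog_vc, "names", []):
            # statsmodels VCSpec: mats[vc_index][group_index]
            for j in range(len(model.exog_vc.names)):
                self.vc_mats.append(
                    [np.asarray(m, float) for m in model.exog_vc.mats[j]]
                )
        self.n_vc = len(self.vc_mats)
        self.n, self.p = self.X.shape

    # -- parameter packing: [vech(cov_re), vcomp..., scale] -----------------
    def pack(self, cov_re, vcomp, scale) -> np.ndarray:
        parts = []
        if self.k_re:
            parts.append(_vech(np.asarray(cov_re, float)))
        if self.n_vc:
            parts.append(np.asarray(vcomp, float))
        parts.append(np.array([float(scale)]))
        return np.concatenate(parts)

    def unpack(self, theta):
        k = self.k_re * (self.k_re + 1) // 2
        cov_re = _unvech(theta[:k], self.k_re) if self.k_re else None
        vcomp = theta[k : k + self.n_vc]
        scale = theta[-1]
        return cov_re, vcomp, scale

    def _v_groups(self, theta):
        cov_re, vcomp, scale = self.unpack(theta)
        scale = max(float(scale), 1e-12)
        if cov_re is not None:
            cov_re = _nearest_psd(cov_re)
        vcomp = np.clip(vcomp, 0.0, None)
        for i, r in enumerate(self.rows):
            m = len(r)
            V = scale * np.eye(m)
            if self.k_re:
                Zi = self.Z[i]
                V += Zi @ cov_re @ Zi.T
            for j in range(self.n_vc):
                Mij = self.vc_mats[j][i]
                V += vcomp[j] * (Mij @ Mij.T)
            yield i, r, V

    def fixed_cov(self, theta) -> np.ndarray:
        """GLS covariance of the fixed effects, C(theta)."""
        XtVX = np.zeros((self.p, self.p))
        for i, r, V in self._v_groups(theta):
            Vi_X = np.linalg.solve(V, self.X[r])
            XtVX += self.X[r].T @ Vi_X
        return np.linalg.pinv(XtVX)

    def reml_loglike(self, theta) -> float:
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        logdet = 0.0
        chunks = []
        for i, r, V in self._v_groups(theta):
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf
            logdet += ld
            Vi = np.linalg.inv(V)
            XtVX += self.X[r].T @ Vi @ self.X[r]
            XtVy += self.X[r].T @ Vi @ self.y[r]
            chunks.append((r, Vi))
        beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        quad = 0.0
        for r, Vi in chunks:
            resid = self.y[r] - self.X[r] @ beta
            quad += resid @ Vi @ resid
        sign, ld2 = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdet + ld2 + quad)


def _gradient(fun, theta, rel=1e-4):
    g = np.zeros_like(theta)
    for j in range(len(theta)):
        h = rel * max(abs(theta[j]), 1e-3 * abs(theta[-1]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        g[j] = (fun(tp) - fun(tm)) / (2 * h)
    return g


def _hessian(fun, theta, rel=1e-3):
    k = len(theta)
    h = np.array(
        [rel * max(abs(theta[j]), 1e-3 * abs(theta[-1]), 1e-8) for j in range(k)]
    )
    H = np.zeros((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i + 1, k):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[i] += h[i]; tpp[j] += h[j]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp[i] -= h[i]; tmp[j] += h[j]
            tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)) / (
                4 * h[i] * h[j]
            )
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        H[i, i] = (fun(tp) - 2 * f0 + fun(tm)) / (h[i] ** 2)
    return H


def satterthwaite_df(mech: _RemlMachinery, theta: np.ndarray, contrast: np.ndarray):
    """Satterthwaite df and variance for one fixed-effect contrast."""

    def f(th):
        C = mech.fixed_cov(th)
        return float(contrast @ C @ contrast)

    var_l = f(theta)
    g = _gradient(f, theta)
    H = _hessian(mech.reml_loglike, theta)
    A = np.linalg.pinv(-H)
    denom = float(g @ A @ g)
    fallback = max(mech.n - mech.p, 1)
    if not np.isfinite(denom) or denom <= 0 or var_l <= 0:
        return float(fallback), var_l
    df = 2.0 * var_l**2 / denom
    if not np.isfinite(df) or df <= 0:
        return float(fallback), var_l
    return float(min(df, 1e7)), var_l


def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    groups: str,
    re_formula: str = "1",
    vc_formula: dict | None = None,
    reml: bool = True,
) -> LmmResult:
    """Fit an LMM and test every fixed-effect coefficient.

    Each term is reported as an omnibus F (the squared Satterthwaite t for
    these 1-df contrasts) with fractional denominator df, the style of
    mixed-model omnibus tests produced by lmerTest/Jamovi.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    notes: list[str] = []
    model = MixedLM.from_formula(
        formula, data, groups=data[groups], re_formula=re_formula, vc_formula=vc_formula
    )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
            converged = bool(res.converged)
        except Exception:  # noqa: BLE001 - optimizer failure -> simplify
            res = None
            converged = False
        if res is None or not converged:
            try:
                res = model.fit(reml=reml, method="powell", maxiter=500)
                converged = bool(res.converged)
                notes.append("lbfgs failed; powell refit")
            except Exception as err:  # noqa: BLE001
                raise RuntimeError(f"mixed-model fit failed: {err}") from err

    mech = _RemlMachinery(model)
    cov_re = np.atleast_2d(res.cov_re) if mech.k_re else None
    vcomp = np.asarray(res.vcomp, float) if mech.n_vc else np.empty(0)
    theta = mech.pack(cov_re, vcomp, res.scale)
    singular = False
    if mech.k_re:
        d = np.diag(np.atleast_2d(res.cov_re))
        singular = bool(np.any(d < 1e-8 * res.scale))
    if mech.n_vc and np.any(vcomp < 1e-8 * res.scale):
        singular = True
    if singular:
        notes.append("variance estimate at boundary")

    names = list(model.exog_names)
    beta = np.asarray(res.fe_params, float)
    terms: dict[str, TermTest] = {}
    for k, name in enumerate(names):
        l = np.zeros(len(names))
        l[k] = 1.0
        df_den, var_l = satterthwaite_df(mech, theta, l)
        se = float(np.sqrt(max(var_l, 1e-300)))
        Fstat = float((beta[k] / se) ** 2) if se > 0 else np.inf
        p = float(sst.f.sf(Fstat, 1, df_den))
        terms[name] = TermTest(float(beta[k]), se, Fstat, 1.0, df_den, p)

    return LmmResult(
        terms=terms,
        formula=formula,
        n_obs=mech.n,
        n_groups=len(mech.labels),
        converged=converged,
        singular=singular,
        notes=notes,
    )
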