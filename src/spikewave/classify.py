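"""Patient-level classification of surgical outcome from the resected /
nonresected corrected IED-to-LoWS delay ratio.

Good outcome (Engel I-II) is the positive class, and *low* metric values
point toward it (short delays in resected tissue of successfully operated
patients).  The classifier is a single threshold learned on a stratified
training split by maximising training accuracy, evaluated on the held-out
validation split, and repeated; all performance metrics are summarised as
median [IQR] over repeats and compared against label-permutation re-runs of
the entire procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "patient_ratio_metric",
    "f1_score",
    "roc_evaluate",
    "train_validate",
    "ClassificationReport",
    "DelayRatioClassifier",
]

METRIC_NAMES = ["odds_ratio", "accuracy", "f1", "specificity", "sensitivity", "npv", "ppv"]


def patient_ratio_metric(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Per-patient ratio of resected over nonresected mean corrected delay.

    Patients with a zero nonresected mean are excluded (the ratio is
    undefined).  Input columns: patient, resected_mean, nonresected_mean.
    """
    out = aggregates.copy()
    bad = out["nonresected_mean"] == 0
    if bad.any():
        warnings.warn(
            f"patient_ratio_metric: excluded {int(bad.sum())} patients with zero "
            "nonresected mean",
            stacklevel=2,
        )
    out = out[~bad].copy()
    out["metric"] = out["resected_mean"] / out["nonresected_mean"]
    return out[["patient", "metric"]]


def f1_score(ppv: float, sn: float) -> float:
    """Harmonic mean of positive predictive value and sensitivity."""
    if not (0 <= ppv <= 1 and 0 <= sn <= 1):
        raise ValueError("ppv and sn must lie in [0, 1]")
    if ppv == 0 and sn == 0:
        warnings.warn("f1_score: ppv = sn = 0; defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * ppv * sn / (ppv + sn)


def roc_evaluate(metrics, labels) -> dict:
    """Rank-based AUC with good outcome as the positive class and low metric
    as the positive direction; z and two-sided p from the Hanley-McNeil
    standard error."""
    m = np.asarray(metrics, float)
    y = np.asarray(labels, bool)
    n1, n2 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sst.rankdata(-m)  # low metric -> high score for the positive class
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = float(np.sqrt(max(var, 1e-300)))
    z = (auc - 0.5) / se if se > 0 else 0.0
    p = 2.0 * sst.norm.sf(abs(z))
    return {"auc": float(auc), "z": float(z), "p": float(p), "n_good": n1, "n_poor": n2}


def _best_threshold(m_train: np.ndarray, y_train: np.ndarray) -> float:
    """Accuracy-maximising threshold (predict good when metric < threshold);
    ties broken toward the lower threshold."""
    s = np.sort(np.unique(m_train))
    cands = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    pred = m_train[None, :] < cands[:, None]
    acc = (pred == y_train[None, :]).mean(axis=1)
    return float(cands[int(np.argmax(acc))])  # argmax returns the first (lowest)


def _confusion_metrics(tp, fp, tn, fn) -> dict:
    def _safe(a, b):
        return a / b if b > 0 else np.nan

    sn = _safe(tp, tp + fn)
    sp = _safe(tn, tn + fp)
    ppv = _safe(tp, tp + fp)
    npv = _safe(tn, tn + fn)
    t = np.array([[tp, fn], [fp, tn]], float)
    if (t == 0).any():
        t = t + 0.5
    return {
        "odds_ratio": float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])),
        "accuracy": _safe(tp + tn, tp + tn + fp + fn),
        "f1": 0.0 if (np.isnan(ppv) or np.isnan(sn) or ppv + sn == 0) else 2 * ppv * sn / (ppv + sn),
        "specificity": sp,
        "sensitivity": sn,
        "npv": npv,
        "ppv": ppv,
    }


@dataclass
class ClassificationReport:
    """Median [IQR] validation metrics, threshold stability, permutation p."""

    summary: dict
    threshold_mean: float
    threshold_sd: float
    per_repeat: pd.DataFrame
    permutation_p: dict = field(default_factory=dict)
    n_patients: int = 0

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "threshold_mean": self.threshold_mean,
            "threshold_sd": self.threshold_sd,
            "permutation_p": self.permutation_p,
            "n_patients": self.n_patients,
        }


def _run_repeats(m, y, n_repeats, split_fraction, rng, max_redraws=50):
    n_good = int(y.sum())
    n_poor = len(y) - n_good
    if n_good < 2 or n_poor < 2:
        raise ValueError("need at least 2 patients per class")
    k_good = min(max(int(round(split_fraction * n_good)), 1), n_good - 1)
    k_poor = min(max(int(round(split_fraction * n_poor)), 1), n_poor - 1)
    # canonical within-class order: results are invariant to patient ordering
    gi, pi = np.flatnonzero(y), np.flatnonzero(~y)
    gi = gi[np.argsort(m[gi], kind="stable")]
    pi = pi[np.argsort(m[pi], kind="stable")]
    rec = {name: np.empty(n_repeats) for name in METRIC_NAMES}
    thresholds = np.empty(n_repeats)
    for r in range(n_repeats):
        for _ in range(max_redraws):
            tr = np.concatenate(
                [rng.choice(gi, k_good, replace=False), rng.choice(pi, k_poor, replace=False)]
            )
            tr_mask = np.zeros(len(y), dtype=bool)
            tr_mask[tr] = True
            if y[tr_mask].any() and (~y[tr_mask]).any() and y[~tr_mask].any() and (~y[~tr_mask]).any():
                break
        thr = _best_threshold(m[tr_mask], y[tr_mask])
        thresholds[r] = thr
        pred = m[~tr_mask] < thr
        truth = y[~tr_mask]
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        tn = int((~pred & ~truth).sum())
        fn = int((~pred & truth).sum())
        for name, v in _confusion_metrics(tp, fp, tn, fn).items():
            rec[name][r] = v
    return rec, thresholds


def train_validate(
    metrics,
    labels,
    n_repeats: int = 1000,
    split_fraction: float = 0.7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated stratified train/validate evaluation of the threshold rule.

    Per repeat, a ``split_fraction`` stratified training set fixes the
    accuracy-maximising threshold; the held-out patients are classified
    (metric below threshold -> predicted good).  Significance against chance
    is assessed by re-running the whole procedure under label permutations.
    """
    m = np.asarray(metrics, float)
    y = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    rec, thresholds = _run_repeats(m, y, n_repeats, split_fraction, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        summary = {
            name: {
                "median": float(np.nanmedian(v)),
                "iqr": [float(np.nanpercentile(v, 25)), float(np.nanpercentile(v, 75))],
            }
            for name, v in rec.items()
        }
        perm_p = {}
        if n_permutations > 0:
            # permutation statistic: the mean over repeats (nearly continuous,
            # unlike the median on a coarse accuracy grid), computed by the
            # identical procedure on permuted labels
            obs = {name: np.nanmean(v) for name, v in rec.items()}
            exceed = {name: 0 for name in METRIC_NAMES}
            for _ in range(n_permutations):
                yp = rng.permutation(y)
                rp, _ = _run_repeats(m, yp, n_repeats, split_fraction, rng)
                for name in METRIC_NAMES:
                    if np.nanmean(rp[name]) >= obs[name]:
                        exceed[name] += 1
            perm_p = {
                name: (1 + exceed[name]) / (n_permutations + 1) for name in METRIC_NAMES
            }
    per_repeat = pd.DataFrame(rec)
    return ClassificationReport(
        summary=summary,
        threshold_mean=float(thresholds.mean()),
        threshold_sd=float(thresholds.std()),
        per_repeat=per_repeat,
        permutation_p=perm_p,
        n_patients=len(y),
    )


class DelayRatioClassifier:
    """Threshold classifier over the per-patient delay-ratio metric,
    sklearn-compatible (fit/predict/score, get_params/set_params).

    ``fit`` learns the accuracy-maximising threshold on (metric, label)
    pairs; ``predict`` labels metrics below ``threshold_`` as good outcome.
    """

    def __init__(self, split_fraction: float = 0.7):
        self.split_fraction = split_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {"split_fraction": self.split_fraction}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        m = np.asarray(X, float).reshape(-1)
        yy = np.asarray(y, bool)
        if len(m) != len(yy):
            raise ValueError("X and y length mismatch")
        if yy.all() or not yy.any():
            raise ValueError("need both classes to fit")
        self.threshold_ = _best_threshold(m, yy)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "threshold_"):
            raise RuntimeError("classifier is not fitted")
        return np.asarray(X, float).reshape(-1) < self.threshold_

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y, bool)).mean())
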