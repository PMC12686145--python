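"""Verification battery for response-prediction models.

ROC curves and AUC, confusion matrices at a stated threshold, calibration
tables, decision-curve analysis (net benefit), and univariate/multivariate
logistic regression with Wald odds-ratio inference.  Labels may be given as
0/1 integers or as "R"/"NR" strings; the positive class is always the
non-responder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "ConfusionMatrix",
    "roc_auc",
    "confusion_at_threshold",
    "youden_threshold",
    "calibration_table",
    "net_benefit_curve",
    "logistic_compare",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        known = set(np.unique(y)) - {"R", "NR"}
        if known:
            raise ValueError(f"unknown labels {sorted(known)}; expected R/NR or 0/1")
        return (y == "NR").astype(int)
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("integer labels must be 0/1")
    return y


@dataclass
class ROCCurve:
    """Threshold-swept ROC curve with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC of scores against binary labels (positive = NR).

    Tied scores move the curve diagonally in one simultaneous step, so the
    trapezoidal AUC equals the Mann–Whitney concordance probability with
    half-credit for ties.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCCurve(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


@dataclass
class ConfusionMatrix:
    """Counts at a stated threshold (predicted positive iff score >= t)."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionMatrix:
    """Confusion matrix with the inclusive >= prediction rule."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    y = _as_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return ConfusionMatrix(tp, fp, tn, fn, float(threshold))


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity − 1."""
    curve = roc_auc(scores, labels)
    j = curve.tpr - curve.fpr
    return float(curve.thresholds[int(np.argmax(j))])


def calibration_table(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Mean predicted probability vs observed event fraction per bin.

    Equal-width bins partition [0, 1]; empty bins are emitted with n = 0 and
    a missing observed fraction.
    """
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _as_binary(labels)
    idx = np.clip(np.floor(p * n_bins).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin_low": b / n_bins,
                "bin_high": (b + 1) / n_bins,
                "n": n,
                "mean_predicted": float(p[mask].mean()) if n else float("nan"),
                "observed": float(y[mask].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def net_benefit_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Decision-curve analysis: net benefit across threshold probabilities.

    NB(pt) = TP/N − (FP/N) · pt/(1−pt) with positives called at prob >= pt;
    the treat-all strategy calls everyone positive, treat-none is zero.
    Thresholds at or above 1 are excluded (undefined).
    """
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 2)
    thresholds = np.asarray(thresholds, dtype=float)
    keep = (thresholds > 0) & (thresholds < 1)
    if not keep.all():
        logger.warning("excluded %d thresholds outside (0, 1)", int((~keep).sum()))
    thresholds = thresholds[keep]
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        called = p >= pt
        tp = np.sum(called & (y == 1)) / n
        fp = np.sum(called & (y == 0)) / n
        odds = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "nb_model": tp - fp * odds,
                "nb_treat_all": prevalence - (1 - prevalence) * odds,
                "nb_treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def logistic_compare(
    outcome,
    covariates: pd.DataFrame,
    mode: str = "multivariate",
) -> pd.DataFrame:
    """Logistic regression of non-response on covariates.

    ``mode='univariate'`` fits one single-covariate model per column;
    ``mode='multivariate'`` fits one joint model.  Returns a table with
    coefficient, SE, odds ratio, Wald 95% CI and p per covariate; fits with
    (near-)perfect separation are flagged and carry no Wald inference.
    """
    if mode not in {"univariate", "multivariate"}:
        raise ValueError(f"mode must be 'univariate' or 'multivariate', got {mode!r}")
    y = _as_binary(outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if covariates.shape[0] != len(y):
        raise ValueError("covariates and outcome lengths differ")
    if len(y) <= covariates.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")

    def fit_one(cols: list[str]) -> list[dict]:
        X = sm.add_constant(covariates[cols].to_numpy(dtype=float))
        flagged = False
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params[1:]
            ses = res.bse[1:]
            if not np.all(np.isfinite(ses)) or np.any(ses > 50):
                flagged = True
        except Exception:
            flagged = True
        rows = []
        for i, c in enumerate(cols):
            if flagged:
                rows.append(
                    {"covariate": c, "mode": mode, "coef": float("nan"),
                     "se": float("nan"), "odds_ratio": float("nan"),
                     "ci_low": float("nan"), "ci_high": float("nan"),
                     "p_value": float("nan"), "separation_flag": True}
                )
                continue
            b, se = float(params[i]), float(ses[i])
            z = b / se
            rows.append(
                {"covariate": c, "mode": mode, "coef": b, "se": se,
                 "odds_ratio": float(np.exp(b)),
                 "ci_low": float(np.exp(b - 1.96 * se)),
                 "ci_high": float(np.exp(b + 1.96 * se)),
                 "p_value": float(2 * norm.sf(abs(z))),
                 "separation_flag": False}
            )
        return rows

    if mode == "multivariate":
        rows = fit_one(list(covariates.columns))
    else:
        rows = [r for c in covariates.columns for r in fit_one([c])]
    return pd.DataFrame(rows)
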