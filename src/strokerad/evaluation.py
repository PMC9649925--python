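"""Model evaluation: AUC with DeLong confidence intervals, the DeLong test
for correlated AUCs, threshold metrics, and decision-curve analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str = "delong-logit"


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray


def _split_scores(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    x = scores[labels == 1]
    y = scores[labels == 0]
    if len(x) == 0 or len(y) == 0:
        raise DataError("need at least one positive and one negative label")
    return x, y


def _placements(x: np.ndarray, y: np.ndarray):
    """DeLong structural components: V10 (per positive), V01 (per negative),
    using the half-weight tie convention."""
    diff = x[:, None] - y[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the pair-counting (Mann-Whitney) estimator; ties count 1/2."""
    x, y = _split_scores(scores, labels)
    v10, _ = _placements(x, y)
    return float(v10.mean())


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC with a 95% CI from the DeLong variance on the logit scale."""
    x, y = _split_scores(scores, labels)
    v10, v01 = _placements(x, y)
    auc = float(v10.mean())
    m, n = len(x), len(y)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    if se == 0 or auc in (0.0, 1.0):
        lo = hi = auc
    else:
        logit = np.log(auc / (1 - auc))
        half = 1.959963984540054 * se / (auc * (1 - auc))
        lo = float(1 / (1 + np.exp(-(logit - half))))
        hi = float(1 / (1 + np.exp(-(logit + half))))
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi, n_pos=m, n_neg=n)


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float]:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Returns ``(p_value, auc_a - auc_b)``.  If the estimated variance of the
    difference is zero (e.g. identical scores) the p-value is 1.0.
    """
    labels = np.asarray(labels).astype(int)
    xa, ya = _split_scores(scores_a, labels)
    xb, yb = _split_scores(scores_b, labels)
    v10a, v01a = _placements(xa, ya)
    v10b, v01b = _placements(xb, yb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(xa), len(ya)
    s10 = np.cov(np.vstack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) > 0:
            warnings.warn("zero DeLong variance with nonzero AUC difference", RuntimeWarning)
        return 1.0, diff
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(p), diff


def confusion_metrics(scores: np.ndarray, labels: np.ndarray,
                      threshold: float) -> dict[str, float]:
    """Accuracy / sensitivity / specificity at ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise DataError("both classes must be present")
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (lowest on ties)."""
    scores = np.asarray(scores, dtype=float)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        m = confusion_metrics(scores, labels, t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def decision_curve(scores: np.ndarray, labels: np.ndarray,
                   grid: np.ndarray) -> NetBenefitCurve:
    """Net benefit NB(t) = TP/N - (FP/N) * t/(1-t) over a threshold grid in (0,1),
    with treat-all and treat-none reference strategies."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ParameterError("threshold grid must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("threshold grid must be strictly increasing")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    N = len(y)
    n_pos = int(y.sum())
    nb_model = np.empty_like(grid)
    nb_all = np.empty_like(grid)
    for i, t in enumerate(grid):
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        odds = t / (1 - t)
        nb_model[i] = tp / N - (fp / N) * odds
        nb_all[i] = n_pos / N - ((N - n_pos) / N) * odds
    return NetBenefitCurve(thresholds=grid, nb_model=nb_model,
                           nb_treat_all=nb_all, nb_treat_none=np.zeros_like(grid))
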