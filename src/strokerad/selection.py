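"""L0 sparse-representation feature selection.

Solves  argmin_w ||l - F w||_2^2 + eta ||w||_0  for a -1/+1 label vector l
and a column-standardized feature matrix F, by greedy forward selection
(orthogonal matching pursuit) with a least-squares refit on the active
support.  The exact problem is NP-hard; the greedy solution is validated
against an exhaustive-subset oracle on small instances in the test suite.
Feature importance is |w_j|; the top-K entries form the selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class SelectionResult:
    w: np.ndarray
    selected: list[int]          # indices sorted by |w| descending (ties: lower index)
    K: int
    names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "names": ([self.names[i] for i in self.selected] if self.names else None),
            "coefficients": [float(self.w[i]) for i in self.selected],
            "K": self.K,
            "meta": self.meta,
        }


def standardize_columns(F: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD); constant columns map to zero."""
    F = np.asarray(F, dtype=float)
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (F - mu) / sd


def sparse_objective(F: np.ndarray, l: np.ndarray, w: np.ndarray, eta: float) -> float:
    """||l - Fw||^2 + eta * ||w||_0."""
    r = l - F @ w
    return float(r @ r + eta * np.count_nonzero(w))


def _refit(F: np.ndarray, l: np.ndarray, support: list[int]) -> np.ndarray:
    Fs = F[:, support]
    coef, _res, rank, _sv = np.linalg.lstsq(Fs, l, rcond=None)
    if rank < len(support):
        warnings.warn("rank-deficient support refit; returning minimum-norm solution",
                      RuntimeWarning, stacklevel=3)
    return coef


#: exact subset enumeration is used up to this many columns
EXACT_ENUMERATION_LIMIT = 12


def _solve_exact(F: np.ndarray, l: np.ndarray, eta: float | None,
                 max_support: int | None) -> np.ndarray:
    """Exact minimizer by enumeration of all supports (small p only).

    Ties break toward fewer columns, then the lexicographically smaller
    support, so the result is deterministic.
    """
    from itertools import combinations

    m, p = F.shape
    cap = min(m, p) if max_support is None else min(max_support, p)
    pen = 0.0 if eta is None else eta
    best_obj = float(l @ l)
    best: tuple[tuple[int, ...], np.ndarray] = ((), np.zeros(0))
    for k in range(1, cap + 1):
        for supp in combinations(range(p), k):
            cols = list(supp)
            coef, _res, _rank, _sv = np.linalg.lstsq(F[:, cols], l, rcond=None)
            r = l - F[:, cols] @ coef
            obj = float(r @ r) + pen * k
            if obj < best_obj - 1e-12:
                best_obj = obj
                best = (supp, coef)
    w = np.zeros(p)
    if best[0]:
        w[list(best[0])] = best[1]
    return w


def solve_sparse(F: np.ndarray, l: np.ndarray,
                 eta: float | None = None,
                 max_support: int | None = None,
                 method: str = "auto") -> np.ndarray:
    """Minimize ||l - Fw||^2 + eta ||w||_0 (or at fixed support budget).

    Small problems (p <= 12) are solved exactly by subset enumeration;
    larger ones by greedy forward selection (OMP) with least-squares refit
    on the active support.  Exactly one budget applies: ``max_support`` caps
    the support size (and wins if both are given); otherwise the support
    grows while adding the best column lowers the penalized objective, i.e.
    while the residual sum-of-squares drop exceeds ``eta``.  Deterministic:
    correlation ties break toward the lower column index.
    """
    F = np.asarray(F, dtype=float)
    l = np.asarray(l, dtype=float).ravel()
    m, p = F.shape if F.ndim == 2 else (len(F), 0)
    w = np.zeros(p)
    if p == 0:
        return w
    if max_support is None and eta is None:
        raise ConfigError("provide eta or max_support")
    if method not in ("auto", "greedy", "exact"):
        raise ConfigError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and p <= EXACT_ENUMERATION_LIMIT):
        return _solve_exact(F, l, eta, max_support)
    limit = min(m, p) if max_support is None else min(max_support, p)

    support: list[int] = []
    resid = l.copy()
    rss = float(resid @ resid)
    active = np.zeros(p, dtype=bool)
    while len(support) < limit:
        corr = np.abs(F.T @ resid)
        corr[active] = -np.inf
        j = int(np.argmax(corr))  # argmax takes the lowest index on ties
        trial = support + [j]
        coef = _refit(F, l, trial)
        r = l - F[:, trial] @ coef
        new_rss = float(r @ r)
        if max_support is None and rss - new_rss <= eta:
            break
        support, resid, rss = trial, r, new_rss
        active[j] = True
        if rss <= 1e-14:
            break
    if support:
        w[support] = _refit(F, l, support)
    return w


def select_top_k(w: np.ndarray, K: int = 100,
                 names: list[str] | None = None) -> SelectionResult:
    """Indices of the K largest |w_j|; ties broken toward the lower index."""
    if K < 0:
        raise ConfigError("K must be >= 0")
    w = np.asarray(w, dtype=float)
    p = w.size
    if K > p:
        warnings.warn(f"K={K} exceeds {p} coefficients; returning all", RuntimeWarning)
        K = p
    order = np.argsort(-np.abs(w), kind="stable")  # stable => lower index wins ties
    n_nonzero = int(np.count_nonzero(w))
    take = min(K, max(n_nonzero, 0)) if n_nonzero else 0
    # keep zero-coefficient slots only if K exceeds the nonzero count is not
    # meaningful for importance ranking; |selected| = min(K, #nonzero w)
    selected = [int(i) for i in order[:take]]
    return SelectionResult(w=w, selected=selected, K=K, names=names)


def build_candidate_matrix(features: pd.DataFrame,
                           clinical_design: pd.DataFrame) -> pd.DataFrame:
    """Standardized [radiomic | clinical] candidate matrix for selection
    (513 + 6 = 519 columns with the default blocks)."""
    joined = pd.concat([features.reset_index(drop=True),
                        clinical_design.reset_index(drop=True)], axis=1)
    out = pd.DataFrame(standardize_columns(joined.to_numpy()),
                       columns=list(joined.columns))
    return out


def select_features(candidates: pd.DataFrame, labels: np.ndarray,
                    K: int = 100, eta: float | None = None) -> SelectionResult:
    """End-to-end selection: -1/+1 label coding, OMP with a K-sized support
    budget (or eta if given), importance ranking by |w|."""
    l = np.where(np.asarray(labels) > 0, 1.0, -1.0)
    F = candidates.to_numpy()
    w = solve_sparse(F, l, eta=eta, max_support=None if eta is not None else K)
    res = select_top_k(w, K, names=list(candidates.columns))
    res.meta = {"solver": "omp+refit", "eta": eta, "K": K, "m": int(F.shape[0])}
    return res
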