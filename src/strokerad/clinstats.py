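"""Cohort statistics: two-sample t-tests (pooled and Welch), Mann-Whitney U
with exact enumeration on small samples, chi-square / Fisher contingency
tests with the expected-count-5 rule, and the grouped "table one" report.

Conventions match the common clinical-reporting style: normally distributed
continuous variables as mean +/- SD with the pooled Student t-test, ordinal
scores as median (IQR) with Mann-Whitney, categorical variables as n (%)
with uncorrected Pearson chi-square when every expected count is >= 5 and
Fisher's exact test (2x2) otherwise.  P-values format to three decimals,
"<0.001" below that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass
class GroupSummary:
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise DataError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise DataError("standard deviations must be >= 0")


def t_test_pooled(s: GroupSummary) -> tuple[float, float]:
    """Pooled-variance two-sample Student t-test from summary statistics."""
    df = s.n1 + s.n2 - 2
    sp2 = ((s.n1 - 1) * s.sd1 ** 2 + (s.n2 - 1) * s.sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
    if se == 0:
        return 0.0, 1.0
    t = (s.mean1 - s.mean2) / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


def t_test_welch(s: GroupSummary) -> tuple[float, float]:
    """Welch variant (unequal variances, Welch-Satterthwaite df)."""
    v1, v2 = s.sd1 ** 2 / s.n1, s.sd2 ** 2 / s.n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        return 0.0, 1.0
    t = (s.mean1 - s.mean2) / se
    df = (v1 + v2) ** 2 / (v1 ** 2 / (s.n1 - 1) + v2 ** 2 / (s.n2 - 1))
    return float(t), float(2 * stats.t.sf(abs(t), df))


def t_test_raw(x, y, pooled: bool = True) -> tuple[float, float]:
    """Raw-data entry point wrapping the same summary-statistic formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = GroupSummary(len(x), float(x.mean()), float(x.std(ddof=1)),
                     len(y), float(y.mean()), float(y.std(ddof=1)))
    return t_test_pooled(s) if pooled else t_test_welch(s)


EXACT_PAIR_LIMIT = 400      # exact enumeration when n1*n2 <= this
_EXACT_COMB_LIMIT = 400_000  # ... and C(n1+n2, n1) is enumerable


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Small samples (n1*n2 <= 400) use exact enumeration of the permutation
    distribution of U (tie-aware); larger samples use the tie-corrected
    normal approximation.  Returns ``(U, p)`` with U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 * n2 <= EXACT_PAIR_LIMIT and comb(n1 + n2, n1) <= _EXACT_COMB_LIMIT:
        mu = n1 * n2 / 2.0
        obs = abs(u1 - mu)
        count = 0
        total = 0
        base = n1 * (n1 + 1) / 2.0
        for pick in combinations(range(n1 + n2), n1):
            u = ranks[list(pick)].sum() - base
            total += 1
            if abs(u - mu) >= obs - 1e-9:
                count += 1
        return u1, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def chi_square(table, mode: str = "auto") -> tuple[float, float, str]:
    """Contingency-table test: Pearson (uncorrected), Yates, or Fisher.

    ``auto``: uncorrected Pearson when all expected counts are >= 5;
    otherwise Fisher's exact test on 2x2 tables, or Pearson with a warning
    on larger tables.  Returns ``(statistic, p, method_used)``; Fisher's
    statistic slot carries the odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DataError("need a table with >= 2 rows and columns")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise DataError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("degenerate table: zero marginal row/column")
    expected = stats.contingency.expected_freq(t)
    if mode == "auto":
        if (expected >= 5).all():
            mode = "pearson"
        elif t.shape == (2, 2):
            mode = "fisher"
        else:
            warnings.warn("expected counts < 5 on a non-2x2 table; using Pearson",
                          RuntimeWarning)
            mode = "pearson"
    if mode == "pearson":
        res = stats.chi2_contingency(t, correction=False)
        return float(res.statistic), float(res.pvalue), "pearson"
    if mode == "yates":
        res = stats.chi2_contingency(t, correction=True)
        return float(res.statistic), float(res.pvalue), "yates"
    if mode == "fisher":
        if t.shape != (2, 2):
            raise DataError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(t)
        return float(odds), float(p), "fisher"
    raise DataError(f"unknown mode {mode!r}")


def format_p(p: float) -> str:
    if np.isnan(p):
        return ""
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


# variable classification for the cohort report
NORMAL_CONTINUOUS = ("age",)
ORDINAL = ("nihss", "mrs90")
CATEGORICAL = ("sex", "smoking", "drinking", "hypertension", "hyperlipidemia",
               "diabetes", "atrial_fibrillation", "toast", "circulation",
               "statins", "antiplatelets", "anticoagulants")


def _variable_row(df: pd.DataFrame, var: str, group: str) -> dict:
    g0 = df[df[group] == 0][var]
    g1 = df[df[group] == 1][var]
    skip = len(g0) == 0 or len(g1) == 0
    if var in NORMAL_CONTINUOUS:
        summary0 = f"{g0.mean():.2f} ± {g0.std(ddof=1):.2f}" if len(g0) else ""
        summary1 = f"{g1.mean():.2f} ± {g1.std(ddof=1):.2f}" if len(g1) else ""
        if skip or len(g0) < 2 or len(g1) < 2:
            return {"variable": var, "type": "continuous", "group0": summary0,
                    "group1": summary1, "test": "skipped", "p": np.nan}
        _, p = t_test_raw(g0, g1, pooled=True)
        return {"variable": var, "type": "continuous", "group0": summary0,
                "group1": summary1, "test": "t-pooled", "p": p}
    if var in ORDINAL:
        def med(s):
            if not len(s):
                return ""
            q1, q3 = np.percentile(s, [25, 75])
            return f"{np.median(s):.0f} ({q1:.0f}, {q3:.0f})"
        if skip:
            return {"variable": var, "type": "ordinal", "group0": med(g0),
                    "group1": med(g1), "test": "skipped", "p": np.nan}
        _, p = mann_whitney(g0.to_numpy(), g1.to_numpy())
        return {"variable": var, "type": "ordinal", "group0": med(g0),
                "group1": med(g1), "test": "mann-whitney", "p": p}
    # categorical
    ct = pd.crosstab(df[var], df[group])
    for col in (0, 1):
        if col not in ct.columns:
            ct[col] = 0
    ct = ct[[0, 1]]
    levels = " / ".join(str(i) for i in ct.index)
    summary0 = " / ".join(str(int(v)) for v in ct[0])
    summary1 = " / ".join(str(int(v)) for v in ct[1])
    if skip or ct.shape[0] < 2:
        return {"variable": var, "type": f"categorical [{levels}]", "group0": summary0,
                "group1": summary1, "test": "skipped", "p": np.nan}
    stat, p, method = chi_square(ct.to_numpy(), mode="auto")
    return {"variable": var, "type": f"categorical [{levels}]", "group0": summary0,
            "group1": summary1, "test": method, "p": p}


def table_one(cohort: pd.DataFrame, group: str = "recurrence",
              variables: tuple[str, ...] | None = None,
              stratify: str | None = None) -> pd.DataFrame:
    """Grouped cohort summary with per-variable tests.

    With ``stratify`` set (e.g. to the TOAST subtype column) the report is
    produced per stratum and concatenated with a ``stratum`` column.
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    if variables is None:
        variables = tuple(v for v in NORMAL_CONTINUOUS + ORDINAL + CATEGORICAL
                          if v in cohort.columns)
    if stratify is not None:
        parts = []
        for level, sub in cohort.groupby(stratify, sort=False):
            rep = table_one(sub, group=group, variables=variables)
            rep.insert(0, "stratum", level)
            parts.append(rep)
        return pd.concat(parts, ignore_index=True)
    rows = [_variable_row(cohort, v, group) for v in variables]
    rep = pd.DataFrame(rows)
    rep["p_formatted"] = rep["p"].map(format_p)
    return rep
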