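"""Nonparametric comparison suite for users x methods macro-F1 tables.

The central object is a complete n-users x k-methods matrix of macro-F1
percentages. On it the suite computes: the Friedman rank test (chi-square
form with the standard tie correction, plus the Iman–Davenport F variant),
the Nemenyi all-pairs post hoc on mean-rank differences, Cliff's delta
effect sizes, and paired t / exact Wilcoxon signed-rank tests for selected
method pairs.

Nemenyi convention: p-values come from the studentized-range distribution
evaluated at q = |R̄_i - R̄_j| / sqrt(k(k+1)/(12 n)) with infinite degrees
of freedom. (Some references evaluate at q*sqrt(2); the convention here is
the one used by the scikit-posthocs Friedman/Nemenyi implementation and by
the published benchmark this package's fixtures reproduce.)

A published benchmark comparison table — per-user macro-F1 percentages of
19 runners under five example-selection strategies — ships with the
package (``data/benchmark_macro_f1.csv``) and serves as the reference
input for the suite's regression tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "MethodScoreTable",
    "load_benchmark_table",
    "friedman_statistic",
    "iman_davenport_f",
    "nemenyi_posthoc",
    "cliffs_delta",
    "paired_tests",
    "summarize",
]


@dataclass(frozen=True)
class MethodScoreTable:
    """Complete users x methods matrix of macro-F1 values (percent)."""

    users: tuple[str, ...]
    methods: tuple[str, ...]
    values: np.ndarray  # shape (n_users, n_methods)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, k = len(self.users), len(self.methods)
        if values.shape != (n, k):
            raise ValueError(
                f"values shape {values.shape} does not match {n} users x {k} methods"
            )
        if n < 1 or k < 1:
            raise ValueError("score table must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("score table contains missing or non-finite cells")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, user_col: str = "user_id") -> "MethodScoreTable":
        if user_col not in df.columns:
            raise ValueError(f"table must contain a {user_col!r} column")
        methods = [c for c in df.columns if c != user_col]
        return cls(
            users=tuple(str(u) for u in df[user_col]),
            methods=tuple(methods),
            values=df[methods].to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.methods))
        df.insert(0, "user_id", list(self.users))
        return df

    def column(self, method: str) -> np.ndarray:
        return self.values[:, self.methods.index(method)]


def load_benchmark_table() -> MethodScoreTable:
    """The bundled reference benchmark of per-user macro-F1 percentages."""
    with resources.files("hedlm.data").joinpath("benchmark_macro_f1.csv").open() as fh:
        return MethodScoreTable.from_dataframe(pd.read_csv(fh))


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sst.rankdata, 1, values)


def friedman_statistic(table: MethodScoreTable) -> tuple[float, float]:
    """Friedman chi-square statistic with tie correction and its p-value.

    Rows are ranked (average ranks on ties); the chi-square form
    12n/(k(k+1)) * sum_j (R̄_j - (k+1)/2)^2 is divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); p from chi-square with
    k-1 degrees of freedom.
    """
    values = table.values
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test needs at least 2 users and 2 methods")
    ranks = _row_ranks(values)
    rbar = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(np.sum((rbar - (k + 1) / 2.0) ** 2))
    tie_sum = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # every row fully tied
        return 0.0, 1.0
    chi2 /= correction
    return chi2, float(sst.chi2.sf(chi2, k - 1))


def iman_davenport_f(table: MethodScoreTable) -> tuple[float, float]:
    """Iman–Davenport F transformation of the Friedman statistic."""
    n, k = table.values.shape
    chi2, _ = friedman_statistic(table)
    denom = n * (k - 1) - chi2
    if denom <= 0:
        return float("inf"), 0.0
    f = (n - 1) * chi2 / denom
    return f, float(sst.f.sf(f, k - 1, (n - 1) * (k - 1)))


def nemenyi_posthoc(table: MethodScoreTable) -> pd.DataFrame:
    """All-pairs Nemenyi p-values on mean-rank differences.

    Symmetric k x k matrix with a unit diagonal, indexed by method name.
    """
    values = table.values
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("Nemenyi post hoc needs at least 2 users and 2 methods")
    rbar = _row_ranks(values).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(rbar[i] - rbar[j]) / se
            p[i, j] = p[j, i] = float(sst.studentized_range.sf(q, k, np.inf))
    return pd.DataFrame(p, index=list(table.methods), columns=list(table.methods))


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("inputs must be non-empty")
    diff = xa[:, None] - ya[None, :]
    gt = int(np.count_nonzero(diff > 0))
    lt = int(np.count_nonzero(diff < 0))
    return (gt - lt) / (xa.size * ya.size)


def paired_tests(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t and Wilcoxon signed-rank p-values for x vs y.

    Wilcoxon drops zero differences and uses the exact null distribution
    for n <= 25 (normal approximation with continuity correction above).
    All differences zero yields (1.0, 1.0) with a warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 2:
        raise ValueError("inputs must be equal-length sequences of length >= 2")
    d = xa - ya
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; tests are degenerate")
        return 1.0, 1.0
    t_p = float(sst.ttest_rel(xa, ya).pvalue)
    nz = d[d != 0]
    method = "exact" if nz.size <= 25 else "approx"
    w_p = float(
        sst.wilcoxon(
            xa, ya, zero_method="wilcox", method=method, correction=(method == "approx")
        ).pvalue
    )
    return t_p, w_p


def summarize(table: MethodScoreTable) -> pd.DataFrame:
    """Per-method mean with sample (primary) and population SDs."""
    values = table.values
    return pd.DataFrame(
        {
            "method": list(table.methods),
            "mean": values.mean(axis=0),
            "sd_sample": values.std(axis=0, ddof=1),
            "sd_population": values.std(axis=0, ddof=0),
        }
    )
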