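"""Univariate analyses: contingency chi-squares and Welch t from summaries.

These are the checks a field team runs on the outcome tables of a cluster
campaign: Pearson chi-square (optionally Yates-corrected for 2x2 tables)
comparing predation frequency across categories, and a two-sample t computed
from group means and standard errors (Welch form) when only summary
statistics are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "pearson_chi2",
    "chi2_monte_carlo_p",
    "welch_t",
    "welch_satterthwaite_dof",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = self.as_array()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table needs >= 2 rows and columns")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("zero marginal: chi-square undefined")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def _coerce(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.as_array()
    arr = np.asarray(table, dtype=float)
    ContingencyTable(tuple(tuple(int(v) for v in row) for row in arr))  # validate
    return arr


def pearson_chi2(table, continuity: bool = False) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom.

    *continuity* applies the Yates correction and is valid only for 2x2
    tables.  Expected counts come from the row/column marginals.
    """
    arr = _coerce(table)
    if continuity and arr.shape != (2, 2):
        raise ValueError("continuity correction applies only to 2x2 tables")
    res = sps.chi2_contingency(arr, correction=continuity)
    return float(res.statistic), int(res.dof)


def chi2_monte_carlo_p(table, n_resamples: int = 9999, seed: int | None = None) -> float:
    """Seeded Monte Carlo p-value for the Pearson statistic under fixed
    margins (an 'exact'-style check for sparse tables)."""
    arr = _coerce(table).astype(int)
    stat, _ = pearson_chi2(arr, continuity=False)
    rng = np.random.default_rng(seed)
    r = arr.sum(axis=1)
    c = arr.sum(axis=0)
    samples = sps.random_table(r, c).rvs(n_resamples, method="patefield", random_state=rng)
    expected = np.outer(r, c) / arr.sum()
    stats_null = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1 + np.sum(stats_null >= stat - 1e-12)) / (n_resamples + 1))


def welch_t(mean1: float, se1: float, mean2: float, se2: float) -> float:
    """Two-sample t statistic from group means and standard errors:
    t = (mean1 - mean2) / sqrt(se1^2 + se2^2).

    This is the Welch (unequal-variance) form evaluated directly on summary
    data — the only form computable when raw measurements are unavailable.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    if se1 == 0 and se2 == 0:
        raise ValueError("both standard errors are zero")
    return (mean1 - mean2) / math.hypot(se1, se2)


def welch_satterthwaite_dof(se1: float, n1: int, se2: float, n2: int) -> float:
    """Welch–Satterthwaite degrees of freedom; needs the group sizes, which
    summary tables do not always print."""
    v1, v2 = se1**2, se2**2
    if v1 + v2 == 0:
        raise ValueError("both standard errors are zero")
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
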