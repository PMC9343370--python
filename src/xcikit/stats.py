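"""Association statistics for the derived XCI categories.

Two-sided Fisher's exact test on 2x2 tables (probability-mass definition:
the p-value sums hypergeometric probabilities of all margin-preserving
tables no more probable than the observed one), the Pearson chi-squared
test used instead when the number of units exceeds 300, and the two-sample
Kolmogorov-Smirnov comparison of fold-change distributions.

The tests themselves are delegated to scipy; the exact-rational enumeration
oracles live in the test suite so each route stays independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact",
    "chi_squared_2x2",
    "choose_test",
    "ks_two_sample",
    "escape_dependence_association",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-classifying two binary labels: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    p_value: float
    test_name: str
    tails: str = "two-sided"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    arr = np.asarray(t, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*arr.ravel().tolist())


def fisher_exact(t) -> TestResult:
    """Two-sided Fisher's exact test; statistic is the sample odds ratio."""
    tab = _as_table(t)
    res = _sps.fisher_exact(tab.as_array(), alternative="two-sided")
    stat = float(res.statistic) if np.isfinite(res.statistic) else None
    return TestResult(stat, float(res.pvalue), "fisher_exact")


def chi_squared_2x2(t, yates: bool = False) -> TestResult:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction
    by default.  Requires all expected counts > 0 (no zero margin)."""
    tab = _as_table(t)
    arr = tab.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero row or column margin")
    res = _sps.chi2_contingency(arr, correction=yates)
    return TestResult(float(res.statistic), float(res.pvalue), "chi_squared")


def choose_test(n_units: int, threshold: int = 300) -> str:
    """Chi-squared when the number of units exceeds the threshold (strict >),
    Fisher's exact otherwise."""
    if n_units < 0:
        raise ValueError("n_units must be >= 0")
    return "chi_squared" if n_units > threshold else "fisher"


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |F_x - F_y|; p-value by exact enumeration when min(n, m) <= 10,
    by the asymptotic two-sample formula otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(x.size, y.size) <= 10 else "asymp"
    res = _sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "ks_two_sample")


def contingency_from_classification(
    classification: pd.DataFrame, exclude: Sequence[str] = ()
) -> np.ndarray:
    """Escape x dependence 2x2 from an allelic classification table.

    Row 1 = escape genes, row 2 = subjective genes; column 1 = dependent,
    column 2 = independent.  ``exclude`` drops features by id (e.g. Xist,
    whose own reads vanish upon Xist deletion and which therefore carries no
    information about dependence of silencing).
    """
    df = classification
    if exclude:
        df = df.loc[~df.index.isin(set(exclude))]
    esc = df["xci_status"].to_numpy() == "escape"
    dep = df["dependence"].to_numpy() == "dependent"
    return np.array(
        [
            [int((esc & dep).sum()), int((esc & ~dep).sum())],
            [int((~esc & dep).sum()), int((~esc & ~dep).sum())],
        ],
        dtype=np.int64,
    )


def escape_dependence_association(
    classification: pd.DataFrame, exclude: Sequence[str] = ()
) -> tuple[ContingencyTable2x2, TestResult]:
    """Fisher association between XCI escape and Xist dependence.

    A degenerate table (an empty row or column — e.g. no gene classified
    dependent) carries no association signal; it is reported with p = 1 and
    a warning rather than an error.
    """
    if len(classification) == 0:
        raise ValueError("classification table is empty")
    arr = contingency_from_classification(classification, exclude=exclude)
    tab = ContingencyTable2x2(*arr.ravel().tolist())
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(
            "degenerate escape x dependence table (empty row or column); "
            "reporting p = 1",
            stacklevel=2,
        )
        return tab, TestResult(None, 1.0, "fisher_exact")
    return tab, fisher_exact(tab)
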