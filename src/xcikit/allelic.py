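"""Allelic imbalance d-scores and XCI classification.

The inactive/active X (Xi/Xa) allelic skew of a feature (gene or peak) is
summarised by the d-score

    d = Reads_Xi / (Reads_Xi + Reads_Xa) - 0.5

so d = -0.5 means fully Xa-monoallelic (complete silencing of the Xi copy),
0 means biallelic balance, and +0.5 fully Xi-monoallelic.  Features with at
least ``min_allelic_reads`` total allelic reads (default 10) are *allelically
analyzable*; the d-score is undefined otherwise.

Classification rules, applied to features analyzable in both conditions:

* **escape vs subjective** (from wild-type counts only): a gene escapes XCI
  when Reads_Xi >= 5% of Reads_Xa, i.e. residual Xi expression survives
  silencing; otherwise it is subject to ("subjective" to) XCI.
* **Xist-dependent vs independent**: a feature is Xist-dependent when its
  d-score rises by at least 0.03 after Xist loss (mutant minus wild type),
  i.e. its Xi silencing depended on continued Xist expression.
* the symmetric three-way **increased / decreased / unchanged** call at
  +/-0.03 used for accessibility and ChIP peaks (and for shYY1 vs shSCR).

All threshold comparisons are evaluated in exact integer arithmetic on the
raw counts (cross-multiplication), so boundary cases such as Reads_Xi/Reads_Xa
exactly 0.05 or a d-score shift of exactly 0.03 are classified without float
rounding.  The float ``d_score`` field is for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "AllelicCount",
    "DScoreRecord",
    "compute_dscore",
    "classify_escape",
    "classify_dependence",
    "classify_dscore_change",
    "run_allelic_pipeline",
]


def _as_fraction(x) -> Fraction:
    """Exact rational view of a threshold given as int, float or Fraction.

    Floats go through their shortest decimal repr, so 0.05 means 1/20 and
    0.03 means 3/100 — the printed thresholds, not their binary neighbours.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(float(x)))


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs of the allelic analysis.

    min_allelic_reads : total Xi+Xa reads required for analyzability (>= 10).
    escape_ratio      : minimum Reads_Xi/Reads_Xa for XCI escape (>= 0.05).
    delta_d           : d-score shift declaring dependence / change (>= 0.03).
    All comparisons are inclusive.
    """

    min_allelic_reads: int = 10
    escape_ratio: float = 0.05
    delta_d: float = 0.03

    def __post_init__(self):
        if self.min_allelic_reads <= 0 or self.escape_ratio <= 0 or self.delta_d <= 0:
            raise ValueError("all thresholds must be positive")

    @property
    def escape_ratio_frac(self) -> Fraction:
        return _as_fraction(self.escape_ratio)

    @property
    def delta_d_frac(self) -> Fraction:
        return _as_fraction(self.delta_d)


@dataclass(frozen=True)
class AllelicCount:
    """Xi/Xa read counts of one feature in one condition."""

    feature_id: str
    reads_xi: int
    reads_xa: int
    condition: str = ""

    def __post_init__(self):
        if self.reads_xi < 0 or self.reads_xa < 0:
            raise ValueError(
                f"{self.feature_id}: allelic read counts must be non-negative"
            )

    @property
    def total(self) -> int:
        return self.reads_xi + self.reads_xa


@dataclass(frozen=True)
class DScoreRecord:
    """Per-feature d-score with analyzability; carries raw counts so that
    downstream threshold rules can be applied exactly."""

    feature_id: str
    condition: str
    analyzable: bool
    d_score: Optional[float]
    reads_xi: int
    reads_xa: int

    @property
    def d_exact(self) -> Fraction:
        if not self.analyzable:
            raise ValueError(f"{self.feature_id}: d-score undefined (not analyzable)")
        return Fraction(self.reads_xi, self.reads_xi + self.reads_xa) - Fraction(1, 2)


def compute_dscore(c: AllelicCount, th: Thresholds = Thresholds()) -> DScoreRecord:
    """d = Reads_Xi/(Reads_Xi+Reads_Xa) - 0.5, defined when total >= min reads."""
    if c.reads_xi < 0 or c.reads_xa < 0:
        raise ValueError("negative counts")
    analyzable = c.total >= th.min_allelic_reads
    d = c.reads_xi / c.total - 0.5 if analyzable else None
    return DScoreRecord(c.feature_id, c.condition, analyzable, d, c.reads_xi, c.reads_xa)


def classify_escape(wt: AllelicCount, th: Thresholds = Thresholds()) -> str:
    """'escape' iff Reads_Xi >= escape_ratio * Reads_Xa in wild type.

    Evaluated by integer cross-multiplication, so xa = 0 with xi > 0 is
    escape (unbounded ratio) and no division is performed.  Refuses
    non-analyzable input: the caller must filter first.
    """
    if wt.total < th.min_allelic_reads:
        raise ValueError(
            f"{wt.feature_id}: not allelically analyzable "
            f"({wt.total} < {th.min_allelic_reads} reads); filter before classifying"
        )
    r = th.escape_ratio_frac
    return "escape" if wt.reads_xi * r.denominator >= wt.reads_xa * r.numerator else "subjective"


def _delta_at_least(d1: DScoreRecord, d2: DScoreRecord, delta: Fraction) -> bool:
    """Exact test of d2 - d1 >= delta on raw counts.

    d2 - d1 = xi2/n2 - xi1/n1; cross-multiplying by n1*n2*q (all positive)
    gives q*(xi2*n1 - xi1*n2) >= p*n1*n2 for delta = p/q.
    """
    n1 = d1.reads_xi + d1.reads_xa
    n2 = d2.reads_xi + d2.reads_xa
    lhs = delta.denominator * (d2.reads_xi * n1 - d1.reads_xi * n2)
    return lhs >= delta.numerator * n1 * n2


def _check_pair(d1: DScoreRecord, d2: DScoreRecord) -> None:
    if d1.feature_id != d2.feature_id:
        raise ValueError(f"feature id mismatch: {d1.feature_id!r} vs {d2.feature_id!r}")
    if not (d1.analyzable and d2.analyzable):
        raise ValueError(
            f"{d1.feature_id}: both conditions must be analyzable; filter first"
        )


def classify_dependence(
    d1: DScoreRecord, d2: DScoreRecord, th: Thresholds = Thresholds()
) -> str:
    """'dependent' iff condition-2 d-score minus condition-1 d-score >= delta_d
    (inclusive), e.g. Xi-dXist minus WT >= 0.03."""
    _check_pair(d1, d2)
    return "dependent" if _delta_at_least(d1, d2, th.delta_d_frac) else "independent"


def classify_dscore_change(
    d1: DScoreRecord, d2: DScoreRecord, th: Thresholds = Thresholds()
) -> str:
    """Three-way d-score change call with inclusive boundaries at +/-delta_d."""
    _check_pair(d1, d2)
    if _delta_at_least(d1, d2, th.delta_d_frac):
        return "increased"
    if _delta_at_least(d2, d1, th.delta_d_frac):
        return "decreased"
    return "unchanged"


# ---------------------------------------------------------------------------
# vectorised pipeline over count tables
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("feature_id", "reads_xi", "reads_xa")


def _validate_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"{name}: duplicated feature_id {dup!r}")
    if (df["reads_xi"] < 0).any() or (df["reads_xa"] < 0).any():
        raise ValueError(f"{name}: negative counts")
    return df.set_index("feature_id")


def run_allelic_pipeline(
    wt_table: pd.DataFrame,
    mut_table: pd.DataFrame,
    th: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Escape and dependence classification of a WT/mutant allelic count pair.

    Both tables need columns feature_id, reads_xi, reads_xa.  Only features
    allelically analyzable in BOTH conditions are classified; escape status
    comes from the WT counts alone, dependence from the d-score difference.

    Returns a frame indexed by feature_id with columns reads_xi_wt,
    reads_xa_wt, reads_xi_mut, reads_xa_mut, d_wt, d_mut, delta_d,
    xci_status, dependence, xa_zero_escape (flag for the xa=0 convention).
    The classification counts are attached as ``result.attrs['summary']``.
    """
    wt = _validate_table(wt_table, "wt_table")
    mut = _validate_table(mut_table, "mut_table")

    common = wt.index.intersection(mut.index)
    xi1 = wt.loc[common, "reads_xi"].to_numpy(np.int64)
    xa1 = wt.loc[common, "reads_xa"].to_numpy(np.int64)
    xi2 = mut.loc[common, "reads_xi"].to_numpy(np.int64)
    xa2 = mut.loc[common, "reads_xa"].to_numpy(np.int64)
    n1, n2 = xi1 + xa1, xi2 + xa2
    keep = (n1 >= th.min_allelic_reads) & (n2 >= th.min_allelic_reads)

    if not keep.any():
        warnings.warn(
            "no feature is allelically analyzable in both conditions; "
            "returning empty classification",
            stacklevel=2,
        )

    xi1, xa1, xi2, xa2, n1, n2 = (a[keep] for a in (xi1, xa1, xi2, xa2, n1, n2))
    idx = common[keep]

    d1 = xi1 / n1 - 0.5
    d2 = xi2 / n2 - 0.5

    r = th.escape_ratio_frac
    escape = xi1 * r.denominator >= xa1 * r.numerator
    dd = th.delta_d_frac
    # exact: dd.den * (xi2*n1 - xi1*n2) >= dd.num * n1 * n2   (int64 safe for
    # counts up to ~1e6 with the default 3/100 threshold)
    dependent = dd.denominator * (xi2 * n1 - xi1 * n2) >= dd.numerator * n1 * n2

    out = pd.DataFrame(
        {
            "reads_xi_wt": xi1,
            "reads_xa_wt": xa1,
            "reads_xi_mut": xi2,
            "reads_xa_mut": xa2,
            "d_wt": d1,
            "d_mut": d2,
            "delta_d": d2 - d1,
            "xci_status": np.where(escape, "escape", "subjective"),
            "dependence": np.where(dependent, "dependent", "independent"),
            "xa_zero_escape": (xa1 == 0) & (xi1 > 0),
        },
        index=idx,
    )
    out.attrs["summary"] = {
        "n_input_wt": int(len(wt)),
        "n_input_mut": int(len(mut)),
        "n_common": int(len(common)),
        "n_analyzable": int(len(out)),
        "n_escape": int(escape.sum()),
        "n_subjective": int((~escape).sum()),
        "n_dependent": int(dependent.sum()),
        "n_dependent_escape": int((escape & dependent).sum()),
        "n_dependent_subjective": int((~escape & dependent).sum()),
    }
    return out
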