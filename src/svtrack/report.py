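"""Group-comparison arithmetic: fold/percent changes, Q10, t-tests and
class-proportion tables.

These are the small, exact computations that turn per-terminal diffusion
coefficients and per-track classifications into headline comparisons —
for instance a drug raising ensemble D from 0.065 to 0.093 µm²/s is a
1.4-fold, +43% change.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChange",
    "TTestResult",
    "fold_and_percent",
    "round_fold",
    "q10",
    "two_sample_ttest",
    "proportion_table",
]


@dataclass(frozen=True)
class FoldChange:
    """a relative to b: fold = a/b; percent_change signed ((a-b)/b·100)."""

    fold: float
    percent_change: float

    @property
    def percent_increase(self) -> float:
        return self.percent_change

    @property
    def percent_decrease(self) -> float:
        return -self.percent_change


def fold_and_percent(value_a: float, value_b: float) -> FoldChange:
    """Fold change a/b and signed percent change of a relative to b."""
    if value_b <= 0:
        raise ValueError("reference value_b must be > 0")
    fold = value_a / value_b
    return FoldChange(fold=fold, percent_change=(value_a - value_b) / value_b * 100.0)


def round_fold(fold: float, as_integer: bool = False) -> float:
    """Reporting convention: one decimal place, half-up; or nearest integer
    where a whole-number fold is quoted ('seven times')."""
    q = Decimal("1") if as_integer else Decimal("0.1")
    return float(Decimal(repr(fold)).quantize(q, rounding=ROUND_HALF_UP))


def q10(d1: float, t1: float, d2: float, t2: float) -> float:
    """Temperature coefficient: Q10 = (D1/D2) ** (10 / (T1 - T2)).

    ``(d1, t1)`` and ``(d2, t2)`` are rate/temperature pairs in µm²/s and
    °C; the formula is symmetric under swapping the pairs.
    """
    if t1 == t2:
        raise ValueError("temperatures must differ")
    if d1 <= 0 or d2 <= 0:
        raise ValueError("rates must be > 0")
    return float((d1 / d2) ** (10.0 / (t1 - t2)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool
    df: float


def two_sample_ttest(group_a, group_b, equal_var: bool = True,
                     alpha: float = 0.05) -> TTestResult:
    """Two-tailed unpaired t-test (Student by default, Welch optional)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       significant=bool(res.pvalue < alpha), df=float(res.df))


def proportion_table(summaries: pd.DataFrame) -> dict:
    """Percentages of tracks per S/M/L length class and per modality.

    Also reports the combined 'active' share (facilitated + impeded).
    Percentages are over classified tracks and sum to 100 within rounding.
    """
    if len(summaries) == 0:
        raise ValueError("no classified tracks")
    n = len(summaries)
    length = {c: 100.0 * float((summaries["length_class"] == c).sum()) / n
              for c in ("S", "M", "L")}
    modal = {c: 100.0 * float((summaries["modality"] == c).sum()) / n
             for c in ("diffusive", "active_facilitated", "active_impeded")}
    modal["active"] = modal["active_facilitated"] + modal["active_impeded"]
    return {"n": n, "length_pct": length, "modality_pct": modal}
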