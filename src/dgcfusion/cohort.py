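"""Cohort-level counting and association tests.

Recurrence and prevalence counting plus the 2x2 and rank tests used to
relate fusion status to driver mutations and clinical variables:

* Pearson chi-square on a 2x2 table, **without** continuity correction
  (the uncorrected statistic is what reproduces the study-style P values;
  Yates correction is available behind a flag),
* Fisher's exact test (two-sided, by summing hypergeometric probabilities
  no larger than the observed table's),
* the Wilcoxon rank-sum / Mann-Whitney test (normal approximation with tie
  correction by default; exact enumeration available for small samples).

The test statistics are computed from first principles; scipy supplies
only the chi-square/normal distribution functions for p-value lookup.
Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortError",
    "TwoByTwo",
    "load_cohort",
    "round_percent",
    "fusion_prevalence",
    "find_recurrent",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "mutual_exclusivity_report",
]

BOOL_TRUE = {"1", "true", "True", "TRUE", "yes"}
BOOL_FALSE = {"0", "false", "False", "FALSE", "no"}
MISSING = {"", "NA", "na", "NaN", "nan", "."}


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class TwoByTwo:
    """Cell counts with rows = group and columns = outcome:

        a  b      (group 1: outcome+, outcome-)
        c  d      (group 2: outcome+, outcome-)
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortError("2x2 cells must be non-negative")
        if self.n == 0:
            raise CohortError("2x2 table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV indexed by sample_id.

    Boolean-like columns (fusion statuses, mutation flags, CIN, event, ...)
    are parsed to pandas nullable booleans; empty/NA cells stay missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise CohortError("cohort table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise CohortError("duplicate sample_ids in cohort table")
    df = df.set_index("sample_id")
    out = {}
    for col in df.columns:
        series = df[col]
        vals = set(series.dropna().unique()) - MISSING
        if vals and vals <= (BOOL_TRUE | BOOL_FALSE):
            out[col] = series.map(
                lambda v: True if v in BOOL_TRUE else (False if v in BOOL_FALSE else pd.NA)
            ).astype("boolean")
        else:
            try:
                out[col] = pd.to_numeric(series)
            except (ValueError, TypeError):
                out[col] = series
    result = pd.DataFrame(out, index=df.index)
    if "survival_months" in result.columns and (result["survival_months"].dropna() < 0).any():
        raise CohortError("survival_months must be non-negative")
    return result


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` (4.35 -> 4.4 style)."""
    if total <= 0:
        raise CohortError("total must be positive")
    pct = Decimal(100 * count) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def fusion_prevalence(
    cohort: pd.DataFrame, fusion_names: Sequence[str]
) -> tuple[int, int, float]:
    """Count samples positive for at least one named fusion.

    Returns ``(count, n, percent)`` with the percent rounded half-up to one
    decimal.  An empty fusion list yields ``(0, n, 0.0)``.
    """
    n = len(cohort)
    if not fusion_names:
        return 0, n, 0.0
    for name in fusion_names:
        if name not in cohort.columns:
            raise CohortError(f"unknown fusion column {name!r}")
    positive = cohort[list(fusion_names)].fillna(False).any(axis=1)
    count = int(positive.sum())
    return count, n, round_percent(count, n)


def find_recurrent(sample_counts: dict[str, int], min_samples: int = 2) -> set[str]:
    """Fusions present in >= ``min_samples`` distinct samples."""
    return {name for name, k in sample_counts.items() if k >= min_samples}


def chi_square_2x2(t: TwoByTwo, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table; continuity correction off by default.

    Returns ``(statistic, df, p)``.  Undefined (raises) when any marginal
    is zero.
    """
    if min(t.margins) == 0:
        raise CohortError("chi-square undefined: zero marginal total")
    r1, r2, c1, c2 = t.margins
    n = t.n
    observed = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    expected = np.outer([r1, r2], [c1, c2]) / n
    diff = np.abs(observed - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, 1, float(stats.chi2.sf(stat, 1))


def _hypergeom_pmf(a: int, r1: int, c1: int, n: int) -> float:
    """P(first cell = a) under fixed margins (hypergeometric)."""
    return math.comb(r1, a) * math.comb(n - r1, c1 - a) / math.comb(n, c1)


def fisher_exact_2x2(t: TwoByTwo, sidedness: str = "two-sided") -> float:
    """Fisher's exact test p-value on a 2x2 table.

    Two-sided p sums hypergeometric probabilities that do not exceed the
    observed table's (with a small relative tolerance against floating-point
    ties); "greater"/"less" are one-sided on the first cell.
    """
    r1, _, c1, _ = t.margins
    n = t.n
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = _hypergeom_pmf(t.a, r1, c1, n)
    if sidedness == "two-sided":
        total = sum(
            p for a in range(lo, hi + 1)
            if (p := _hypergeom_pmf(a, r1, c1, n)) <= p_obs * (1 + 1e-9)
        )
    elif sidedness == "greater":
        total = sum(_hypergeom_pmf(a, r1, c1, n) for a in range(t.a, hi + 1))
    elif sidedness == "less":
        total = sum(_hypergeom_pmf(a, r1, c1, n) for a in range(lo, t.a + 1))
    else:
        raise CohortError(f"unknown sidedness {sidedness!r}")
    return min(1.0, float(total))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], method: str = "normal"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided.

    Returns ``(U, p)`` with U the Mann-Whitney statistic of group ``a``.
    ``method="normal"`` uses the normal approximation with tie correction
    and a continuity correction of 1/2; ``method="exact"`` enumerates rank
    assignments (small, tie-free samples only).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise CohortError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if method == "exact":
        if len(np.unique(pooled)) != len(pooled):
            raise CohortError("exact method requires tie-free data")
        total = math.comb(n1 + n2, n1)
        count = 0
        all_ranks = range(1, n1 + n2 + 1)
        crit = min(u1, n1 * n2 - u1)
        for combo in combinations(all_ranks, n1):
            u = sum(combo) - n1 * (n1 + 1) / 2.0
            if min(u, n1 * n2 - u) <= crit + 1e-12:
                count += 1
        return u1, count / total

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    return u1, float(2 * stats.norm.sf(max(z, 0.0)))


def mutual_exclusivity_report(
    cohort: pd.DataFrame,
    fusion_names: Sequence[str],
    mutation_flag: str,
) -> dict:
    """Test mutual exclusivity between fusion positivity and a mutation flag.

    Builds the 2x2 over samples with a non-missing mutation flag (the
    "sequenced" subset; missing flags are excluded test-wise) and runs both
    the uncorrected chi-square and Fisher's exact test.
    """
    if mutation_flag not in cohort.columns:
        raise CohortError(f"unknown mutation flag {mutation_flag!r}")
    flags = cohort[mutation_flag]
    informative = cohort[flags.notna()]
    if len(informative) < 2:
        raise CohortError("fewer than 2 samples with a non-missing mutation flag")
    fusion_pos = informative[list(fusion_names)].fillna(False).any(axis=1)
    mut = informative[mutation_flag].astype(bool)
    a = int((fusion_pos & mut).sum())
    b = int((fusion_pos & ~mut).sum())
    c = int((~fusion_pos & mut).sum())
    d = int((~fusion_pos & ~mut).sum())
    table = TwoByTwo(a, b, c, d)
    chi_stat, _, chi_p = chi_square_2x2(table)
    fisher_p = fisher_exact_2x2(table)
    frac_neg = round_percent(c, c + d) if (c + d) else None
    return {
        "mutation_flag": mutation_flag,
        "table": table,
        "n_informative": len(informative),
        "mutated_fraction_fusion_negative": frac_neg,
        "chi_square": chi_stat,
        "chi_square_p": chi_p,
        "fisher_p": fisher_p,
    }
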