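"""Fisher's-exact enrichment of descriptors within groups, plus 2x2 risk
statistics (odds ratio, relative risk).

Enrichment asks, for each (group, descriptor) pair, how surprising the
observed overlap is under random draws from the annotated population: a
one-sided upper-tail hypergeometric probability, i.e. the one-sided
Fisher's exact test for over-representation. P-values are adjusted for
multiplicity within each descriptor category (Benjamini-Hochberg by
default, Bonferroni optionally) and rows with fewer than ``min_observed``
members are retained but flagged unreported.

The hypergeometric tail is computed with exact rational arithmetic so the
p-values are correct to the last floating-point digit; risk statistics
delegate the two-sided Fisher test to scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb, exp, log, sqrt
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatsError

__all__ = [
    "hypergeom_tail",
    "enrich",
    "co_enrich",
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "OddsRatioResult",
    "odds_ratio",
    "relative_risk",
]

ENRICHMENT_COLUMNS = [
    "group_label",
    "category",
    "descriptor",
    "group_size",
    "descriptor_total",
    "population",
    "observed",
    "expected",
    "p_value",
    "adjusted_p",
    "reported",
]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts descriptor members in a group of size ``n`` drawn without
    replacement from a population of ``N`` scans of which ``K`` carry the
    descriptor. Computed with exact rational arithmetic.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise StatsError(f"{name} must be a non-negative integer, got {v}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if k > n or n > N or K > N:
        raise StatsError(f"bounds violated: k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    total = comb(N, n)
    tail = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1))
    return float(Fraction(tail, total))


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    if len(p_values) == 0:
        return p_values
    if method in ("bh", "fdr_bh"):
        return multipletests(p_values, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p_values, method="bonferroni")[1]
    raise StatsError(f"unknown adjustment method {method!r}")


def enrich(
    groups: Mapping[str, Iterable[str]],
    annotations: pd.DataFrame,
    categories: Optional[Iterable[str]] = None,
    min_observed: int = 3,
    adjust_method: str = "bh",
    population: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Test every group for over-representation of every descriptor.

    Parameters
    ----------
    groups
        Mapping group label -> iterable of scan IDs (clusters, or
        diagnostic-class sets).
    annotations
        DataFrame indexed by scan_id; one column per descriptor category.
        NaN entries drop the scan from that category's tests only.
    categories
        Category columns to test (default: all columns of ``annotations``).
    min_observed
        Rows with observed < min_observed keep their statistics but carry
        ``reported=False``.
    adjust_method
        'bh' (Benjamini-Hochberg, default) or 'bonferroni'; applied across
        all rows of the same category.
    population
        Scan universe; defaults to the annotation index. Groups are
        intersected with it.

    Returns one row per (group, category, descriptor) as an EnrichmentTable
    DataFrame.
    """
    universe = list(annotations.index if population is None else population)
    if len(set(universe)) != len(universe):
        raise StatsError("population contains duplicate scan IDs")
    universe_set = set(universe)
    if categories is None:
        categories = list(annotations.columns)
    rows = []
    for category in categories:
        ann = annotations[category].reindex(universe).dropna()
        pop = set(ann.index)
        N = len(pop)
        if N == 0:
            continue
        totals = ann.value_counts()
        for group_label, members in groups.items():
            member_set = set(members) & universe_set
            if not member_set:
                warnings.warn(
                    f"group {group_label!r} is empty within the population; skipped",
                    stacklevel=2,
                )
                continue
            group_ann = ann.reindex(sorted(member_set & pop)).dropna()
            n = len(group_ann)
            if n == 0:
                continue
            observed_counts = group_ann.value_counts()
            for descriptor, K in totals.items():
                k = int(observed_counts.get(descriptor, 0))
                rows.append(
                    {
                        "group_label": group_label,
                        "category": category,
                        "descriptor": descriptor,
                        "group_size": n,
                        "descriptor_total": int(K),
                        "population": N,
                        "observed": k,
                        "expected": n * int(K) / N,
                        "p_value": hypergeom_tail(k, n, int(K), N),
                        "reported": k >= min_observed,
                    }
                )
    table = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "adjusted_p"])
    if table.empty:
        table["adjusted_p"] = pd.Series(dtype=float)
        return table[ENRICHMENT_COLUMNS]
    table["adjusted_p"] = np.nan
    for category, idx in table.groupby("category").groups.items():
        table.loc[idx, "adjusted_p"] = _adjust(
            table.loc[idx, "p_value"].to_numpy(), adjust_method
        )
    return table[ENRICHMENT_COLUMNS].sort_values(
        ["category", "group_label", "p_value"], kind="stable"
    ).reset_index(drop=True)


def co_enrich(
    groups: Mapping[str, Iterable[str]],
    annotations: pd.DataFrame,
    category_pair: tuple[str, str],
    min_observed: int = 3,
    adjust_method: str = "bh",
    population: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Enrichment of joint descriptors from two categories (labelA & labelB).

    Scans missing either annotation are dropped; the intersection labels
    are tested exactly like single-category descriptors.
    """
    cat_a, cat_b = category_pair
    for cat in (cat_a, cat_b):
        if cat not in annotations.columns:
            raise StatsError(f"category {cat!r} not annotated")
    joint = (
        annotations[[cat_a, cat_b]]
        .dropna()
        .apply(lambda r: f"{r[cat_a]} & {r[cat_b]}", axis=1)
    )
    combined = joint.to_frame(name=f"{cat_a}&{cat_b}")
    return enrich(
        groups,
        combined,
        min_observed=min_observed,
        adjust_method=adjust_method,
        population=population,
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts::

            outcome+  outcome-
        exposed     a        b
        unexposed   c        d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if int(v) != v or v < 0:
                raise StatsError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise StatsError("empty 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (int(self.a), int(self.b), int(self.c), int(self.d))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum, over all tables with the observed
    margins, of hypergeometric probabilities not exceeding the observed
    table's probability. Exact rational arithmetic throughout."""
    a, b, c, d = table.cells
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    total = comb(n, col1)
    probs = {
        x: Fraction(comb(row1, x) * comb(n - row1, col1 - x), total)
        for x in range(lo, hi + 1)
    }
    observed = probs[a]
    return float(sum(p for p in probs.values() if p <= observed))


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str
    corrected: bool  # Haldane-Anscombe 0.5 applied


def odds_ratio(
    table: ContingencyTable2x2, ci_method: str = "woolf", alpha: float = 0.05
) -> OddsRatioResult:
    """Cross-product odds ratio with CI and a two-sided Fisher exact p.

    A Haldane-Anscombe correction (0.5 added to every cell) is applied to
    the point estimate and the Woolf interval iff any cell is zero; the
    p-value always uses the raw counts. ``ci_method`` is 'woolf'
    (log-OR +/- z * SE, default) or 'conditional-exact'.
    """
    a, b, c, d = table.cells
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise StatsError("odds ratio undefined: a zero margin (two zero cells)")
    corrected = 0 in (a, b, c, d)
    if corrected:
        fa, fb, fc, fd = (x + 0.5 for x in (a, b, c, d))
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    or_point = (fa * fd) / (fb * fc)
    p_value = fisher_exact_two_sided(table)
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "woolf":
        se = sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
        ci_low = exp(log(or_point) - z * se)
        ci_high = exp(log(or_point) + z * se)
    elif ci_method == "conditional-exact":
        res = stats.contingency.odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        ci_low, ci_high = float(ci.low), float(ci.high)
    else:
        raise StatsError(f"unknown ci_method {ci_method!r}")
    return OddsRatioResult(
        odds_ratio=float(or_point),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        ci_method=ci_method,
        corrected=corrected,
    )


def relative_risk(table: ContingencyTable2x2) -> float:
    """Risk ratio [a/(a+b)] / [c/(c+d)]; infinite when the baseline risk is 0."""
    a, b, c, d = table.cells
    if a + b == 0 or c + d == 0:
        raise StatsError("relative risk requires both exposure rows non-empty")
    risk_exposed = a / (a + b)
    risk_unexposed = c / (c + d)
    if risk_unexposed == 0:
        if risk_exposed == 0:
            raise StatsError("relative risk undefined: both risks are zero")
        warnings.warn("baseline risk is zero; relative risk is infinite", stacklevel=2)
        return float("inf")
    return risk_exposed / risk_unexposed
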