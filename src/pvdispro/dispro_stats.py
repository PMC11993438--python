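"""2×2 disproportionality statistics: ROR, PRR, chi-square and signal rules.

For an index drug and an event category, reports (or term occurrences) are
cross-classified against a within-class comparator — here the other drugs of
the same class rather than the whole database:

                 in category   not in category
    index drug        a               b
    comparator        c               d

The reporting odds ratio is ROR = (a·d)/(b·c) with the Woolf log-scale 95%
interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); the proportional
reporting ratio is PRR = [a/(a+b)] / [c/(c+d)] with interval
exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).  A drug–category pair
is flagged as a signal only when the target event count a is at least 3;
given that, the ROR rule requires the lower 95% bound to exceed 1 and the
PRR rule requires the point estimate to be at least 2.  These flags mark
reporting disproportion, a hypothesis for further study — not causality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from scipy.stats import chi2 as _chi2_dist

from .io_ingest import CaseReport

__all__ = [
    "ContingencyTable",
    "EstimateCI",
    "SignalResult",
    "build_table",
    "compute_ror",
    "compute_prr",
    "chi_square",
    "detect_signal",
    "all_signals",
]

Z95 = 1.96  # fixed: only 95% intervals are reported

Unit = Literal["event", "report"]
ZeroCorrection = Literal["none", "haldane"]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """a/b/c/d counts for one (drug, category) pair against a comparator set."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    category: str = ""
    counting_unit: Unit = "event"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True, slots=True)
class EstimateCI:
    """Point estimate with 95% bounds; ``defined`` is False for zero cells."""

    estimate: float
    lower95: float
    upper95: float
    defined: bool = True

    @staticmethod
    def undefined() -> "EstimateCI":
        return EstimateCI(math.nan, math.nan, math.nan, defined=False)


@dataclass(frozen=True, slots=True)
class SignalResult:
    table: ContingencyTable
    ror: EstimateCI
    prr: EstimateCI
    chi2: float
    p_value: float
    count_criterion_met: bool
    ror_signal: bool
    prr_signal: bool


def build_table(
    reports: Sequence[CaseReport],
    drug: str,
    category: str,
    comparator: Iterable[str],
    unit: Unit = "event",
) -> ContingencyTable:
    """Count the 2×2 table for ``drug`` × ``category`` against ``comparator``.

    Reports must already carry ``category_counts`` (see
    :func:`pvdispro.categorize.attach_categories`).  With ``unit="report"``
    a/c count reports mentioning at least one category term and b/d the
    remaining reports; with ``unit="event"`` a/c count in-category term
    occurrences and b/d all other term occurrences (uncategorized terms
    included — they are events too).
    """
    comparator = frozenset(comparator)
    if drug in comparator:
        raise ValueError(f"index drug {drug!r} must not be in the comparator set")
    if not comparator:
        raise ValueError("comparator set must be non-empty")

    a = b = c = d = 0
    for rep in reports:
        if rep.category_counts is None:
            raise ValueError(f"report {rep.case_id!r} has no categories attached")
        if rep.drug == drug:
            in_index = True
        elif rep.drug in comparator:
            in_index = False
        else:
            continue
        if unit == "report":
            hit = 1 if rep.category_counts.get(category, 0) > 0 else 0
            miss = 1 - hit
        else:
            hit = rep.category_counts.get(category, 0)
            miss = len(rep.preferred_terms) - hit
        if in_index:
            a += hit
            b += miss
        else:
            c += hit
            d += miss
    return ContingencyTable(a, b, c, d, drug=drug, category=category, counting_unit=unit)


def _cells(table: ContingencyTable, zero_correction: ZeroCorrection):
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if zero_correction == "haldane":
            return a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return None
    return float(a), float(b), float(c), float(d)


def compute_ror(
    table: ContingencyTable, zero_correction: ZeroCorrection = "none"
) -> EstimateCI:
    """Reporting odds ratio with Woolf 95% CI; undefined on zero cells unless
    the Haldane–Anscombe 0.5 correction is requested."""
    cells = _cells(table, zero_correction)
    if cells is None:
        return EstimateCI.undefined()
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EstimateCI(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def compute_prr(
    table: ContingencyTable, zero_correction: ZeroCorrection = "none"
) -> EstimateCI:
    """Proportional reporting ratio with its log-scale 95% CI."""
    cells = _cells(table, zero_correction)
    if cells is None:
        return EstimateCI.undefined()
    a, b, c, d = cells
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return EstimateCI(prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def chi_square(
    table: ContingencyTable, yates: bool = False
) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square statistic (1 df) and p-value for the 2×2 table.

    Returns ``(None, None)`` when any margin is zero (statistic undefined).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None, None
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / denom
    return stat, float(_chi2_dist.sf(stat, 1))


def detect_signal(
    table: ContingencyTable, zero_correction: ZeroCorrection = "none"
) -> SignalResult:
    """Apply the three signal criteria to one (drug, category) table.

    Fewer than 3 target events forces both signal flags false regardless of
    the estimates.
    """
    ror = compute_ror(table, zero_correction)
    prr = compute_prr(table, zero_correction)
    stat, p = chi_square(table)
    count_ok = table.a >= 3
    return SignalResult(
        table=table,
        ror=ror,
        prr=prr,
        chi2=stat if stat is not None else math.nan,
        p_value=p if p is not None else math.nan,
        count_criterion_met=count_ok,
        ror_signal=bool(count_ok and ror.defined and ror.lower95 > 1.0),
        prr_signal=bool(count_ok and prr.defined and prr.estimate >= 2.0),
    )


def all_signals(
    reports: Sequence[CaseReport],
    drugs: Sequence[str],
    categories: Sequence[str],
    unit: Unit = "event",
    zero_correction: ZeroCorrection = "none",
) -> list[SignalResult]:
    """Signal results for every (drug, category) pair under the within-class
    comparator (each drug against all the others)."""
    results = []
    for drug in drugs:
        comparator = frozenset(drugs) - {drug}
        for category in categories:
            table = build_table(reports, drug, category, comparator, unit=unit)
            results.append(detect_signal(table, zero_correction))
    return results
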