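"""Mapping preferred terms to disease categories and outcome codes to classes.

Adverse events arrive as MedDRA-style preferred terms (PTs).  The analysis
groups them into six fixed disease categories — cardiovascular, cancer,
respiratory, gastrointestinal, musculoskeletal, and arthralgia (a single-term
category reported separately from the broader musculoskeletal group).  The
PT → category mapping is data, not code: it is loaded from YAML and validated;
a small default dictionary ships with the package for simulation and testing.

Report seriousness is carried by the standard FAERS outcome codes, a fixed
seven-class bijection (DE death, LT life-threatening, HO hospitalization,
DS disability, CA congenital anomaly, RI required intervention, OT other
serious).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from .io_ingest import CaseReport

__all__ = [
    "CATEGORIES",
    "OUTCOME_CLASSES",
    "TermDictionary",
    "default_term_dictionary",
    "load_term_dictionary",
    "categorize_terms",
    "classify_outcomes",
    "attach_categories",
]

#: the six disease categories, exactly
CATEGORIES = (
    "cardiovascular",
    "cancer",
    "respiratory",
    "gastrointestinal",
    "musculoskeletal",
    "arthralgia",
)

#: FAERS outcome code → clinical-outcome label (a bijection)
OUTCOME_CLASSES = {
    "CA": "congenital anomaly",
    "DE": "death",
    "DS": "disability",
    "HO": "hospitalization",
    "LT": "life-threatening",
    "RI": "required intervention",
    "OT": "other serious",
}


@dataclass
class TermDictionary:
    """Case-insensitive preferred-term sets for the six disease categories.

    Term sets must be pairwise disjoint so that a term names exactly one
    category; matching is exact on normalized case/whitespace (no substring
    matching, to avoid PT collisions).
    """

    category_terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.category_terms) != set(CATEGORIES):
            raise ValueError(
                f"category keys must be exactly {sorted(CATEGORIES)}, "
                f"got {sorted(self.category_terms)}"
            )
        norm = {
            cat: frozenset(_normalize_term(t) for t in terms)
            for cat, terms in self.category_terms.items()
        }
        seen: dict[str, str] = {}
        for cat, terms in norm.items():
            for t in terms:
                if t in seen:
                    raise ValueError(f"term {t!r} appears in both {seen[t]!r} and {cat!r}")
                seen[t] = cat
        self.category_terms = norm
        self._term_to_category = seen

    def lookup(self, term: str) -> Optional[str]:
        return self._term_to_category.get(_normalize_term(term))


def _normalize_term(term: str) -> str:
    return " ".join(term.lower().split())


def load_term_dictionary(path: str | os.PathLike) -> TermDictionary:
    """Load and validate a YAML category → PT-list mapping."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return _dictionary_from_mapping(data, source=str(path))


def _dictionary_from_mapping(data, source: str) -> TermDictionary:
    if not isinstance(data, dict):
        raise ValueError(f"{source}: expected a mapping of category -> term list")
    terms = {}
    for cat, lst in data.items():
        if not isinstance(lst, list) or not all(isinstance(t, str) for t in lst):
            raise ValueError(f"{source}: category {cat!r} must map to a list of strings")
        terms[str(cat)] = frozenset(lst)
    return TermDictionary(category_terms=terms)


def default_term_dictionary() -> TermDictionary:
    """The packaged stand-in dictionary (see ``data/default_terms.yaml``)."""
    text = resources.files("pvdispro").joinpath("data/default_terms.yaml").read_text("utf-8")
    return _dictionary_from_mapping(yaml.safe_load(text), source="default_terms.yaml")


def categorize_terms(
    preferred_terms: Sequence[str], dictionary: TermDictionary
) -> tuple[set[str], list[str]]:
    """Return the categories mentioned by a report plus unmatched terms.

    A category is present iff at least one term matches its set; terms the
    dictionary does not know are returned separately for audit.
    """
    cats: set[str] = set()
    unmatched: list[str] = []
    for term in preferred_terms:
        cat = dictionary.lookup(term)
        if cat is None:
            unmatched.append(term)
        else:
            cats.add(cat)
    return cats, unmatched


def classify_outcomes(outcome_codes: Sequence[str]) -> tuple[set[str], list[str]]:
    """Map FAERS outcome codes to class labels; unknown codes go to the audit list."""
    labels: set[str] = set()
    unknown: list[str] = []
    for code in outcome_codes:
        label = OUTCOME_CLASSES.get(code.strip().upper())
        if label is None:
            unknown.append(code)
        else:
            labels.add(label)
    return labels, unknown


def attach_categories(
    reports: Iterable[CaseReport], dictionary: TermDictionary
) -> tuple[list[CaseReport], list[str]]:
    """Annotate each report with its category set and per-category event counts.

    ``category_counts`` counts PT occurrences per category (the event counting
    unit); ``categories`` is its key set (the report counting unit).  Returns
    the annotated reports and the audit list of unmatched terms.  Annotation
    is done in place (the input report objects are updated and returned).
    """
    # term strings repeat heavily across reports, so memoize the normalized
    # lookup per distinct raw string
    cache: dict[str, Optional[str]] = {}
    lookup = dictionary.lookup
    audit: list[str] = []
    empty_fs: frozenset[str] = frozenset()
    out = list(reports)
    for rep in out:
        terms = rep.preferred_terms
        if not terms:
            rep.categories = empty_fs
            rep.category_counts = {}
            continue
        counts: dict[str, int] = {}
        for term in terms:
            try:
                cat = cache[term]
            except KeyError:
                cat = cache[term] = lookup(term)
            if cat is None:
                audit.append(term)
            else:
                counts[cat] = counts.get(cat, 0) + 1
        rep.categories = frozenset(counts)
        rep.category_counts = counts
    return out, audit
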