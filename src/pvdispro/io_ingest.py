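"""Reading, normalizing and deduplicating spontaneous adverse-event reports.

Two input dialects are supported:

* ``flat_csv`` — one row per (case, version) with semicolon-joined term and
  outcome lists.  Convenient for simulation output and small fixtures.
* ``faers_ascii`` — the quarterly-extract style layout: four ``$``-delimited
  tables (DEMO / DRUG / REAC / OUTC) joined on the case identifier
  (``primaryid``), with an optional ``caseversion`` column.

After loading, drug names are resolved against a :class:`DrugDictionary`
(brand + generic synonyms), records are filtered to the study window, and
follow-up versions of the same case are collapsed to a single
:class:`CaseReport` (keep-latest-version, the FAERS convention).
"""

from __future__ import annotations

import csv
import glob
import io
import os
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Optional, Sequence

__all__ = [
    "RawRecord",
    "CaseReport",
    "DrugDictionary",
    "LoadReport",
    "default_drug_dictionary",
    "read_records",
    "write_records",
    "normalize_drug",
    "resolve_drugs",
    "filter_study_window",
    "deduplicate",
]

SEXES = ("female", "male", "unknown")

#: plausibility bounds for the calendar-year field
YEAR_MIN, YEAR_MAX = 1990, 2100

_TRADEMARK_GLYPHS = str.maketrans("", "", "®™℠")  # ® ™ ℠

_SEX_ALIASES = {
    "f": "female", "female": "female",
    "m": "male", "male": "male",
    "u": "unknown", "unk": "unknown", "unknown": "unknown", "": "unknown",
}


class IngestError(ValueError):
    """Raised when an input file cannot be interpreted under the named dialect."""


@dataclass(slots=True)
class RawRecord:
    """One raw report row: a single version of a single case.

    ``drug_raw`` is free text; for multi-drug cases it is a ``;``-joined list.
    ``drug`` is filled by :func:`resolve_drugs` once the name is matched to a
    canonical study drug.
    """

    case_id: str
    version: int
    drug_raw: str
    sex: str
    age_years: Optional[float]
    year: int
    preferred_terms: tuple[str, ...]
    outcome_codes: tuple[str, ...]
    drug: Optional[str] = None


@dataclass(slots=True)
class CaseReport:
    """One deduplicated safety report with a resolved canonical drug.

    ``categories`` / ``category_counts`` are filled later by the
    categorization step (report-level category set and per-category event
    counts respectively); they default to ``None`` until then.
    """

    case_id: str
    version: int
    drug: str
    sex: str
    age_years: Optional[float]
    year: int
    preferred_terms: tuple[str, ...]
    outcome_codes: tuple[str, ...]
    categories: Optional[frozenset[str]] = None
    category_counts: Optional[dict[str, int]] = None


@dataclass
class DrugDictionary:
    """Canonical drug → synonym sets (case-insensitive) plus approval dates."""

    entries: dict[str, frozenset[str]]
    approval_dates: dict[str, date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for drug, syns in self.entries.items():
            canon = drug.strip().lower()
            names = {canon} | {_normalize_name(s) for s in syns}
            for name in names:
                if name in seen and seen[name] != canon:
                    raise ValueError(
                        f"synonym {name!r} is claimed by both {seen[name]!r} and {canon!r}"
                    )
                seen[name] = canon
            norm[canon] = frozenset(names)
        self.entries = norm

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.entries)


@dataclass
class LoadReport:
    """Bookkeeping emitted by the loading / cleaning stages."""

    n_loaded: int = 0
    n_skipped: int = 0
    n_unresolved_drug: int = 0
    n_multi_drug: int = 0
    n_duplicates_removed: int = 0
    notes: list[str] = field(default_factory=list)


def default_drug_dictionary() -> DrugDictionary:
    """The three JAK inhibitors studied, with brand synonyms and approval dates."""
    return DrugDictionary(
        entries={
            "tofacitinib": frozenset({"xeljanz", "xeljanz xr", "tofacitinib citrate"}),
            "baricitinib": frozenset({"olumiant"}),
            "upadacitinib": frozenset({"rinvoq"}),
        },
        approval_dates={
            "tofacitinib": date(2012, 11, 6),
            "baricitinib": date(2018, 6, 1),
            "upadacitinib": date(2019, 8, 16),
        },
    )


def _normalize_name(name: str) -> str:
    return " ".join(name.translate(_TRADEMARK_GLYPHS).lower().split())


def normalize_drug(drug_raw: str, dictionary: DrugDictionary) -> Optional[str]:
    """Map a free-text drug name to its canonical study drug, or ``None``.

    Matching is exact after lower-casing, trimming/collapsing whitespace and
    stripping trademark glyphs; unmatched names are a value, not an error.
    """
    name = _normalize_name(drug_raw)
    for drug, synonyms in dictionary.entries.items():
        if name in synonyms:
            return drug
    return None


# ---------------------------------------------------------------------------
# reading / writing


def read_records(
    source: str | os.PathLike | io.TextIOBase,
    dialect: str = "flat_csv",
) -> tuple[list[RawRecord], LoadReport]:
    """Load raw records from ``source`` under the named dialect.

    ``flat_csv`` expects a single CSV file (or open stream); ``faers_ascii``
    expects a directory containing ``DEMO*.txt``, ``DRUG*.txt``, ``REAC*.txt``
    and ``OUTC*.txt``.  Malformed rows are skipped and counted; more than 50%
    malformed rows raises :class:`IngestError` (almost always a wrong-dialect
    mistake).
    """
    if dialect == "flat_csv":
        records, report = _read_flat_csv(source)
    elif dialect == "faers_ascii":
        records, report = _read_faers_ascii(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    total = report.n_loaded + report.n_skipped
    if total > 0 and report.n_skipped > total / 2:
        raise IngestError(
            f"{report.n_skipped}/{total} rows malformed; wrong dialect for this input?"
        )
    return records, report


def _parse_row(
    case_id: str,
    version: str,
    drug_raw: str,
    sex: str,
    age: str,
    year: str,
    terms: Sequence[str],
    outcomes: Sequence[str],
) -> RawRecord:
    case_id = case_id.strip()
    if not case_id:
        raise ValueError("empty case_id")
    y = int(year)
    if not YEAR_MIN <= y <= YEAR_MAX:
        raise ValueError(f"year {y} outside plausible range")
    sex_norm = _SEX_ALIASES.get(sex.strip().lower())
    if sex_norm is None:
        raise ValueError(f"unrecognized sex {sex!r}")
    age_val = float(age) if age.strip() else None
    if age_val is not None and age_val <= 0:
        raise ValueError(f"non-positive age {age_val}")
    v = int(version) if str(version).strip() else 0
    if v < 0:
        raise ValueError(f"negative version {v}")
    return RawRecord(
        case_id=case_id,
        version=v,
        drug_raw=drug_raw.strip(),
        sex=sex_norm,
        age_years=age_val,
        year=y,
        preferred_terms=tuple(t for t in (t.strip() for t in terms) if t),
        outcome_codes=tuple(c for c in (c.strip() for c in outcomes) if c),
    )


FLAT_CSV_COLUMNS = ("case_id", "version", "drug", "sex", "age", "year", "pt_list", "outcome_list")


def _read_flat_csv(source) -> tuple[list[RawRecord], LoadReport]:
    report = LoadReport()
    records: list[RawRecord] = []

    def _consume(fh) -> None:
        reader = csv.DictReader(fh)
        missing = set(FLAT_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise IngestError(f"flat_csv input missing columns: {sorted(missing)}")
        for row in reader:
            try:
                rec = _parse_row(
                    row["case_id"], row["version"], row["drug"], row["sex"],
                    row["age"] or "", row["year"],
                    (row["pt_list"] or "").split(";"),
                    (row["outcome_list"] or "").split(";"),
                )
            except (ValueError, TypeError) as exc:
                report.n_skipped += 1
                if len(report.notes) < 20:
                    report.notes.append(f"skipped row: {exc}")
                continue
            records.append(rec)
            report.n_loaded += 1

    if isinstance(source, io.TextIOBase):
        _consume(source)
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            _consume(fh)
    return records, report


def _read_dollar_table(path: str) -> tuple[list[str], list[list[str]]]:
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except UnicodeDecodeError:
        with open(path, encoding="latin-1") as fh:
            lines = fh.read().splitlines()
    if not lines:
        return [], []
    header = [h.strip().lower() for h in lines[0].split("$")]
    rows = [line.split("$") for line in lines[1:] if line.strip()]
    return header, rows


def _find_table(directory: str, prefix: str) -> Optional[str]:
    hits = sorted(glob.glob(os.path.join(directory, f"{prefix}*.txt")))
    return hits[0] if hits else None


def _read_faers_ascii(directory) -> tuple[list[RawRecord], LoadReport]:
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise IngestError(f"faers_ascii dialect expects a directory, got {directory!r}")
    report = LoadReport()

    paths = {p: _find_table(directory, p) for p in ("DEMO", "DRUG", "REAC", "OUTC")}
    if paths["DEMO"] is None:
        raise IngestError(f"no DEMO*.txt table found in {directory}")

    def table_as_dicts(kind: str) -> list[dict[str, str]]:
        path = paths[kind]
        if path is None:
            report.notes.append(f"no {kind} table found; treating as empty")
            return []
        header, rows = _read_dollar_table(path)
        out = []
        for r in rows:
            if len(r) != len(header):
                report.n_skipped += 1
                continue
            out.append(dict(zip(header, r)))
        return out

    demo = table_as_dicts("DEMO")
    drug_rows = table_as_dicts("DRUG")
    reac_rows = table_as_dicts("REAC")
    outc_rows = table_as_dicts("OUTC")

    def by_case(rows: list[dict[str, str]], col: str) -> dict[str, list[str]]:
        acc: dict[str, list[str]] = {}
        for r in rows:
            pid = r.get("primaryid", "").strip()
            val = r.get(col, "").strip()
            if pid and val:
                acc.setdefault(pid, []).append(val)
        return acc

    drugs = by_case(drug_rows, "drugname")
    terms = by_case(reac_rows, "pt")
    outcomes = by_case(outc_rows, "outc_cod")
    if not reac_rows:
        report.notes.append("REAC table empty: records carry no preferred terms")

    records: list[RawRecord] = []
    for row in demo:
        pid = row.get("primaryid", "").strip()
        try:
            rec = _parse_row(
                pid,
                row.get("caseversion", "0"),
                ";".join(drugs.get(pid, [])),
                row.get("sex", ""),
                row.get("age", ""),
                row.get("year", ""),
                terms.get(pid, []),
                outcomes.get(pid, []),
            )
        except (ValueError, TypeError) as exc:
            report.n_skipped += 1
            if len(report.notes) < 20:
                report.notes.append(f"skipped DEMO row {pid!r}: {exc}")
            continue
        records.append(rec)
        report.n_loaded += 1
    return records, report


def write_records(
    records: Iterable[RawRecord],
    destination: str | os.PathLike,
    dialect: str = "flat_csv",
) -> None:
    """Write raw records in either input dialect (inverse of :func:`read_records`)."""
    if dialect == "flat_csv":
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(FLAT_CSV_COLUMNS)
            for r in records:
                writer.writerow([
                    r.case_id, r.version, r.drug_raw, r.sex,
                    "" if r.age_years is None else r.age_years,
                    r.year, ";".join(r.preferred_terms), ";".join(r.outcome_codes),
                ])
    elif dialect == "faers_ascii":
        directory = os.fspath(destination)
        os.makedirs(directory, exist_ok=True)
        demo, drug, reac, outc = [], [], [], []
        for r in records:
            demo.append([
                r.case_id, str(r.version), r.sex,
                "" if r.age_years is None else str(r.age_years), str(r.year),
            ])
            for name in r.drug_raw.split(";"):
                if name.strip():
                    drug.append([r.case_id, name.strip()])
            for t in r.preferred_terms:
                reac.append([r.case_id, t])
            for c in r.outcome_codes:
                outc.append([r.case_id, c])
        tables = {
            "DEMO": (["primaryid", "caseversion", "sex", "age", "year"], demo),
            "DRUG": (["primaryid", "drugname"], drug),
            "REAC": (["primaryid", "pt"], reac),
            "OUTC": (["primaryid", "outc_cod"], outc),
        }
        for kind, (header, rows) in tables.items():
            with open(os.path.join(directory, f"{kind}.txt"), "w", encoding="utf-8") as fh:
                fh.write("$".join(header) + "\n")
                for row in rows:
                    fh.write("$".join(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# cleaning pipeline


def resolve_drugs(
    records: Sequence[RawRecord],
    dictionary: DrugDictionary,
    report: Optional[LoadReport] = None,
) -> tuple[list[RawRecord], LoadReport]:
    """Attach the canonical study drug to each record.

    Records naming no study drug are dropped (counted as unresolved); records
    naming two or more distinct study drugs are dropped too, because the
    within-class comparator is undefined for them.
    """
    report = report or LoadReport()
    kept: list[RawRecord] = []
    for rec in records:
        matches = {
            m for m in (normalize_drug(n, dictionary) for n in rec.drug_raw.split(";"))
            if m is not None
        }
        if len(matches) == 1:
            kept.append(replace(rec, drug=next(iter(matches))))
        elif len(matches) == 0:
            report.n_unresolved_drug += 1
        else:
            report.n_multi_drug += 1
    return kept, report


def filter_study_window(
    records: Sequence[RawRecord], start_year: int, end_year: int
) -> list[RawRecord]:
    """Keep records whose year lies in the inclusive window; order preserved."""
    if start_year > end_year:
        raise ValueError(f"start_year {start_year} exceeds end_year {end_year}")
    return [r for r in records if start_year <= r.year <= end_year]


def deduplicate(
    records: Sequence[RawRecord],
    report: Optional[LoadReport] = None,
) -> tuple[list[CaseReport], LoadReport]:
    """Collapse follow-up versions: one :class:`CaseReport` per case identifier.

    The highest version wins; ties break to the latest-read record.  Records
    must already carry a resolved canonical drug (see :func:`resolve_drugs`).
    """
    report = report or LoadReport()
    best: dict[str, RawRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.drug is None:
            raise ValueError(f"record {rec.case_id!r} has no resolved drug; run resolve_drugs first")
        prev = best.get(rec.case_id)
        if prev is None:
            best[rec.case_id] = rec
            order.append(rec.case_id)
        else:
            report.n_duplicates_removed += 1
            if rec.version >= prev.version:
                if rec.version == prev.version and len(report.notes) < 20:
                    report.notes.append(f"version tie for case {rec.case_id!r}: kept later record")
                best[rec.case_id] = rec
    out = [
        CaseReport(
            case_id=r.case_id, version=r.version, drug=r.drug, sex=r.sex,
            age_years=r.age_years, year=r.year,
            preferred_terms=r.preferred_terms, outcome_codes=r.outcome_codes,
        )
        for r in (best[cid] for cid in order)
    ]
    return out, report
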