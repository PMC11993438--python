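"""Descriptive summary tables and end-to-end pipeline orchestration.

Produces the study's descriptive outputs — per-drug demographics, annual
report counts, category frequencies, clinical-outcome counts — and the full
ingest → filter → deduplicate → categorize → disproportionality run behind a
single configuration object.

Demographic percentages are computed over each drug's own reports (sex
recorded or explicitly unknown) and rounded half-up to two decimals;
ratio estimates are rendered at four decimals, full precision retained
internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .categorize import (
    CATEGORIES,
    OUTCOME_CLASSES,
    TermDictionary,
    attach_categories,
    classify_outcomes,
    default_term_dictionary,
    load_term_dictionary,
)
from .dispro_stats import SignalResult, all_signals
from .io_ingest import (
    CaseReport,
    DrugDictionary,
    LoadReport,
    default_drug_dictionary,
    deduplicate,
    filter_study_window,
    read_records,
    resolve_drugs,
)
from .synth_data import GeneratorConfig, simulate_to_path

__all__ = [
    "DemographicsRow",
    "OutcomeRow",
    "round_half_up",
    "demographics_table",
    "yearly_counts",
    "category_counts",
    "outcome_table",
    "signals_frame",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


def round_half_up(value: float | Decimal, decimals: int = 2) -> float:
    """Decimal round-half-up (5 rounds away from zero), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, total: int) -> float:
    if total == 0:
        return math.nan
    exact = Decimal(n) * 100 / Decimal(total)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class DemographicsRow:
    drug: str
    n_reports: int
    mean_age: float
    sd_age: float
    n_female: int
    n_male: int
    n_unknown: int
    pct_female: float
    pct_male: float
    pct_unknown: float


@dataclass(slots=True)
class OutcomeRow:
    drug: str
    counts: Dict[str, int]  # outcome label -> report count


def demographics_table(reports: Sequence[CaseReport]) -> list[DemographicsRow]:
    """One demographics row per drug: age moments and sex mix percentages.

    Mean/SD are over reports with a known age (sample SD; 0 when fewer than
    two ages are known); percentages are over all of the drug's reports,
    rounded half-up to two decimals.
    """
    by_drug: dict[str, list[CaseReport]] = {}
    for rep in reports:
        by_drug.setdefault(rep.drug, []).append(rep)
    rows = []
    for drug, reps in by_drug.items():
        n = len(reps)
        ages = [r.age_years for r in reps if r.age_years is not None]
        if len(ages) >= 2:
            mean = sum(ages) / len(ages)
            sd = math.sqrt(sum((a - mean) ** 2 for a in ages) / (len(ages) - 1))
        elif len(ages) == 1:
            mean, sd = ages[0], 0.0
        else:
            mean = sd = math.nan
        counts = {"female": 0, "male": 0, "unknown": 0}
        for r in reps:
            counts[r.sex] += 1
        rows.append(DemographicsRow(
            drug=drug,
            n_reports=n,
            mean_age=mean,
            sd_age=sd,
            n_female=counts["female"],
            n_male=counts["male"],
            n_unknown=counts["unknown"],
            pct_female=_pct(counts["female"], n),
            pct_male=_pct(counts["male"], n),
            pct_unknown=_pct(counts["unknown"], n),
        ))
    return rows


def yearly_counts(
    reports: Sequence[CaseReport],
    year_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Drug × year table of deduplicated report counts (missing years are 0).

    The cells partition the report set: the grand total equals the number of
    input reports.
    """
    if not reports:
        return pd.DataFrame()
    drugs = sorted({r.drug for r in reports})
    if year_range is None:
        year_range = (min(r.year for r in reports), max(r.year for r in reports))
    years = list(range(year_range[0], year_range[1] + 1))
    counts: dict[tuple[str, int], int] = {}
    for r in reports:
        key = (r.drug, r.year)
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(0, index=pd.Index(drugs, name="drug"), columns=years)
    for (drug, year), k in counts.items():
        if year_range[0] <= year <= year_range[1]:
            table.loc[drug, year] = k
    return table


def category_counts(
    reports: Sequence[CaseReport],
    unit: Literal["event", "report"] = "event",
) -> pd.DataFrame:
    """Drug × category counts under the chosen counting unit.

    ``report``: number of reports mentioning the category at least once (a
    multi-category report increments several cells).  ``event``: number of
    categorized term occurrences.
    """
    drugs = sorted({r.drug for r in reports})
    counts: dict[tuple[str, str], int] = {}
    for r in reports:
        if r.category_counts is None:
            raise ValueError(f"report {r.case_id!r} has no categories attached")
        for cat, k in r.category_counts.items():
            key = (r.drug, cat)
            counts[key] = counts.get(key, 0) + (1 if unit == "report" else k)
    table = pd.DataFrame(0, index=pd.Index(drugs, name="drug"), columns=list(CATEGORIES))
    for (drug, cat), k in counts.items():
        table.loc[drug, cat] = k
    return table


def outcome_table(reports: Sequence[CaseReport]) -> list[OutcomeRow]:
    """Per-drug report counts for each clinical-outcome class.

    A report with several outcome codes counts once per distinct class.
    Unknown codes are ignored here (they surface in the pipeline audit).
    """
    labels = list(OUTCOME_CLASSES.values())
    acc: dict[str, dict[str, int]] = {}
    for r in reports:
        row = acc.setdefault(r.drug, {lab: 0 for lab in labels})
        classes, _ = classify_outcomes(r.outcome_codes)
        for lab in classes:
            row[lab] += 1
    return [OutcomeRow(drug=d, counts=acc[d]) for d in sorted(acc)]


def signals_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results to the published CSV column layout."""
    rows = []
    for res in results:
        t = res.table
        rows.append({
            "drug": t.drug, "category": t.category,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d, "unit": t.counting_unit,
            "ror": res.ror.estimate, "ror_l95": res.ror.lower95, "ror_u95": res.ror.upper95,
            "prr": res.prr.estimate, "prr_l95": res.prr.lower95, "prr_u95": res.prr.upper95,
            "chi2": res.chi2, "p_value": res.p_value,
            "n_ge_3": res.count_criterion_met,
            "ror_signal": res.ror_signal, "prr_signal": res.prr_signal,
        })
    df = pd.DataFrame(rows)
    for col in ("ror", "ror_l95", "ror_u95", "prr", "prr_l95", "prr_u95", "chi2"):
        df[col] = df[col].round(4)
    return df


# ---------------------------------------------------------------------------
# pipeline


class PipelineConfig(BaseModel):
    """One full analysis run: input (file or generator), dictionaries, window,
    counting unit and output directory."""

    model_config = ConfigDict(extra="forbid")

    input_path: Optional[str] = None
    dialect: Literal["flat_csv", "faers_ascii"] = "flat_csv"
    generator: Optional[GeneratorConfig] = None
    drug_dict_path: Optional[str] = None
    term_dict_path: Optional[str] = None
    start_year: int = 2012
    end_year: int = 2022
    unit: Literal["event", "report"] = "event"
    comparator: Literal["within-class"] = "within-class"
    zero_correction: Literal["none", "haldane"] = "none"
    out_dir: str = "pvdispro_out"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator must be set")
        if self.start_year > self.end_year:
            raise ValueError("start_year exceeds end_year")
        return self


@dataclass
class PipelineResult:
    reports: List[CaseReport]
    demographics: List[DemographicsRow]
    yearly: pd.DataFrame
    categories: pd.DataFrame
    outcomes: List[OutcomeRow]
    signals: List[SignalResult]
    load_report: LoadReport
    unmatched_terms: List[str]
    out_dir: Path


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the output bundle.

    Stages: simulate-or-load → resolve drugs → window filter → deduplicate →
    categorize → disproportionality → summaries.  Writes demographics.csv,
    yearly_counts.csv, category_counts.csv, outcomes.csv,
    disproportionality.csv, signals.json, manifest.json and audit.log to
    ``out_dir``; deterministic for a fixed config (and generator seed).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    drug_dict: DrugDictionary = (
        default_drug_dictionary() if config.drug_dict_path is None
        else _load_drug_dictionary(config.drug_dict_path)
    )
    term_dict: TermDictionary = (
        default_term_dictionary() if config.term_dict_path is None
        else load_term_dictionary(config.term_dict_path)
    )

    if config.generator is not None:
        source = out_dir / ("simulated" if config.dialect == "faers_ascii" else "simulated.csv")
        simulate_to_path(config.generator, source, config.dialect)
    else:
        source = Path(config.input_path)
    raws, load_report = read_records(source, config.dialect)

    resolved, load_report = resolve_drugs(raws, drug_dict, load_report)
    windowed = filter_study_window(resolved, config.start_year, config.end_year)
    cases, load_report = deduplicate(windowed, load_report)
    cases, unmatched = attach_categories(cases, term_dict)

    demo = demographics_table(cases)
    yearly = yearly_counts(cases, (config.start_year, config.end_year))
    cats = category_counts(cases, unit=config.unit)
    outcomes = outcome_table(cases)
    drugs = sorted({r.drug for r in cases})
    signals = (
        all_signals(cases, drugs, CATEGORIES, unit=config.unit,
                    zero_correction=config.zero_correction)
        if len(drugs) >= 2 else []
    )

    _write_bundle(config, out_dir, demo, yearly, cats, outcomes, signals,
                  load_report, unmatched)
    return PipelineResult(
        reports=cases, demographics=demo, yearly=yearly, categories=cats,
        outcomes=outcomes, signals=signals, load_report=load_report,
        unmatched_terms=unmatched, out_dir=out_dir,
    )


def _load_drug_dictionary(path: str) -> DrugDictionary:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    entries = {drug: frozenset(syns or ()) for drug, syns in data.get("entries", data).items()}
    return DrugDictionary(entries=entries)


def _write_bundle(
    config: PipelineConfig,
    out_dir: Path,
    demo: List[DemographicsRow],
    yearly: pd.DataFrame,
    cats: pd.DataFrame,
    outcomes: List[OutcomeRow],
    signals: List[SignalResult],
    load_report: LoadReport,
    unmatched: List[str],
) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in demo]).to_csv(
        out_dir / "demographics.csv", index=False)
    yearly.to_csv(out_dir / "yearly_counts.csv")
    cats.to_csv(out_dir / "category_counts.csv")
    pd.DataFrame(
        [{"drug": r.drug, **r.counts} for r in outcomes]
    ).to_csv(out_dir / "outcomes.csv", index=False)
    sig_df = signals_frame(signals) if signals else pd.DataFrame()
    sig_df.to_csv(out_dir / "disproportionality.csv", index=False)
    with open(out_dir / "signals.json", "w", encoding="utf-8") as fh:
        json.dump(
            json.loads(sig_df.to_json(orient="records")) if not sig_df.empty else [],
            fh, indent=2)
    manifest = {
        "tool": "pvdispro",
        "version": __version__,
        "config_hash": _config_hash(config),
        "counting_unit": config.unit,
        "comparator": config.comparator,
        "zero_correction": config.zero_correction,
        "window": [config.start_year, config.end_year],
        "seed": None if config.generator is None else config.generator.seed,
        "n_reports": int(sum(r.n_reports for r in demo)),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out_dir / "audit.log", "w", encoding="utf-8") as fh:
        fh.write(f"rows loaded: {load_report.n_loaded}\n")
        fh.write(f"rows skipped: {load_report.n_skipped}\n")
        fh.write(f"unresolved drug: {load_report.n_unresolved_drug}\n")
        fh.write(f"multi study-drug records excluded: {load_report.n_multi_drug}\n")
        fh.write(f"duplicate versions removed: {load_report.n_duplicates_removed}\n")
        fh.write(f"uncategorized term occurrences: {len(unmatched)}\n")
        for term in sorted(set(unmatched))[:200]:
            fh.write(f"  uncategorized: {term}\n")
        for note in load_report.notes:
            fh.write(f"note: {note}\n")
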