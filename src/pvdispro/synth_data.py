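"""FAERS-like synthetic report generator with known disproportionality structure.

The generator emulates the shape of spontaneous adverse-event data — heavily
imbalanced per-drug report volumes, per-drug sex mixes and age distributions,
receipt years over a study window, per-report sets of MedDRA-style preferred
terms, FAERS outcome codes, and injected duplicate/follow-up records — while
keeping the statistical effect structure exactly known.

Effects are configured as odds multipliers: a report for drug ``g`` mentions
at least one term of category ``k`` with probability

    p' = m * p / (1 - p + m * p)

where ``p`` is the category's baseline probability and ``m`` the configured
multiplier, i.e. the multiplier acts on the *odds* ``p/(1-p)``.  Against a
comparator arm with multiplier 1 the true reporting odds ratio is therefore
exactly ``m``, which makes parameter recovery an exact oracle for the
downstream contingency-table statistics.

Default parameters are calibrated to the study conditions of a JAK-inhibitor
safety analysis: three drugs with report volumes down-sampled 100-fold from
the real per-drug totals, the published per-drug sex mixes and age moments,
receipt years 2012–2022, and outcome-code rates derived from the published
outcome counts.
"""

from __future__ import annotations

import math
import os
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from .categorize import CATEGORIES, default_term_dictionary
from .io_ingest import SEXES, CaseReport, RawRecord, write_records

__all__ = [
    "GeneratorConfig",
    "default_config",
    "adjusted_probability",
    "generate_reports",
    "inject_duplicates",
    "case_to_raw",
    "simulate_to_path",
]

AGE_MIN, AGE_MAX = 18.0, 100.0


def adjusted_probability(p: float, m: float) -> float:
    """Bernoulli probability after multiplying the odds ``p/(1-p)`` by ``m``."""
    return m * p / (1.0 - p + m * p)


class GeneratorConfig(BaseModel):
    """Full parameterization of one synthetic report set.

    ``odds_multipliers`` is a nested drug → category → multiplier map; any
    (drug, category) pair not listed defaults to 1 (no effect).  The config
    round-trips through YAML/JSON with these field names.
    """

    model_config = ConfigDict(extra="forbid")

    reports_per_drug: Dict[str, int]
    year_range: Tuple[int, int] = (2012, 2022)
    sex_probs: Dict[str, Tuple[float, float, float]]
    age_mean_sd: Dict[str, Tuple[float, float]]
    category_base_rates: Dict[str, float]
    odds_multipliers: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    terms_per_category: Dict[str, List[str]]
    outcome_probs: Dict[str, float] = Field(default_factory=dict)
    duplicate_fraction: float = 0.0
    seed: int = 0
    output_dialect: Literal["flat_csv", "faers_ascii"] = "flat_csv"

    @field_validator("reports_per_drug")
    @classmethod
    def _positive_counts(cls, v):
        for drug, n in v.items():
            if n <= 0:
                raise ValueError(f"reports_per_drug[{drug!r}] must be strictly positive, got {n}")
        return v

    @field_validator("year_range")
    @classmethod
    def _ordered_years(cls, v):
        if v[0] > v[1]:
            raise ValueError(f"year_range {v} is inverted")
        return v

    @field_validator("sex_probs")
    @classmethod
    def _sex_probs_valid(cls, v):
        for drug, probs in v.items():
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"sex_probs[{drug!r}] outside [0, 1]: {probs}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"sex_probs[{drug!r}] must sum to 1, got {sum(probs)!r}")
        return v

    @field_validator("category_base_rates")
    @classmethod
    def _rates_valid(cls, v):
        for cat, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"category_base_rates[{cat!r}] outside [0, 1]: {p}")
        return v

    @field_validator("outcome_probs")
    @classmethod
    def _outcome_probs_valid(cls, v):
        for code, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcome_probs[{code!r}] outside [0, 1]: {p}")
        return v

    @field_validator("duplicate_fraction")
    @classmethod
    def _fraction_valid(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"duplicate_fraction must lie in [0, 1), got {v}")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        for drug in self.reports_per_drug:
            if drug not in self.sex_probs:
                raise ValueError(f"sex_probs missing entry for drug {drug!r}")
            if drug not in self.age_mean_sd:
                raise ValueError(f"age_mean_sd missing entry for drug {drug!r}")
        for drug, cats in self.odds_multipliers.items():
            for cat, m in cats.items():
                if m <= 0:
                    raise ValueError(f"odds_multipliers[{drug!r}][{cat!r}] must be > 0, got {m}")
                if cat not in self.category_base_rates:
                    raise ValueError(
                        f"odds_multipliers names category {cat!r} absent from category_base_rates"
                    )
        for cat, p in self.category_base_rates.items():
            if p > 0 and not self.terms_per_category.get(cat):
                raise ValueError(f"category {cat!r} has base rate {p} but no terms to draw from")
        return self

    def multiplier(self, drug: str, category: str) -> float:
        return self.odds_multipliers.get(drug, {}).get(category, 1.0)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def default_config(scale: float = 0.01, seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults: three JAK inhibitors, volumes down-sampled.

    Report volumes are ``scale`` times the real per-drug totals (227,144 /
    9,305 / 37,208); sex mixes, age moments and outcome-code rates follow the
    published per-drug demographics and outcome counts; effect multipliers
    follow the published within-class reporting odds ratios.
    """
    dic = default_term_dictionary()
    return GeneratorConfig(
        reports_per_drug={
            "tofacitinib": max(1, round(227_144 * scale)),
            "baricitinib": max(1, round(9_305 * scale)),
            "upadacitinib": max(1, round(37_208 * scale)),
        },
        year_range=(2012, 2022),
        sex_probs={
            "tofacitinib": (0.7568, 0.1804, 0.0628),
            "baricitinib": (0.6234, 0.3095, 0.0671),
            "upadacitinib": (0.7246, 0.2219, 0.0535),
        },
        age_mean_sd={
            "tofacitinib": (57.5, 6.15),
            "baricitinib": (60.14, 2.96),
            "upadacitinib": (58.5, 1.31),
        },
        category_base_rates={
            "cardiovascular": 0.05,
            "cancer": 0.04,
            "respiratory": 0.08,
            "gastrointestinal": 0.07,
            "musculoskeletal": 0.35,
            "arthralgia": 0.10,
        },
        odds_multipliers={
            "tofacitinib": {
                "cardiovascular": 0.96, "cancer": 0.44, "respiratory": 0.68,
                "arthralgia": 0.91, "musculoskeletal": 1.53, "gastrointestinal": 0.53,
            },
            "baricitinib": {
                "cardiovascular": 1.63, "cancer": 2.17, "respiratory": 2.04,
                "arthralgia": 0.33, "musculoskeletal": 0.33, "gastrointestinal": 2.05,
            },
            "upadacitinib": {
                "cardiovascular": 0.91, "cancer": 2.24, "respiratory": 1.33,
                "arthralgia": 1.25, "musculoskeletal": 0.73, "gastrointestinal": 1.82,
            },
        },
        terms_per_category={cat: sorted(dic.category_terms[cat]) for cat in CATEGORIES},
        outcome_probs={
            "HO": 0.1206, "OT": 0.3989, "DE": 0.0419, "DS": 0.0321,
            "LT": 0.0138, "CA": 0.0012, "RI": 0.00015,
        },
        duplicate_fraction=0.05,
        seed=seed,
    )


def generate_reports(config: GeneratorConfig) -> list[CaseReport]:
    """Draw one unique :class:`CaseReport` per configured report, reproducibly.

    Ages are normal per drug, truncated to [18, 100]; years uniform over the
    window; category mention is Bernoulli on odds-adjusted probabilities; each
    mentioned category contributes one term drawn uniformly from its term
    list; outcome codes are independent Bernoulli per code.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    cats = [c for c in config.category_base_rates]
    out_codes = list(config.outcome_probs)
    out_p = np.array([config.outcome_probs[c] for c in out_codes])

    reports: list[CaseReport] = []
    case_no = 0
    for drug, n in config.reports_per_drug.items():
        sex_idx = rng.choice(3, size=n, p=np.asarray(config.sex_probs[drug]))
        mean, sd = config.age_mean_sd[drug]
        if sd > 0:
            a, b = (AGE_MIN - mean) / sd, (AGE_MAX - mean) / sd
            ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        else:
            ages = np.full(n, float(np.clip(mean, AGE_MIN, AGE_MAX)))
        ages = np.round(ages, 1)
        years = rng.integers(y0, y1 + 1, size=n)

        # category membership: odds-multiplied Bernoulli, then one uniform term
        # per mentioned category; stored sparsely (most reports hit few
        # categories)
        term_hits: dict[int, list[str]] = {}
        for cat in cats:
            p = adjusted_probability(config.category_base_rates[cat], config.multiplier(drug, cat))
            hit = np.flatnonzero(rng.random(n) < p)
            if hit.size:
                vocab = config.terms_per_category[cat]
                picks = rng.integers(len(vocab), size=hit.size)
                for i, t in zip(hit.tolist(), picks.tolist()):
                    term_hits.setdefault(i, []).append(vocab[t])

        outcome_hits: dict[int, list[str]] = {}
        if out_codes:
            hits = rng.random((n, len(out_codes))) < out_p
            for i, j in zip(*np.nonzero(hits)):
                outcome_hits.setdefault(int(i), []).append(out_codes[j])

        sexes = [SEXES[i] for i in sex_idx.tolist()]
        ids = ["C%08d" % i for i in range(case_no, case_no + n)]
        case_no += n
        append = reports.append
        empty: tuple = ()
        t_get, o_get = term_hits.get, outcome_hits.get
        for i, (cid, sex, age, yr) in enumerate(
            zip(ids, sexes, ages.tolist(), years.tolist())
        ):
            terms = t_get(i)
            outs = o_get(i)
            append(CaseReport(
                cid, 0, drug, sex, age, yr,
                tuple(terms) if terms else empty,
                tuple(outs) if outs else empty,
            ))
    return reports


def case_to_raw(report: CaseReport) -> RawRecord:
    """Lower a generated case to the raw-record form the ingest stage reads."""
    return RawRecord(
        case_id=report.case_id,
        version=report.version,
        drug_raw=report.drug,
        sex=report.sex,
        age_years=report.age_years,
        year=report.year,
        preferred_terms=report.preferred_terms,
        outcome_codes=report.outcome_codes,
    )


def inject_duplicates(
    reports: list[CaseReport], fraction: float, seed: int
) -> list[RawRecord]:
    """Re-emit a random ⌊fraction·n⌋ subset of cases as follow-up versions.

    Follow-ups keep the case identifier and drug, increment the version by 1,
    and may perturb non-key fields (here: the reported age).  The originals
    come first so keep-latest deduplication is exercised by file order too.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    raws = [case_to_raw(r) for r in reports]
    k = math.floor(fraction * len(reports))
    if k:
        chosen = rng.choice(len(reports), size=k, replace=False)
        for i in sorted(chosen.tolist()):
            orig = reports[i]
            age = orig.age_years
            if age is not None:
                age = float(np.clip(round(age + rng.normal(0.0, 0.5), 1), AGE_MIN, AGE_MAX))
            dup = case_to_raw(orig)
            dup.version = orig.version + 1
            dup.age_years = age
            raws.append(dup)
    return raws


def simulate_to_path(
    config: GeneratorConfig,
    destination: str | os.PathLike,
    dialect: Optional[str] = None,
) -> list[RawRecord]:
    """Generate reports, inject duplicates, and write them in the chosen dialect."""
    reports = generate_reports(config)
    raws = inject_duplicates(reports, config.duplicate_fraction, config.seed + 1)
    write_records(raws, destination, dialect or config.output_dialect)
    return raws
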