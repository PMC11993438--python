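"""Descriptive tables, rounding conventions, and the end-to-end pipeline."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvdispro.categorize import CATEGORIES, TermDictionary, attach_categories, default_term_dictionary
from pvdispro.io_ingest import CaseReport
from pvdispro.summaries import (
    PipelineConfig,
    category_counts,
    demographics_table,
    outcome_table,
    round_half_up,
    run_pipeline,
    yearly_counts,
)


def case(drug, sex="female", age=50.0, year=2020, terms=(), outcomes=(), cid=None):
    return CaseReport(cid or f"{drug}-{sex}-{year}-{id(object())}", 0, drug,
                      sex, age, year, tuple(terms), tuple(outcomes))


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (75.675, 75.68), (75.674, 75.67), (0.005, 0.01), (62.335, 62.34),
    ])
    def test_half_up_at_two_decimals(self, value, expected):
        assert round_half_up(value, 2) == expected


class TestDemographics:
    def test_single_report(self):
        rows = demographics_table([case("tofacitinib", age=50.0)])
        row = rows[0]
        assert row.n_reports == 1 and row.mean_age == 50.0 and row.sd_age == 0.0
        assert row.pct_female == 100.00 and row.pct_male == 0.0

    def test_percentages_from_counts(self):
        reports = (
            [case("baricitinib", sex="female", cid=f"f{i}") for i in range(697)]
            + [case("baricitinib", sex="male", cid=f"m{i}") for i in range(346)]
            + [case("baricitinib", sex="unknown", cid=f"u{i}") for i in range(75)]
        )
        row = demographics_table(reports)[0]
        assert (row.pct_female, row.pct_male, row.pct_unknown) == (62.34, 30.95, 6.71)
        assert row.n_reports == 1118

    def test_age_moments_over_known_ages_only(self):
        reports = [case("tofacitinib", age=40.0, cid="a"),
                   case("tofacitinib", age=60.0, cid="b"),
                   case("tofacitinib", age=None, cid="c")]
        row = demographics_table(reports)[0]
        assert row.mean_age == pytest.approx(50.0)
        assert row.sd_age == pytest.approx(14.1421, abs=1e-4)
        assert row.n_reports == 3

    @given(st.lists(st.sampled_from(["female", "male", "unknown"]),
                    min_size=1, max_size=60))
    def test_sex_counts_partition_and_percentages_sum(self, sexes):
        reports = [case("tofacitinib", sex=s, cid=str(i)) for i, s in enumerate(sexes)]
        row = demographics_table(reports)[0]
        assert row.n_female + row.n_male + row.n_unknown == row.n_reports
        assert row.pct_female + row.pct_male + row.pct_unknown == pytest.approx(100, abs=0.02)


class TestYearlyCounts:
    def test_counts_partition_reports(self):
        reports = [case("a", year=2020, cid=str(i)) for i in range(5)]
        table = yearly_counts(reports, (2018, 2022))
        assert table.loc["a", 2020] == 5
        assert table.values.sum() == 5
        assert set(table.columns) == set(range(2018, 2023))

    def test_grand_total_conservation(self):
        reports = [case(d, year=y, cid=f"{d}{y}{i}")
                   for d in ("a", "b") for y in (2019, 2021) for i in range(3)]
        table = yearly_counts(reports)
        assert table.values.sum() == len(reports)
        assert table.sum(axis=1).to_dict() == {"a": 6, "b": 6}


class TestCategoryCounts:
    def test_multi_category_report_increments_both(self, term_dict):
        reports, _ = attach_categories(
            [case("a", terms=("Myocardial infarction", "Nausea"), cid="x")], term_dict)
        table = category_counts(reports, unit="report")
        assert table.loc["a", "cardiovascular"] == 1
        assert table.loc["a", "gastrointestinal"] == 1

    def test_event_unit_counts_occurrences(self, term_dict):
        reports, _ = attach_categories(
            [case("a", terms=("Nausea", "Vomiting"), cid="x")], term_dict)
        assert category_counts(reports, unit="event").loc["a", "gastrointestinal"] == 2
        assert category_counts(reports, unit="report").loc["a", "gastrointestinal"] == 1

    def test_empty_dictionary_audits_everything(self):
        empty = TermDictionary(category_terms={c: frozenset() for c in CATEGORIES})
        reports, audit = attach_categories(
            [case("a", terms=("Nausea", "Arthralgia"), cid="x")], empty)
        table = category_counts(reports)
        assert table.values.sum() == 0
        assert sorted(audit) == ["Arthralgia", "Nausea"]


class TestOutcomeTable:
    def test_counts_once_per_class(self):
        reports = [case("a", outcomes=("HO", "DE", "HO"), cid="x"),
                   case("a", outcomes=("HO",), cid="y"),
                   case("a", outcomes=("HO",), cid="z"),
                   case("a", cid="w")]
        row = outcome_table(reports)[0]
        assert row.counts["hospitalization"] == 3
        assert row.counts["death"] == 1
        assert row.counts["disability"] == 0


class TestPipeline:
    def test_generator_run_writes_bundle(self, tmp_path, small_study_config):
        cfg = PipelineConfig(generator=small_study_config(seed=5, n=300),
                             out_dir=str(tmp_path / "out"))
        result = run_pipeline(cfg)
        for name in ("demographics.csv", "yearly_counts.csv", "category_counts.csv",
                     "outcomes.csv", "disproportionality.csv", "signals.json",
                     "manifest.json", "audit.log"):
            assert (tmp_path / "out" / name).exists()
        assert len(result.reports) == 900  # duplicates collapsed back
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["n_reports"] == 900 and manifest["seed"] == 5

    def test_partition_checks_hold(self, tmp_path, small_study_config):
        cfg = PipelineConfig(generator=small_study_config(seed=6, n=250),
                             out_dir=str(tmp_path / "out"))
        result = run_pipeline(cfg)
        total = len(result.reports)
        assert result.yearly.values.sum() == total
        assert sum(r.n_reports for r in result.demographics) == total

    def test_same_config_is_byte_identical(self, tmp_path, small_study_config):
        blobs = []
        for sub in ("r1", "r2"):
            cfg = PipelineConfig(generator=small_study_config(seed=7, n=200),
                                 out_dir=str(tmp_path / sub))
            run_pipeline(cfg)
            blobs.append((tmp_path / sub / "disproportionality.csv").read_bytes())
        assert blobs[0] == blobs[1]

    def test_analysis_of_written_file_round_trips(self, tmp_path, small_study_config):
        from pvdispro.synth_data import simulate_to_path
        src = tmp_path / "reports.csv"
        simulate_to_path(small_study_config(seed=8, n=200), src)
        cfg = PipelineConfig(input_path=str(src), out_dir=str(tmp_path / "out"))
        result = run_pipeline(cfg)
        assert len(result.reports) == 600
        assert {r.drug for r in result.reports} == {
            "tofacitinib", "baricitinib", "upadacitinib"}

    def test_rendered_percentages_recompute_from_rendered_counts(
            self, tmp_path, small_study_config):
        import pandas as pd
        cfg = PipelineConfig(generator=small_study_config(seed=9, n=300),
                             out_dir=str(tmp_path / "out"))
        run_pipeline(cfg)
        demo = pd.read_csv(tmp_path / "out" / "demographics.csv")
        for _, row in demo.iterrows():
            assert round_half_up(100 * row.n_female / row.n_reports) == row.pct_female
            assert round_half_up(100 * row.n_male / row.n_reports) == row.pct_male

    def test_config_requires_exactly_one_source(self, small_study_config):
        with pytest.raises(ValueError, match="exactly one"):
            PipelineConfig(out_dir="x")
        with pytest.raises(ValueError, match="exactly one"):
            PipelineConfig(input_path="a.csv", generator=small_study_config(), out_dir="x")

    def test_injected_effect_recovered_qualitatively(self, tmp_path, small_study_config):
        cfg = PipelineConfig(
            generator=small_study_config(
                seed=10, n=4000,
                multipliers={"baricitinib": {"cardiovascular": 4.0}}),
            unit="report",
            out_dir=str(tmp_path / "out"))
        result = run_pipeline(cfg)
        by_key = {(s.table.drug, s.table.category): s for s in result.signals}
        sig = by_key[("baricitinib", "cardiovascular")]
        assert sig.ror.estimate > 2.0
        assert sig.ror_signal
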