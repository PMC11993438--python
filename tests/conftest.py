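import pytest
from hypothesis import HealthCheck, settings

from pvdispro.categorize import default_term_dictionary
from pvdispro.synth_data import GeneratorConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def term_dict():
    return default_term_dictionary()


@pytest.fixture
def two_arm_config():
    """Two-drug generator config factory: one category with a known odds
    multiplier on the index arm and a null comparator arm."""

    def make(multiplier: float, n_per_arm: int, base_rate: float = 0.1, seed: int = 0):
        return GeneratorConfig(
            reports_per_drug={"tofacitinib": n_per_arm, "baricitinib": n_per_arm},
            sex_probs={
                "tofacitinib": (0.7568, 0.1804, 0.0628),
                "baricitinib": (0.6234, 0.3095, 0.0671),
            },
            age_mean_sd={"tofacitinib": (57.5, 6.15), "baricitinib": (60.14, 2.96)},
            category_base_rates={"cardiovascular": base_rate},
            odds_multipliers={"tofacitinib": {"cardiovascular": multiplier}},
            terms_per_category={
                "cardiovascular": ["myocardial infarction", "pulmonary embolism"]
            },
            seed=seed,
        )

    return make


@pytest.fixture
def small_study_config():
    """Three-drug config at small scale with the study's default structure."""

    def make(seed: int = 0, n: int = 400, multipliers: dict | None = None):
        drugs = ("tofacitinib", "baricitinib", "upadacitinib")
        return GeneratorConfig(
            reports_per_drug={d: n for d in drugs},
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
            odds_multipliers=multipliers or {},
            terms_per_category={
                cat: sorted(default_term_dictionary().category_terms[cat])
                for cat in (
                    "cardiovascular", "cancer", "respiratory",
                    "gastrointestinal", "musculoskeletal", "arthralgia",
                )
            },
            outcome_probs={"HO": 0.12, "DE": 0.04, "LT": 0.014, "OT": 0.4},
            duplicate_fraction=0.05,
            seed=seed,
        )

    return make
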