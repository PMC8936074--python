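import pytest

from aodkit import FitConfig, GeneratorConfig, simulate_cohort
from aodkit.methods import build_cohort_relations


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at study-default conditions (fixed seed)."""
    cohort, truths = simulate_cohort(GeneratorConfig(seed=42))
    return cohort, truths


@pytest.fixture(scope="session")
def default_relations(default_cohort):
    """All nine method relations per subject at 1.5 Hz."""
    cohort, _ = default_cohort
    return build_cohort_relations(cohort, FitConfig(), 1.5)


@pytest.fixture()
def fit_config():
    return FitConfig()
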