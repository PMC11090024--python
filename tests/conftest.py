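import pytest
from hypothesis import HealthCheck, settings

from isletcal.synthetic_data import CohortConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized synthetic cohort (2300 cases; 1504/456/535 controls)."""
    config = CohortConfig(seed=20240508)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-analyte, two-assay cohort for fast pipeline tests."""
    config = CohortConfig(
        n_cases=80,
        n_controls_by_group={"PBC": 40, "DOC": 20, "BDC": 20},
        analytes=("GADA", "IA-2A"),
        assays=("RBA", "ADAP_CRC"),
        seed=5,
    )
    return config, simulate_cohort(config)
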