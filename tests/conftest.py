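import dataclasses

import numpy as np
import pytest

from hdpsim import ScenarioConfig, ConfounderSpec, default_scenario, generate_cohort


def small_scenario(n=800, seed=11, **overrides) -> ScenarioConfig:
    """A scaled-down two-confounder scenario for fast unit tests."""
    cfg = ScenarioConfig(
        n_patients=n,
        true_log_hr=0.0,
        treatment_intercept=-1.2,
        confounders=[
            ConfounderSpec(
                "high_surgical_risk", 0.5, 2.0, 0.7,
                registry_dimension="high_surgical_risk",
                claims_sensitivity={"inpatient_dx": 0.2},
            ),
            ConfounderSpec(
                "heart_failure", 0.2, 0.8, 0.6,
                claims_sensitivity={"inpatient_dx": 0.9, "carrier": 0.85},
                claims_mean_count=2.0,
            ),
        ],
        n_noise_codes=5,
        missingness_rates={},
        baseline_hazard=2e-4,
        n_hospitals=20,
        n_physicians=60,
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_scenario())


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort, shared across tests (generation is cheap
    but the tables are reused many times)."""
    return generate_cohort(default_scenario())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
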