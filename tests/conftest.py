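import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diaclust import fit_sex_stratified, name_archetypes
from diaclust.synthetic import MixtureConfig, simulate_cross_section

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort():
    """One default-condition synthetic cohort with ground truth (n=3000)."""
    cohort, labels = simulate_cross_section(
        MixtureConfig(n_subjects=3000, seed=42), "study")
    return cohort, labels


@pytest.fixture(scope="session")
def study_model(study_cohort):
    """Named five-cluster model fitted on the session cohort."""
    cohort, _ = study_cohort
    model = fit_sex_stratified(cohort, k=5, n_restarts=50, seed=42)
    name_archetypes(model)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(7)
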