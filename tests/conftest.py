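import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from gilandscape.core_model import default_panel, filter_variants
from gilandscape.synthetic_cohort import (
    default_sim_params,
    generate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A quick mixed-type cohort for smoke-level checks."""
    params = default_sim_params(seed=11)
    params.n_per_type = {"CORE": 30, "GAST": 20, "PAAD": 5, "GABI": 3, "GIST": 5}
    return generate_cohort(params, panel)


@pytest.fixture(scope="session")
def full_cohort(panel):
    """The default-condition cohort (414 patients) at a fixed seed."""
    return generate_cohort(default_sim_params(seed=7), panel)


@pytest.fixture(scope="session")
def full_cohort_filtered(full_cohort):
    patients, variants, segments, msi, truth = full_cohort
    return patients, filter_variants(variants), segments, msi, truth
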