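import numpy as np
import pytest

from fviiidose.pk_model import PKModelSpec, sample_cohort_parameters, typical_parameters
from fviiidose.population import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def pk_spec():
    return PKModelSpec()


@pytest.fixture(scope="session")
def typical_params(pk_spec):
    """Population-typical subject at the reference lean body weight."""
    return typical_parameters(pk_spec, pk_spec.lbw_reference)


@pytest.fixture(scope="session")
def small_cohort(pk_spec):
    """30 patients per group with sampled PK parameters (fixed seed)."""
    patients = generate_population(PopulationSpec(n_per_group=30, rng_seed=424242))
    rng = np.random.default_rng(90210)
    params = sample_cohort_parameters(pk_spec, [p.metrics.lbw_kg for p in patients], rng)
    return patients, params
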