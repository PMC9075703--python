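import numpy as np
import pytest

from telogene import synthio
from telogene.lmm import TwoStageLMM


@pytest.fixture(scope="session")
def family_cohort():
    """Moderate family cohort with one planted causal variant."""
    spec = synthio.CohortSimSpec(
        n_families=250, family_size=4, h2=0.4,
        causal_variants=((0.3, -30.0),), n_null_variants=10, seed=11)
    cohort, block, kinship = synthio.simulate_cohort(spec)
    return spec, cohort, block, kinship


@pytest.fixture(scope="session")
def fitted_two_stage(family_cohort):
    _, cohort, block, kinship = family_cohort
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    fit1, fit2 = ts.fit()
    return ts, fit1, fit2


@pytest.fixture(scope="session")
def unrelated_cohort():
    """Unrelated samples (identity kinship), single stratum."""
    spec = synthio.CohortSimSpec(
        n_families=800, family_size=1, n_strata=1,
        stratum_residual_sd=(500.0,), h2=0.0,
        causal_variants=((0.3, -30.0),), n_null_variants=5, seed=21)
    cohort, block, kinship = synthio.simulate_cohort(spec)
    return spec, cohort, block, kinship


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
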