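import pytest

from temporalbias import (
    GeneratorParams,
    gen_claims_cohort,
    gen_repeated_measures,
    standin_laws,
)


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=101)


@pytest.fixture(scope="session")
def laws(default_params):
    """(case, control) log-normal laws with the 15% median gap."""
    return standin_laws(default_params)


@pytest.fixture(scope="session")
def repeated_cohort(default_params):
    return gen_repeated_measures(default_params)


@pytest.fixture(scope="session")
def claims_cohort():
    params = GeneratorParams(seed=202, n_cases=1500, n_controls=3000)
    return gen_claims_cohort(params)
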