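import pytest

from tilmark import synth


@pytest.fixture(scope="session")
def study_cohort():
    """Default ten-patient study-conditions cohort, fixed seed."""
    spec = synth.SyntheticCohortSpec.study_default(seed=1)
    return synth.simulate_cohort(spec)


@pytest.fixture(scope="session")
def study_spec(study_cohort):
    return study_cohort.spec
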