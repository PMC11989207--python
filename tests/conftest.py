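import pytest
from hypothesis import settings

from larcscore import pipeline, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def joint_records():
    return synthetic.paper_fixture_joint()


@pytest.fixture(scope="session")
def joint_scored(joint_records):
    return pipeline.score_cohort(joint_records)


@pytest.fixture(scope="session")
def joint_report(joint_scored):
    return pipeline.analyze(joint_scored)


@pytest.fixture(scope="session")
def big_cohort():
    """One large simulated cohort shared by the recovery checks."""
    cfg = synthetic.SimulationConfig(n=10_000, seed=20180329)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_scored(big_cohort):
    return pipeline.score_cohort(big_cohort)
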