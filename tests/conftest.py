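import numpy as np
import pytest

from brainage import SimulationConfig, generate_cohort


def mk_control(pid, age, sex="male", education=15.0, mmse=29.0):
    from brainage import ParticipantRecord

    return ParticipantRecord(
        participant_id=pid, diagnosis="control", age=float(age), sex=sex,
        education=education, mmse=mmse,
    )


def mk_patient(pid, age, duration, sex="male", education=12.0, mmse=27.0,
               **clinical):
    from brainage import ParticipantRecord

    return ParticipantRecord(
        participant_id=pid, diagnosis="patient", age=float(age), sex=sex,
        education=education, mmse=mmse, duration=float(duration), **clinical,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale synthetic cohort (330 controls, 194 patients), seed 1."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ages_of(default_cohort):
    records, _ = default_cohort
    return {r.participant_id: r.age for r in records}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
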