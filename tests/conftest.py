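import pytest
from hypothesis import settings

from capscore import PatientRecord, Sex

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def make_record():
    """Factory for a valid complete record; override any field via kwargs."""

    def factory(**overrides):
        base = dict(
            patient_id="P1",
            age=61,
            sex=Sex.male,
            confusion=False,
            urea=6.65,
            resp_rate=24,
            sbp=130.0,
            dbp=74.0,
            heart_rate=100.0,
            temperature=37.0,
            died_6wk=False,
            icu_6wk=False,
        )
        base.update(overrides)
        return PatientRecord(**base)

    return factory
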