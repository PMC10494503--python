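import pytest

from freevitd import GeneratorConfig, ParticipantRecord, generate_cohort

# overall cohort central biomarker values used in worked examples
MEDIANS = dict(
    albumin=4.3,
    d25_3=20.3,
    d25_2=0.33,
    vdbp=253.3,
    d1_25_3=40.2,
    d24_25_3=1.7,
    ipth=34.0,
)


@pytest.fixture
def median_record() -> ParticipantRecord:
    return ParticipantRecord(phenotype="Gc1f/Gc1f", **MEDIANS)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration synthetic cohort of the study's size."""
    return generate_cohort(GeneratorConfig(n=370, seed=11))
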