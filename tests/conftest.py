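import pytest
from hypothesis import settings

from depotbia import CohortConfig, UnitCostTable, generate_cohort, packaged_component_table
from depotbia.cohort import PatientRecord, PhaseUtilization

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def component_table():
    return packaged_component_table()


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig())


def make_patient(patient_id="P1", employment="employed", **phase_a_fields) -> PatientRecord:
    """A minimal patient with phase-A utilization set from keyword args."""
    return PatientRecord(
        patient_id=patient_id, age=40.0, sex="female", employment=employment,
        insurance="statutory", copay_exempt=False, age_at_diagnosis=30.0,
        phase_a=PhaseUtilization(**phase_a_fields),
        phase_b=PhaseUtilization())
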