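from datetime import date

import pytest

from comorbidikit.io import AdmissionRecord, ClaimsDataset, PatientRecord


@pytest.fixture
def tiny_dataset() -> ClaimsDataset:
    """Three admissions (one prior, two index-year) over two patients.

    Patient A: AMI index admission in March 2002 with a CHF secondary code,
    plus a prior admission in 2001 with diabetes codes; died 2002-03-15
    (in hospital). Patient B: COPD admission, alive.
    """
    admissions = [
        AdmissionRecord(
            patient_id="A", admit_date=date(2001, 11, 1),
            discharge_date=date(2001, 11, 5), principal_dx="25000",
            secondary_dx=("4280",), drg="182", discharge_alive=True),
        AdmissionRecord(
            patient_id="A", admit_date=date(2002, 3, 10),
            discharge_date=date(2002, 3, 15), principal_dx="410.71",
            secondary_dx=("4280", "5859"), procedures=("3612",),
            drg="107", discharge_alive=False),
        AdmissionRecord(
            patient_id="B", admit_date=date(2002, 6, 1),
            discharge_date=date(2002, 6, 8), principal_dx="49121",
            secondary_dx=(), drg="088", discharge_alive=True),
    ]
    patients = [
        PatientRecord(patient_id="A", birth_date=date(1940, 2, 2), sex="male",
                      aborigine=False, death_date=date(2002, 3, 15)),
        PatientRecord(patient_id="B", birth_date=date(1955, 7, 20),
                      sex="female", aborigine=True, death_date=None),
    ]
    return ClaimsDataset(admissions=admissions, patients=patients)
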