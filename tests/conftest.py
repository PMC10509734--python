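import datetime as dt

import pytest

from pcnkit.cohort import HospitalizationRecord
from pcnkit.comorbidity import load_default_chronic_map


@pytest.fixture(scope="session")
def chronic_map():
    return load_default_chronic_map()


@pytest.fixture
def make_record():
    """Factory for hand-built admissions with sensible defaults."""

    def _make(
        patient_id="P1",
        sex="male",
        age=65,
        region="urban",
        admit="2020-03-01",
        discharge=None,
        codes=("I10",),
    ):
        admit_d = dt.date.fromisoformat(admit)
        discharge_d = (
            dt.date.fromisoformat(discharge)
            if discharge
            else admit_d + dt.timedelta(days=5)
        )
        return HospitalizationRecord(
            patient_id=patient_id,
            sex=sex,
            age_at_admission=age,
            region=region,
            admit_date=admit_d,
            discharge_date=discharge_d,
            diagnoses=tuple(codes),
        )

    return _make
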