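from __future__ import annotations

from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from glaucobench.cohort import Cohort, EyeSeries, EyeVisit, PatientRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_visit(year: int, md: float, *, month: int = 6, day: int = 15,
               fp: float = 2.0, iop: float = 16.0, va: float = 1.0,
               meds: int = 1) -> EyeVisit:
    return EyeVisit(visit_date=date(year, month, day), md=md,
                    false_positive_rate=fp, iop=iop, va_raw=va,
                    medications=meds)


def make_patient(pid: str, right_mds=None, left_mds=None, *, birth_year: int = 1950,
                 onset_year: int = 2012, years=None, sex: str = "female",
                 diagnosis: str = "poag", **kwargs) -> PatientRecord:
    """Patient with one visit per listed MD, one year apart by default."""
    eyes = []
    for laterality, mds in (("right", right_mds), ("left", left_mds)):
        if mds is None:
            continue
        visit_years = years or range(onset_year, onset_year + len(mds))
        eyes.append(EyeSeries(eye=laterality, visits=[
            make_visit(y, md) for y, md in zip(visit_years, mds)]))
    return PatientRecord(patient_id=pid, sex=sex, diagnosis=diagnosis,
                         birth_date=date(birth_year, 1, 1), eyes=eyes, **kwargs)


@pytest.fixture
def two_eyed_patient() -> PatientRecord:
    return make_patient("P1", right_mds=[-2.0, -2.5, -3.0], left_mds=[-4.3, -4.8, -5.3])


@pytest.fixture
def small_cohort() -> Cohort:
    patients = [
        make_patient("P1", right_mds=[-1.0, -1.2, -1.5], left_mds=[-3.0, -3.4, -3.8],
                     years=[2012, 2014, 2017]),
        make_patient("P2", right_mds=[-7.5, -9.0, -10.5], left_mds=[-6.5, -7.0, -7.5],
                     years=[2012, 2015, 2017], sex="male", diagnosis="pex"),
        make_patient("P3", right_mds=[-20.0, -21.0], years=[2012, 2017],
                     diagnosis="ntg"),
    ]
    return Cohort(patients=patients, onset_year=2012)
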