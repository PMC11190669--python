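import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from lnscore.cohort import Cohort, PatientRecord, SubsetPanel, VisitRecord
from lnscore.renal import invert_egfr_ckd_epi
from lnscore.simulate import SimConfig, generate

BASE_DATE = dt.date(2015, 1, 1)


def make_visit(days: int = 0, **kw) -> VisitRecord:
    return VisitRecord(date=BASE_DATE + dt.timedelta(days=days), **kw)


def make_panel(**kw) -> SubsetPanel:
    return SubsetPanel(**kw)


def make_adult_with_egfr(egfr_by_year, patient_id="A1", sex="male", age0=30.0):
    """Adult patient whose creatinine encodes an exact eGFR trajectory.

    ``egfr_by_year``: list of (years_from_start, egfr) pairs; creatinine is
    the exact CKD-EPI inverse, so the pipeline recovers the targets.
    """
    birth = BASE_DATE - dt.timedelta(days=round(age0 * 365.25))
    visits = []
    for years, egfr in egfr_by_year:
        days = round(years * 365.25)
        date = BASE_DATE + dt.timedelta(days=days)
        age = (date - birth).days / 365.25
        visits.append(
            VisitRecord(date=date, scr_mg_dl=invert_egfr_ckd_epi(egfr, age, sex))
        )
    return PatientRecord(patient_id, sex, birth, visits)


@pytest.fixture(scope="session")
def default_cohort():
    """One 55-patient synthetic cohort at the default study conditions."""
    cohort, truth = generate(SimConfig(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=42)


def tiny_cohort() -> Cohort:
    p1 = PatientRecord(
        "P1",
        "female",
        dt.date(2000, 5, 10),
        [
            make_visit(0, height_cm=140.0, scr_mg_dl=0.7, sledai=4,
                       subsets=SubsetPanel(pct_nk=10.0, pct_cd4_naive=15.0,
                                           pct_cd4_memory=18.0, pct_cd4_total=34.0)),
            make_visit(400, height_cm=145.0, scr_mg_dl=0.8, sledai=6,
                       urine_rbc_hpf=2.0, urine_wbc_hpf=1.0, cellular_casts=0.0,
                       subsets=SubsetPanel(pct_nk=20.0, pct_cd4_naive=12.0,
                                           pct_cd4_memory=20.0, pct_cd4_total=33.0)),
        ],
    )
    p2 = PatientRecord(
        "P2",
        "male",
        dt.date(1990, 1, 1),
        [
            make_visit(10, scr_mg_dl=0.9, upcr=0.5),
            make_visit(500, scr_mg_dl=1.1, upcr=1.2, therapy_event="rituximab"),
        ],
    )
    return Cohort([p1, p2], provenance="hand-built")
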