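"""Small builders for hand-crafted patients, visits and index pairs."""

from __future__ import annotations

from typing import Optional

from sleresponse import (
    BILAGAssessment,
    IndexPair,
    ORGAN_DOMAINS,
    Patient,
    Visit,
)

ALL_C = {d: "C" for d in ORGAN_DOMAINS}


def assessment(**grades) -> BILAGAssessment:
    """All domains C unless overridden, e.g. ``assessment(renal="A")``."""
    g = dict(ALL_C)
    g.update(grades)
    return BILAGAssessment.from_mapping(g)


def visit(
    pid: str = "p1",
    months: float = 0.0,
    bilag: Optional[dict] = {},
    sledai: Optional[int] = 4,
    dose: Optional[float] = 5.0,
    **kw,
) -> Visit:
    """A visit with an all-C assessment by default; ``bilag=None`` for a
    visit without an assessment, or a dict of domain overrides."""
    return Visit(
        patient_id=pid,
        months_from_enrolment=months,
        bilag=None if bilag is None else assessment(**bilag),
        sledai_2k=sledai,
        oral_steroid_dose=dose,
        **kw,
    )


def patient(pid: str = "p1", visits=(), **kw) -> Patient:
    defaults = dict(
        sex="female",
        age_at_diagnosis=35.0,
        disease_duration_at_enrolment=0.5,
        ethnicity="Caucasian",
        location="Canada",
        post_secondary_education=True,
    )
    defaults.update(kw)
    return Patient(patient_id=pid, visits=list(visits), **defaults)


def pair(
    index_visit: Optional[Visit] = None,
    followup_visit: Optional[Visit] = ...,
    tag: str = "inception",
    pid: str = "p1",
) -> IndexPair:
    """An index pair over a throwaway patient; ``followup_visit=None``
    means no 12-month visit."""
    idx = index_visit if index_visit is not None else visit(pid)
    if followup_visit is ...:
        followup_visit = visit(pid, months=idx.months_from_enrolment + 12.0)
    visits = [idx] + ([followup_visit] if followup_visit is not None else [])
    return IndexPair(
        patient=patient(pid, visits=visits),
        index_visit=idx,
        followup_visit=followup_visit,
        cohort_tag=tag,
    )
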