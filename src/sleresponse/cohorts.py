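"""Landmark cohort construction and outcome labelling.

Two analysis cohorts are drawn from a longitudinal registry cohort:

* **inception** — one index pair per patient whose enrolment visit has a
  complete BILAG assessment; patients without a baseline BILAG are
  excluded (with reasons reported, not silently dropped).
* **active_disease** — a landmark cohort: for each patient, the *first*
  visit meeting the active-disease criterion (>= 1 BILAG A or >= 2 B)
  becomes the index; patients never meeting it are excluded.

Each index visit is paired with its nearest-to-12-months follow-up
inside a configurable window (default 9-15 months; ties resolved to the
earlier visit).  Only elapsed times matter: shifting a patient's entire
visit history leaves cohorts and labels unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .data_model import Cohort, Patient, ValidationError, Visit
from .outcomes import (
    OutcomeLabel,
    classify_improvement,
    classify_mcr,
    is_active,
)

__all__ = [
    "DEFAULT_WINDOW",
    "IndexPair",
    "LabelledCohort",
    "find_followup",
    "build_inception_cohort",
    "build_active_cohort",
    "label_outcomes",
]

DEFAULT_WINDOW = (9.0, 15.0)  # months after index; must bracket 12


def _check_window(window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = window
    if not lo < 12 < hi:
        raise ValidationError(f"follow-up window {window} must bracket 12 months")
    return lo, hi


@dataclass(frozen=True)
class IndexPair:
    """An index visit plus its matched ~12-month follow-up (or absent)."""

    patient: Patient
    index_visit: Visit
    followup_visit: Optional[Visit]
    cohort_tag: str  # "inception" | "active_disease"

    def __post_init__(self):
        if self.cohort_tag not in ("inception", "active_disease"):
            raise ValidationError(f"bad cohort_tag {self.cohort_tag!r}")
        if self.index_visit.bilag is None:
            raise ValidationError(
                f"{self.patient.patient_id}: index visit lacks complete BILAG"
            )
        if self.cohort_tag == "active_disease" and not is_active(
            self.index_visit.bilag
        ):
            raise ValidationError(
                f"{self.patient.patient_id}: active_disease index visit not active"
            )


@dataclass
class LabelledCohort:
    """Index pairs with one outcome label per pair."""

    pairs: list[IndexPair]
    labels: list[OutcomeLabel]
    outcome_name: str  # "mcr" | "improvement"

    def __post_init__(self):
        if len(self.pairs) != len(self.labels):
            raise ValidationError("labels must align one-to-one with pairs")

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(label.value for label in self.labels)
        return {
            "achieved": c.get("achieved", 0),
            "not_achieved": c.get("not_achieved", 0),
            "unclassifiable": c.get("unclassifiable", 0),
        }


def find_followup(
    patient: Patient,
    index_visit: Visit,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> Optional[Visit]:
    """The patient's visit nearest to 12 months after the index visit.

    Considers visits whose elapsed time from the index lies in
    ``[window[0], window[1]]``; ties in distance to 12 months resolve to
    the earlier visit.  Returns ``None`` when no visit qualifies.
    """
    lo, hi = _check_window(window)
    t0 = index_visit.months_from_enrolment
    best: Optional[Visit] = None
    best_dist = float("inf")
    for v in patient.visits:
        elapsed = v.months_from_enrolment - t0
        if lo <= elapsed <= hi:
            dist = abs(elapsed - 12.0)
            if dist < best_dist:  # strict: first (earlier) visit wins ties
                best, best_dist = v, dist
    return best


def build_inception_cohort(
    cohort: Cohort, window: tuple[float, float] = DEFAULT_WINDOW
) -> list[IndexPair]:
    """One pair per patient whose enrolment visit has a complete BILAG."""
    _check_window(window)
    pairs = []
    for patient in cohort:
        if not patient.visits:
            continue
        enrolment = patient.visits[0]
        if enrolment.bilag is None:
            continue
        pairs.append(
            IndexPair(
                patient=patient,
                index_visit=enrolment,
                followup_visit=find_followup(patient, enrolment, window),
                cohort_tag="inception",
            )
        )
    return pairs


def build_active_cohort(
    cohort: Cohort, window: tuple[float, float] = DEFAULT_WINDOW
) -> list[IndexPair]:
    """Landmark cohort at the first visit meeting the active criterion."""
    _check_window(window)
    pairs = []
    for patient in cohort:
        for visit in patient.visits:
            if visit.bilag is not None and is_active(visit.bilag):
                pairs.append(
                    IndexPair(
                        patient=patient,
                        index_visit=visit,
                        followup_visit=find_followup(patient, visit, window),
                        cohort_tag="active_disease",
                    )
                )
                break  # at most one landmark per patient
    return pairs


def label_outcomes(pairs: list[IndexPair], outcome_name: str) -> LabelledCohort:
    """Apply one outcome definition to every pair.

    Improvement is only defined on the active-disease cohort (many
    inception patients lack sufficiently active baseline disease), so
    requesting it for inception pairs is a contract error.
    """
    if outcome_name not in ("mcr", "improvement"):
        raise ValidationError(f"unknown outcome {outcome_name!r}")
    if outcome_name == "improvement":
        bad = [p.patient.patient_id for p in pairs if p.cohort_tag != "active_disease"]
        if bad:
            raise ValidationError(
                f"improvement is only assessed on the active_disease cohort; "
                f"offending patients: {bad[:5]}"
            )
        labels = [classify_improvement(p) for p in pairs]
    else:
        labels = [classify_mcr(p) for p in pairs]
    return LabelledCohort(pairs=list(pairs), labels=labels, outcome_name=outcome_name)
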