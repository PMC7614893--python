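"""BILAG-based 12-month response outcomes.

Two responder definitions are implemented, both assessed at roughly 12
months after an index visit:

* **Major Clinical Response (MCR)** — every organ domain has fallen to
  BILAG C/D/E, daily oral prednisolone-equivalent dose is <= 7.5 mg, and
  SLEDAI-2K is <= 4.
* **Improvement** — at most one BILAG B remaining, and only in a domain
  that was already active (A/B) at index; no newly active domain; a
  banded steroid-reduction rule; and no SLEDAI-2K increase.

A pair whose follow-up visit (or any required follow-up field) is missing
is *unclassifiable* — a data state, never a disease state.  Pulse
steroids play no role in either definition (they name only the daily
oral dose).
"""

from __future__ import annotations

import enum
from typing import NamedTuple, TYPE_CHECKING

from .data_model import BILAGAssessment, Grade, ORGAN_DOMAINS, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cohorts import IndexPair

__all__ = [
    "OutcomeLabel",
    "ActivityCount",
    "InactiveIndexError",
    "MissingIndexDataError",
    "count_ab",
    "is_active",
    "classify_mcr",
    "steroid_improvement_rule",
    "classify_improvement",
]

MCR_DOSE_LIMIT = 7.5  # mg/day prednisolone equivalent
MCR_SLEDAI_LIMIT = 4


class OutcomeLabel(str, enum.Enum):
    achieved = "achieved"
    not_achieved = "not_achieved"
    unclassifiable = "unclassifiable"


class ActivityCount(NamedTuple):
    """Number of domains graded A and graded B in one assessment."""

    n_a: int
    n_b: int

    @property
    def total(self) -> int:
        return self.n_a + self.n_b


class InactiveIndexError(ValidationError):
    """Improvement was asked of a pair whose index visit is not active.

    Signals a cohort-construction bug: the active-disease entry criterion
    must be enforced before classification.
    """


class MissingIndexDataError(ValidationError):
    """The index visit lacks a field the classifier's precondition requires."""


def count_ab(assessment: BILAGAssessment) -> ActivityCount:
    """Count domains graded A and domains graded B."""
    grades = assessment.grades()
    return ActivityCount(
        n_a=sum(g is Grade.A for g in grades),
        n_b=sum(g is Grade.B for g in grades),
    )


def is_active(assessment: BILAGAssessment) -> bool:
    """Active-disease entry criterion: at least one A or two B grades."""
    c = count_ab(assessment)
    return c.n_a >= 1 or c.n_b >= 2


def classify_mcr(pair: "IndexPair") -> OutcomeLabel:
    """Classify one index/follow-up pair against the MCR definition.

    Unclassifiable when the follow-up visit, its BILAG, its SLEDAI-2K or
    its dose is absent.  Achieved iff the follow-up has zero A/B domains,
    dose <= 7.5 mg/day and SLEDAI-2K <= 4 (boundaries inclusive).
    """
    if pair.index_visit.bilag is None:
        raise MissingIndexDataError(
            f"{pair.index_visit.patient_id}: index visit lacks BILAG"
        )
    fu = pair.followup_visit
    if (
        fu is None
        or fu.bilag is None
        or fu.sledai_2k is None
        or fu.oral_steroid_dose is None
    ):
        return OutcomeLabel.unclassifiable
    achieved = (
        count_ab(fu.bilag).total == 0
        and fu.oral_steroid_dose <= MCR_DOSE_LIMIT
        and fu.sledai_2k <= MCR_SLEDAI_LIMIT
    )
    return OutcomeLabel.achieved if achieved else OutcomeLabel.not_achieved


def steroid_improvement_rule(baseline_dose: float, followup_dose: float) -> bool:
    """Banded reduced-or-stable oral steroid rule of the Improvement outcome.

    Bands are half-open, resolving the printed overlap at 20 mg in favour
    of the stricter requirement:

    * baseline >= 20 mg/day      -> follow-up <= 15 mg/day
    * baseline in [10, 20) mg/day -> follow-up <= 10 mg/day
    * baseline < 10 mg/day        -> no increase over baseline
    """
    if baseline_dose < 0 or followup_dose < 0:
        raise ValidationError("steroid doses must be non-negative")
    if baseline_dose >= 20:
        return followup_dose <= 15
    if baseline_dose >= 10:
        return followup_dose <= 10
    return followup_dose <= baseline_dose


def classify_improvement(pair: "IndexPair") -> OutcomeLabel:
    """Classify one index/follow-up pair against the Improvement definition.

    Requires an active index visit (raises :class:`InactiveIndexError`
    otherwise) with SLEDAI-2K and dose recorded.  Unclassifiable when the
    follow-up visit or any required follow-up field (BILAG, SLEDAI-2K,
    dose) is absent.  Achieved iff all of:

    1. no domain graded A at follow-up;
    2. at most one domain graded B at follow-up, and any such B lies in a
       domain that was A or B at index (a B in a previously quiet domain
       is a *new* active domain and fails);
    3. every domain C/D/E at index remains C/D/E at follow-up (implied by
       1-2 but asserted explicitly);
    4. the banded steroid rule holds;
    5. follow-up SLEDAI-2K does not exceed index SLEDAI-2K.
    """
    idx = pair.index_visit
    if idx.bilag is None:
        raise MissingIndexDataError(f"{idx.patient_id}: index visit lacks BILAG")
    if not is_active(idx.bilag):
        raise InactiveIndexError(
            f"{idx.patient_id}: improvement requested for inactive index visit"
        )
    fu = pair.followup_visit
    if (
        fu is None
        or fu.bilag is None
        or fu.sledai_2k is None
        or fu.oral_steroid_dose is None
        or idx.sledai_2k is None
        or idx.oral_steroid_dose is None
    ):
        return OutcomeLabel.unclassifiable

    fu_count = count_ab(fu.bilag)
    previously_active = set(idx.bilag.active_domains())
    conditions = (
        fu_count.n_a == 0,
        fu_count.n_b <= 1
        and all(d in previously_active for d in fu.bilag.active_domains()),
        all(
            fu.bilag.grade(d).is_active is False
            for d in ORGAN_DOMAINS
            if not idx.bilag.grade(d).is_active
        ),
        steroid_improvement_rule(idx.oral_steroid_dose, fu.oral_steroid_dose),
        fu.sledai_2k <= idx.sledai_2k,
    )
    return OutcomeLabel.achieved if all(conditions) else OutcomeLabel.not_achieved
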