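"""Outcome classifiers: activity counting, MCR, Improvement, steroid bands."""

import pytest
from hypothesis import given, settings, strategies as st

import sleresponse as sr
from sleresponse.data_model import ORGAN_DOMAINS, ValidationError
from sleresponse.outcomes import InactiveIndexError, MissingIndexDataError

from helpers import assessment, pair, visit


@pytest.mark.parametrize(
    "grades, expected",
    [
        ({}, (0, 0)),  # all C
        ({"renal": "A", "haematological": "B"}, (1, 1)),
        ({d: "A" for d in ORGAN_DOMAINS}, (8, 0)),
        ({"renal": "D", "vasculitis": "E"}, (0, 0)),
    ],
)
def test_count_ab(grades, expected):
    assert sr.count_ab(assessment(**grades)) == expected


@pytest.mark.parametrize(
    "grades, active",
    [
        ({"renal": "A"}, True),  # one A suffices
        ({"renal": "B", "haematological": "B"}, True),  # two Bs suffice
        ({"renal": "B"}, False),  # a single B is below threshold
        ({}, False),
    ],
)
def test_active_disease_criterion(grades, active):
    assert sr.is_active(assessment(**grades)) is active


class TestMCR:
    def test_boundary_values_achieve(self):
        """All-C domains with dose exactly 7.5 and SLEDAI exactly 4 qualify."""
        p = pair(
            visit(bilag={"renal": "A"}),
            visit(months=12.0, sledai=4, dose=7.5),
        )
        assert sr.classify_mcr(p) is sr.OutcomeLabel.achieved

    def test_single_residual_b_fails(self):
        p = pair(
            visit(bilag={"renal": "A"}),
            visit(months=12.0, bilag={"renal": "B"}, sledai=0, dose=0.0),
        )
        assert sr.classify_mcr(p) is sr.OutcomeLabel.not_achieved

    @pytest.mark.parametrize("kw", [dict(dose=7.6), dict(sledai=5)])
    def test_just_over_dose_or_sledai_fails(self, kw):
        args = dict(months=12.0, sledai=4, dose=7.5)
        args.update(kw)
        assert sr.classify_mcr(pair(visit(), visit(**args))) is (
            sr.OutcomeLabel.not_achieved
        )

    def test_missing_followup_or_fields_unclassifiable(self):
        assert sr.classify_mcr(pair(followup_visit=None)) is (
            sr.OutcomeLabel.unclassifiable
        )
        for kw in (dict(bilag=None), dict(sledai=None), dict(dose=None)):
            args = dict(months=12.0, sledai=4, dose=5.0)
            args.update(kw)
            p = pair(visit(), visit(**args))
            assert sr.classify_mcr(p) is sr.OutcomeLabel.unclassifiable

    def test_index_without_bilag_is_precondition_error(self):
        p = pair(tag="inception")
        object.__setattr__(p.index_visit, "bilag", None)
        with pytest.raises(MissingIndexDataError):
            sr.classify_mcr(p)

    def test_achieved_implies_followup_inactive(self):
        """A/B-free follow-up is never active: MCR implies inactivity."""
        for grades in ({}, {"renal": "C"}, {"renal": "D", "vasculitis": "E"}):
            fu = visit(months=12.0, bilag=grades, sledai=0, dose=0.0)
            p = pair(visit(bilag={"renal": "A"}), fu)
            if sr.classify_mcr(p) is sr.OutcomeLabel.achieved:
                assert not sr.is_active(fu.bilag)


@pytest.mark.parametrize(
    "baseline, followup, ok",
    [
        (20.0, 15.0, True),   # high band: reduce to <= 15
        (20.0, 15.1, False),
        (15.0, 10.0, True),   # middle band: reduce to <= 10
        (15.0, 10.5, False),
        (5.0, 5.0, True),     # low band: no increase
        (5.0, 6.0, False),
        (0.0, 0.0, True),
    ],
)
def test_steroid_improvement_rule(baseline, followup, ok):
    assert sr.steroid_improvement_rule(baseline, followup) is ok


def test_steroid_rule_rejects_negative_dose():
    with pytest.raises(ValidationError):
        sr.steroid_improvement_rule(-1.0, 5.0)


class TestImprovement:
    def _index(self):
        return visit(bilag={"renal": "A", "haematological": "B"}, sledai=8, dose=20.0)

    def test_single_b_in_previously_active_domain_achieves(self):
        fu = visit(months=12.0, bilag={"renal": "B"}, sledai=4, dose=10.0)
        assert sr.classify_improvement(pair(self._index(), fu, tag="active_disease")) is (
            sr.OutcomeLabel.achieved
        )

    def test_new_active_domain_fails(self):
        fu = visit(months=12.0, bilag={"mucocutaneous": "B"}, sledai=4, dose=10.0)
        assert sr.classify_improvement(pair(self._index(), fu, tag="active_disease")) is (
            sr.OutcomeLabel.not_achieved
        )

    def test_sledai_increase_fails(self):
        fu = visit(months=12.0, bilag={"renal": "B"}, sledai=9, dose=10.0)
        assert sr.classify_improvement(pair(self._index(), fu, tag="active_disease")) is (
            sr.OutcomeLabel.not_achieved
        )

    def test_residual_a_fails_even_in_previously_active_domain(self):
        fu = visit(months=12.0, bilag={"renal": "A"}, sledai=4, dose=10.0)
        assert sr.classify_improvement(pair(self._index(), fu, tag="active_disease")) is (
            sr.OutcomeLabel.not_achieved
        )

    def test_two_bs_fail(self):
        fu = visit(months=12.0, bilag={"renal": "B", "haematological": "B"},
                   sledai=4, dose=10.0)
        assert sr.classify_improvement(pair(self._index(), fu, tag="active_disease")) is (
            sr.OutcomeLabel.not_achieved
        )

    def test_missing_fields_unclassifiable(self):
        for kw in (dict(bilag=None), dict(sledai=None), dict(dose=None)):
            args = dict(months=12.0, sledai=4, dose=10.0)
            args.update(kw)
            p = pair(self._index(), visit(**args), tag="active_disease")
            assert sr.classify_improvement(p) is sr.OutcomeLabel.unclassifiable

    def test_missing_index_dose_unclassifiable(self):
        idx = visit(bilag={"renal": "A"}, sledai=8, dose=None)
        p = pair(idx, visit(months=12.0, sledai=4, dose=5.0), tag="active_disease")
        assert sr.classify_improvement(p) is sr.OutcomeLabel.unclassifiable

    def test_inactive_index_is_contract_error(self):
        p = pair(visit(bilag={"renal": "B"}), visit(months=12.0))
        with pytest.raises(InactiveIndexError):
            sr.classify_improvement(p)


def test_outcomes_do_not_imply_each_other():
    """Witness pairs achieving one outcome but not the other, both ways."""
    # MCR without Improvement: dose increased within the low band
    idx = visit(bilag={"renal": "A"}, sledai=8, dose=2.0)
    fu = visit(months=12.0, sledai=4, dose=7.0)
    p = pair(idx, fu, tag="active_disease")
    assert sr.classify_mcr(p) is sr.OutcomeLabel.achieved
    assert sr.classify_improvement(p) is sr.OutcomeLabel.not_achieved
    # Improvement without MCR: one residual B, dose above 7.5
    idx2 = visit(bilag={"renal": "A", "haematological": "B"}, sledai=8, dose=20.0)
    fu2 = visit(months=12.0, bilag={"renal": "B"}, sledai=4, dose=10.0)
    p2 = pair(idx2, fu2, tag="active_disease")
    assert sr.classify_improvement(p2) is sr.OutcomeLabel.achieved
    assert sr.classify_mcr(p2) is sr.OutcomeLabel.not_achieved


_grades = st.sampled_from(["A", "B", "C", "D", "E"])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    idx_grades=st.lists(_grades, min_size=8, max_size=8),
    fu_grades=st.lists(_grades, min_size=8, max_size=8),
    perm=st.permutations(range(8)),
    idx_sledai=st.integers(0, 12),
    fu_sledai=st.integers(0, 12),
    idx_dose=st.sampled_from([0.0, 5.0, 10.0, 20.0, 30.0]),
    fu_dose=st.sampled_from([0.0, 7.5, 10.0, 15.0, 16.0]),
)
def test_labels_invariant_under_domain_permutation(
    idx_grades, fu_grades, perm, idx_sledai, fu_sledai, idx_dose, fu_dose
):
    """Relabelling which organ domain carries which grade pair never
    changes either outcome (classifiers are symmetric in domains)."""

    def build(ig, fg):
        idx = visit(bilag=dict(zip(ORGAN_DOMAINS, ig)), sledai=idx_sledai, dose=idx_dose)
        fu = visit(months=12.0, bilag=dict(zip(ORGAN_DOMAINS, fg)),
                   sledai=fu_sledai, dose=fu_dose)
        tag = "active_disease" if sr.is_active(idx.bilag) else "inception"
        return pair(idx, fu, tag=tag)

    p1 = build(idx_grades, fu_grades)
    p2 = build([idx_grades[i] for i in perm], [fu_grades[i] for i in perm])
    assert sr.classify_mcr(p1) is sr.classify_mcr(p2)
    if p1.cohort_tag == "active_disease":
        assert sr.classify_improvement(p1) is sr.classify_improvement(p2)
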