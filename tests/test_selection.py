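"""Repeated-CV stability selection, AUC, odds ratios, random-forest check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sleresponse as sr
from sleresponse.data_model import ValidationError
from sleresponse.selection import SelectionResult, StabilityConfig


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestComputeAUC:
    def test_worked_example(self):
        assert sr.compute_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert sr.compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert sr.compute_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            sr.compute_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 5), min_size=4, max_size=60),
        data=st.data(),
    )
    def test_matches_brute_force_concordance(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert sr.compute_auc(scores, labels) == brute_force_auc(scores, labels)


def _dummy_result(freqs: dict) -> SelectionResult:
    s = pd.Series(freqs, name="frequency")
    cfg = StabilityConfig(n_repeats=10, n_folds=10)
    return SelectionResult(
        frequencies=s,
        selection_counts=(s * 100).astype(int),
        averaged_oof_probs=np.zeros(1),
        auc=0.5,
        chosen=[],
        per_model_log=pd.DataFrame(),
        config=cfg,
    )


class TestChoosePredictors:
    def test_strict_inequality_at_boundary(self):
        result = _dummy_result({"a": 0.9, "b": 0.5, "c": 0.51})
        assert sr.choose_predictors(result, 0.5) == ["a", "c"]

    def test_all_below_threshold(self):
        assert sr.choose_predictors(_dummy_result({"a": 0.2, "b": 0.4}), 0.5) == []

    def test_sorted_by_descending_frequency(self):
        result = _dummy_result({"a": 0.6, "b": 0.9, "c": 0.6})
        assert sr.choose_predictors(result, 0.5) == ["b", "a", "c"]


class TestUnivariateOR:
    @staticmethod
    def _from_counts(a, b, c, d):
        # exposed cases a, exposed controls b, unexposed cases c, unexposed d
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        return x, y

    def test_cross_product_example(self):
        x, y = self._from_counts(20, 80, 10, 90)
        res = sr.univariate_or(x, y)
        assert res.odds_ratio == pytest.approx(2.25, rel=1e-6)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 90)
        assert res.ci_low == pytest.approx(2.25 * np.exp(-1.96 * se), rel=1e-5)
        assert res.ci_high == pytest.approx(2.25 * np.exp(1.96 * se), rel=1e-5)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_exact_independence_gives_unit_or(self):
        x, y = self._from_counts(30, 60, 20, 40)  # 30/60 == 20/40
        assert sr.univariate_or(x, y).odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_separation_is_flagged_not_raised(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()
        res = sr.univariate_or(x, y)
        assert res.separated
        assert res.ci_high == np.inf and res.ci_low == 0.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            sr.univariate_or(np.ones(10), np.r_[np.ones(5), np.zeros(5)])

    def test_continuous_slope_recovery(self):
        """OR per unit of a continuous predictor generated with slope ln 2."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(5000)
        y = (rng.random(5000) < 1 / (1 + np.exp(-(np.log(2) * x - 1)))).astype(int)
        assert 1.8 <= sr.univariate_or(x, y).odds_ratio <= 2.2


class TestRepeatedCV:
    def test_overwhelming_predictor_has_unit_frequency(self):
        """With a planted log-OR of 5, all R*K = 4 models must select it."""
        d = sr.sample_planted_design(400, [5.0, 0.0, 0.0], prevalence=0.4, seed=3)
        cfg = StabilityConfig(n_repeats=2, n_folds=2, inner_folds=3, seed=5)
        res = sr.repeated_cv(d.X, d.y, cfg)
        assert res.frequencies["x0"] == 1.0
        assert len(res.per_model_log) == 4
        assert all("x0" in s.split(";") for s in res.per_model_log["selected"])

    def test_log_reconstructs_frequencies_exactly(self):
        d = sr.sample_planted_design(200, [1.0, 0.0, 0.0, 0.0], prevalence=0.4, seed=2)
        cfg = StabilityConfig(n_repeats=3, n_folds=3, inner_folds=3, seed=8)
        res = sr.repeated_cv(d.X, d.y, cfg)
        counts = {name: 0 for name in d.X.columns}
        for sel in res.per_model_log["selected"]:
            for name in filter(None, sel.split(";")):
                counts[name] += 1
        for name in d.X.columns:
            assert res.selection_counts[name] == counts[name]
            assert res.frequencies[name] == counts[name] / cfg.n_models
        assert len(res.per_model_log) == cfg.n_models

    def test_seeded_determinism(self):
        d = sr.sample_planted_design(200, [1.0, 0.0], prevalence=0.4, seed=1)
        cfg = StabilityConfig(n_repeats=2, n_folds=3, inner_folds=3, seed=4)
        r1 = sr.repeated_cv(d.X, d.y, cfg)
        r2 = sr.repeated_cv(d.X, d.y, cfg)
        assert r1.frequencies.equals(r2.frequencies)
        assert np.array_equal(r1.averaged_oof_probs, r2.averaged_oof_probs)
        assert r1.per_model_log.equals(r2.per_model_log)
        assert r1.auc == r2.auc

    def test_elastic_net_penalty_runs_and_logs_tuned_alpha(self):
        d = sr.sample_planted_design(200, [2.0, 0.0, 0.0], prevalence=0.4, seed=12)
        cfg = StabilityConfig(
            n_repeats=1, n_folds=2, inner_folds=3, penalty="elastic_net",
            alpha_grid=(0.5, 1.0), seed=3,
        )
        res = sr.repeated_cv(d.X, d.y, cfg)
        assert set(res.per_model_log["alpha"]) <= {0.5, 1.0}
        assert res.frequencies["x0"] == 1.0

    def test_oof_probs_lie_in_unit_interval(self):
        d = sr.sample_planted_design(150, [0.8, 0.0], prevalence=0.3, seed=6)
        res = sr.repeated_cv(
            d.X, d.y, StabilityConfig(n_repeats=2, n_folds=3, inner_folds=3, seed=6)
        )
        assert np.all((res.averaged_oof_probs >= 0) & (res.averaged_oof_probs <= 1))


class TestRFCheck:
    def test_xor_interaction_found_by_forest_not_by_odds_ratios(self):
        """A pure two-way interaction: the forest discriminates, while each
        predictor's univariate OR stays near 1."""
        rng = np.random.default_rng(9)
        n = 1200
        X = pd.DataFrame(
            {"a": rng.integers(0, 2, n).astype(float),
             "b": rng.integers(0, 2, n).astype(float)}
        )
        y = np.logical_xor(X["a"], X["b"]).astype(int)
        rf = sr.rf_check(X, y, n_folds=5, seed=2, n_trees=200)
        assert rf.oof_auc >= 0.9
        for col in ("a", "b"):
            assert 0.7 <= sr.univariate_or(X[col], y).odds_ratio <= 1.4

    def test_linear_signal_gives_similar_auc_to_lasso(self):
        """On a purely linear planted signal the forest's out-of-fold AUC
        tracks the penalized-logistic AUC closely."""
        d = sr.sample_planted_design(
            2000, [np.log(3), -np.log(3), 0.0], prevalence=0.3, seed=11
        )
        res = sr.repeated_cv(
            d.X, d.y, StabilityConfig(n_repeats=2, n_folds=5, inner_folds=4, seed=1)
        )
        rf = sr.rf_check(d.X[["x0", "x1"]], d.y, n_folds=5, seed=1, n_trees=300)
        assert abs(rf.oof_auc - res.auc) <= 0.05

    def test_seeded_importances_identical(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        y = (rng.random(300) < 0.5).astype(int)
        r1 = sr.rf_check(X, y, n_folds=4, seed=5, n_trees=100)
        r2 = sr.rf_check(X, y, n_folds=4, seed=5, n_trees=100)
        assert r1.importance == r2.importance and r1.oof_auc == r2.oof_auc

    def test_empty_chosen_set_rejected(self):
        with pytest.raises(ValidationError):
            sr.rf_check(pd.DataFrame(index=range(4)), [0, 1, 0, 1])


def test_stability_selector_sklearn_interface():
    """The estimator follows fit/transform conventions and clones cleanly."""
    from sklearn.base import clone

    d = sr.sample_planted_design(200, [3.0, 0.0, 0.0], prevalence=0.4, seed=13)
    sel = sr.StabilitySelector(
        n_repeats=2, n_folds=2, inner_folds=3, random_state=7
    )
    cloned = clone(sel)
    assert cloned.get_params() == sel.get_params()
    sel.fit(d.X, d.y)
    assert sel.n_features_in_ == 3
    assert "x0" in sel.chosen_
    assert sel.frequencies_["x0"] == 1.0
    reduced = sel.transform(d.X)
    assert list(reduced.columns) == sel.chosen_
    assert sel.get_support().sum() == len(sel.chosen_)
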