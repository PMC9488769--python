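"""Ensemble classifiers: naive Bayes exactness, rules, selection logic."""

import json

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from ecforge.ensemble import (
    NBParameters,
    TrainingDegenerateError,
    best_tool_assign,
    build_cooccurrence,
    build_training_sets,
    fit_alt_classifier,
    fit_naive_bayes,
    majority_rule_assign,
    model_from_json,
    model_to_json,
    multifunctional_filter,
    nb_posterior,
    score_proteins,
    select_high_confidence,
    train_ensemble,
    ScoredAnnotation,
)
from ecforge.prediction_io import PredictionRecord, PredictionTable
from tests.conftest import two_bin_profile


def brute_force_posterior(f, params):
    """Direct two-class evaluation of the Bayes posterior, no log tricks."""
    def joint(prior, conds):
        p = prior
        for fi, ci in zip(f, conds):
            p *= ci if fi == 1 else (1.0 - ci)
        return p

    num = joint(params.prior_pos, params.cond_pos)
    den = num + joint(1.0 - params.prior_pos, params.cond_neg)
    return num / den


class TestTrainingSets:
    def table(self):
        return PredictionTable(
            [
                PredictionRecord("p1", "1.1.1.1", "A", 0.9, "high"),
                PredictionRecord("p2", "1.1.1.1", "B", 0.8, "high"),
            ]
        )

    def test_positives_from_gold_negatives_from_predictions(self):
        pos, neg = build_training_sets(self.table(), {"p1": {"1.1.1.1"}}, "1.1.1.1")
        assert pos == {"p1"} and neg == {"p2"}

    def test_gold_protein_never_predicted_still_positive(self):
        gold = {"p1": {"1.1.1.1"}, "p9": {"1.1.1.1"}}
        pos, neg = build_training_sets(self.table(), gold, "1.1.1.1")
        assert "p9" in pos

    def test_no_negatives_is_degenerate(self):
        gold = {"p1": {"1.1.1.1"}, "p2": {"1.1.1.1"}}
        with pytest.raises(TrainingDegenerateError):
            build_training_sets(self.table(), gold, "1.1.1.1")


class TestNaiveBayesFit:
    def test_smoothed_conditionals_hand_counted(self):
        # 4 positives all F1=1; 6 negatives with one F1=1
        X = np.array([[1]] * 4 + [[1]] + [[0]] * 5)
        y = np.array([1] * 4 + [0] * 6)
        p = fit_naive_bayes(X, y, "1.1.1.1", ["A"], alpha=1.0)
        assert p.cond_pos[0] == pytest.approx(5 / 6)
        assert p.cond_neg[0] == pytest.approx(2 / 8)
        assert p.prior_pos == pytest.approx(5 / 12)

    def test_zero_alpha_rejected(self):
        X = np.array([[1], [0]])
        y = np.array([1, 0])
        with pytest.raises(ValueError):
            fit_naive_bayes(X, y, "1.1.1.1", ["A"], alpha=0.0)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingDegenerateError):
            fit_naive_bayes(np.array([[1], [0]]), np.array([1, 1]), "e", ["A"])

    def test_agrees_with_sklearn_bernoulli_nb(self):
        """Independent cross-check: scikit-learn's BernoulliNB with the same
        smoothing produces the same posteriors."""
        from sklearn.naive_bayes import BernoulliNB

        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(60, 3))
        y = (X.sum(axis=1) + rng.integers(0, 2, size=60) > 1).astype(int)
        params = fit_naive_bayes(X, y, "e", ["A", "B", "C"], alpha=1.0)
        # BernoulliNB smooths likelihoods identically; priors are unsmoothed,
        # so feed it the matching prior explicitly.
        clf = BernoulliNB(alpha=1.0, class_prior=[1 - params.prior_pos, params.prior_pos])
        clf.fit(X, y)
        for f in [(0, 0, 0), (1, 0, 1), (1, 1, 1), (0, 1, 0)]:
            ours = nb_posterior(np.array(f), params)
            theirs = clf.predict_proba(np.array(f).reshape(1, -1))[0, 1]
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestPosterior:
    PARAMS = NBParameters(
        ec="1.1.1.1", tools=("A", "B"), prior_pos=0.3,
        cond_pos=(0.9, 0.8), cond_neg=(0.2, 0.1),
    )

    def test_hand_evaluated_cases(self):
        assert nb_posterior([1, 0], self.PARAMS) == pytest.approx(0.30)
        assert nb_posterior([1, 1], self.PARAMS) == pytest.approx(0.216 / 0.230)

    def test_uninformative_features_return_prior(self):
        p = NBParameters(
            ec="e", tools=("A",), prior_pos=0.3, cond_pos=(0.6,), cond_neg=(0.6,)
        )
        for f in ([0], [1]):
            assert nb_posterior(f, p) == pytest.approx(0.3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nb_posterior([1], self.PARAMS)

    @seed(2024)
    @given(
        prior=st.floats(1e-6, 1 - 1e-6),
        cps=st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=5),
        data=st.data(),
    )
    @settings(max_examples=1000, deadline=None)
    def test_matches_brute_force_to_1e12(self, prior, cps, data):
        k = len(cps)
        cns = data.draw(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=k, max_size=k))
        f = data.draw(st.lists(st.integers(0, 1), min_size=k, max_size=k))
        params = NBParameters(
            ec="e", tools=tuple(f"t{i}" for i in range(k)),
            prior_pos=prior, cond_pos=tuple(cps), cond_neg=tuple(cns),
        )
        p1 = nb_posterior(f, params)
        assert p1 == pytest.approx(brute_force_posterior(f, params), abs=1e-12)
        # complementary-class normalization: p(y=0|f) from the same parameters
        joint_pos = params.prior_pos
        joint_neg = 1.0 - params.prior_pos
        for fi, cp, cn in zip(f, params.cond_pos, params.cond_neg):
            joint_pos *= cp if fi == 1 else 1.0 - cp
            joint_neg *= cn if fi == 1 else 1.0 - cn
        p0 = joint_neg / (joint_pos + joint_neg)
        assert p1 + p0 == pytest.approx(1.0, abs=1e-12)

    @seed(77)
    @given(data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_monotone_when_tools_are_informative(self, data):
        k = data.draw(st.integers(1, 4))
        cns = data.draw(st.lists(st.floats(0.01, 0.5), min_size=k, max_size=k))
        cps = [
            data.draw(st.floats(min_value=cn + 1e-6, max_value=0.99)) for cn in cns
        ]
        params = NBParameters(
            ec="e", tools=tuple(f"t{i}" for i in range(k)),
            prior_pos=0.3, cond_pos=tuple(cps), cond_neg=tuple(cns),
        )
        f = data.draw(st.lists(st.integers(0, 1), min_size=k, max_size=k))
        base = nb_posterior(f, params)
        for i in range(k):
            if f[i] == 0:
                g = list(f)
                g[i] = 1
                assert nb_posterior(g, params) >= base - 1e-12


class TestAltClassifiers:
    def separable(self):
        X = np.array([[1, 1]] * 10 + [[0, 0]] * 10, dtype=float)
        y = np.array([1] * 10 + [0] * 10)
        return X, y

    @pytest.mark.parametrize("method", ["logistic_regression", "random_forest"])
    def test_separable_data_fits_perfectly(self, method):
        X, y = self.separable()
        scorer = fit_alt_classifier(method, X, y, "e", ["a", "b"], seed=1)
        assert all((scorer.score(x) > 0.5) == bool(t) for x, t in zip(X, y))

    @pytest.mark.parametrize("method", ["logistic_regression", "random_forest"])
    def test_same_seed_same_scores(self, method):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(40, 2)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        held = rng.integers(0, 3, size=(10, 2)).astype(float)
        s1 = fit_alt_classifier(method, X, y, "e", ["a", "b"], seed=9)
        s2 = fit_alt_classifier(method, X, y, "e", ["a", "b"], seed=9)
        assert [s1.score(h) for h in held] == [s2.score(h) for h in held]

    def test_lr_score_monotone_in_tool_agreement(self):
        # more high-confidence tools should never lower the LR score on data
        # generated so that each tool is positively informative
        rng = np.random.default_rng(3)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = np.array([
            [1 if (yi and rng.random() < 0.9) or (not yi and rng.random() < 0.1)
             else 0 for _ in range(2)]
            for yi in y
        ], dtype=float)
        scorer = fit_alt_classifier("logistic_regression", X, y, "e", ["a", "b"], seed=1)
        scores = {f: scorer.score(np.array(f, dtype=float)) for f in
                  [(0, 0), (0, 1), (1, 0), (1, 1)]}
        assert scores[(1, 0)] >= scores[(0, 0)]
        assert scores[(1, 1)] >= max(scores[(1, 0)], scores[(0, 1)])


class TestRules:
    def test_majority_strict_over_able_tools(self):
        ranges = {t: {"1.1.1.1"} for t in "ABCDE"}
        votes3 = {t: {"1.1.1.1"} for t in "ABC"}
        assert majority_rule_assign(votes3, ranges) == {"1.1.1.1"}
        votes2 = {t: {"1.1.1.1"} for t in "AB"}
        assert majority_rule_assign(votes2, ranges) == set()

    def test_majority_single_able_tool(self):
        ranges = {"A": {"1.1.1.1"}, "B": set()}
        assert majority_rule_assign({"A": {"1.1.1.1"}}, ranges) == {"1.1.1.1"}

    def test_best_tool_rule_and_ties(self):
        ranges = {"A": {"1.1.1.1"}, "B": {"1.1.1.1"}}
        perf = {("1.1.1.1", "A"): 0.9, ("1.1.1.1", "B"): 0.4}
        assert best_tool_assign({"B": {"1.1.1.1"}}, perf, ranges) == set()
        assert best_tool_assign({"A": {"1.1.1.1"}}, perf, ranges) == {"1.1.1.1"}
        tie = {("1.1.1.1", "A"): 0.7, ("1.1.1.1", "B"): 0.7}
        assert best_tool_assign({"A": {"1.1.1.1"}}, tie, ranges) == {"1.1.1.1"}

    def test_best_tool_missing_ec_falls_back_to_majority(self):
        ranges = {"A": {"2.2.2.2"}, "B": {"2.2.2.2"}, "C": {"2.2.2.2"}}
        highs = {t: {"2.2.2.2"} for t in "AB"}
        with pytest.warns(UserWarning, match="majority"):
            out = best_tool_assign(highs, {}, ranges)
        assert out == {"2.2.2.2"}  # 2 of 3 able tools


class TestSelection:
    def test_threshold_is_strict(self):
        scored = [
            ScoredAnnotation("p", "1.1.1.1", 0.51, True, "classifier"),
            ScoredAnnotation("p", "2.2.2.2", 0.50, False, "classifier"),
        ]
        assert select_high_confidence(scored) == {("p", "1.1.1.1")}

    def test_rule_sources_selected_without_score(self):
        scored = [
            ScoredAnnotation("p", "1.1.1.1", None, True, "auto_rule"),
            ScoredAnnotation("p", "2.2.2.2", None, True, "passthrough"),
        ]
        assert len(select_high_confidence(scored)) == 2

    def test_idempotent(self):
        scored = [ScoredAnnotation("p", "1.1.1.1", 0.9, True, "classifier")]
        once = select_high_confidence(scored)
        again = select_high_confidence(
            [ScoredAnnotation(p, e, 0.9, True, "classifier") for p, e in once]
        )
        assert once == again


class TestMultifunctionalFilter:
    def test_top_plus_cooccurring(self):
        scores = {"e1": 0.9, "e2": 0.6, "e3": 0.55}
        assert multifunctional_filter(scores, {"e1": {"e2"}}) == {"e1", "e2"}

    def test_single_ec_unchanged(self):
        assert multifunctional_filter({"e1": 0.7}, {}) == {"e1"}

    def test_tied_top_all_retained(self):
        scores = {"e1": 0.9, "e2": 0.9, "e3": 0.2}
        out = multifunctional_filter(scores, {"e2": {"e3"}})
        assert out == {"e1", "e2", "e3"}

    def test_cooccurrence_thresholds(self):
        gold = {f"p{i}": {"a.a.a.a", "b.b.b.b"} for i in range(10)}
        gold.update({f"q{i}": {"a.a.a.a"} for i in range(5)})
        co = build_cooccurrence(gold, min_count=10, min_frac=0.5)
        assert co.get("a.a.a.a") == {"b.b.b.b"}  # 10/15 >= 0.5
        assert co.get("b.b.b.b") == {"a.a.a.a"}  # 10/10


class TestTrainScoreRoundTrip:
    def build(self):
        ecs = ["1.1.1.1", "2.7.1.1"]
        profiles = [two_bin_profile("A", ecs), two_bin_profile("B", ecs)]
        recs = []
        gold = {}
        for i in range(30):
            pid = f"p{i}"
            gold[pid] = {"1.1.1.1"} if i < 15 else {"2.7.1.1"}
            ec_true = next(iter(gold[pid]))
            recs.append(PredictionRecord(pid, ec_true, "A", 0.9, "high"))
            if i % 3 == 0:  # tool B false positives on the other EC
                other = "2.7.1.1" if ec_true == "1.1.1.1" else "1.1.1.1"
                recs.append(PredictionRecord(pid, other, "B", 0.8, "high"))
        return PredictionTable(recs), gold, profiles

    def test_high_conf_superset_of_auto_rule_hits(self):
        table, gold, profiles = self.build()
        model = train_ensemble(table, gold, profiles, min_ec_support=5)
        scored = score_proteins(model, table)
        selected = select_high_confidence(scored)
        auto_hits = {
            (a.protein_id, a.ec) for a in scored if a.source == "auto_rule"
        }
        assert auto_hits <= selected

    def test_passthrough_covers_out_of_range_ecs(self):
        table, gold, profiles = self.build()
        # an EC only tool B can emit, too rare to train on
        profiles[1] = two_bin_profile("B", ["1.1.1.1", "2.7.1.1", "5.5.5.5"])
        table.add(PredictionRecord("p0", "5.5.5.5", "B", 0.99, "high"))
        model = train_ensemble(
            table, gold, profiles, min_ec_support=5, passthrough_tool="B"
        )
        scored = score_proteins(model, table)
        tagged = {a for a in scored if a.ec == "5.5.5.5"}
        assert tagged and all(a.source == "passthrough" for a in tagged)
        assert ("p0", "5.5.5.5") in select_high_confidence(scored)

    def test_json_round_trip_preserves_scores(self):
        table, gold, profiles = self.build()
        model = train_ensemble(table, gold, profiles, min_ec_support=5)
        restored = model_from_json(model_to_json(model))
        s1 = score_proteins(model, table)
        s2 = score_proteins(restored, table)
        assert s1 == s2
        assert restored.auto_assign_ecs == model.auto_assign_ecs
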