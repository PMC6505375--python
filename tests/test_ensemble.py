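"""Softmax weighting, majority vote, accuracy deltas and ensemble prediction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raterstack as rs
from conftest import make_table

finite_z = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=8
)


class TestSoftmaxWeights:
    def test_uniform_deltas_give_uniform_weights(self):
        w = rs.softmax_weights([0.0, 0.0, 0.0])
        np.testing.assert_allclose(w.w, [1 / 3] * 3, atol=1e-12)

    def test_log_two_case(self):
        w = rs.softmax_weights([math.log(2), 0.0, 0.0])
        np.testing.assert_allclose(w.w, [0.5, 0.25, 0.25], atol=1e-12)

    def test_matches_direct_formula(self):
        z = np.array([0.3, -0.1, 0.0])
        expected = np.exp(z) / np.exp(z).sum()  # direct, no max-subtraction
        np.testing.assert_allclose(rs.softmax_weights(z).w, expected, atol=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rs.softmax_weights([])
        with pytest.raises(ValueError):
            rs.softmax_weights([0.0, np.inf])

    @settings(deadline=None)
    @given(finite_z)
    def test_normalization_and_positivity(self, z):
        w = rs.softmax_weights(z).w
        assert abs(w.sum() - 1.0) <= 1e-9
        assert (w > 0).all()

    @settings(deadline=None)
    @given(finite_z, st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_shift_invariance(self, z, c):
        w1 = rs.softmax_weights(np.asarray(z)).w
        w2 = rs.softmax_weights(np.asarray(z) + c).w
        np.testing.assert_allclose(w1, w2, atol=1e-9)

    @settings(deadline=None)
    @given(st.lists(st.floats(min_value=-2, max_value=2, allow_nan=False),
                    min_size=2, max_size=6),
           st.integers(min_value=0, max_value=5),
           st.floats(min_value=0.01, max_value=1.0))
    def test_monotonicity(self, z, j_raw, bump):
        z = np.asarray(z)
        j = j_raw % len(z)
        before = rs.softmax_weights(z).w
        z2 = z.copy()
        z2[j] += bump
        after = rs.softmax_weights(z2).w
        assert after[j] > before[j]
        others = np.delete(np.arange(len(z)), j)
        assert (after[others] < before[others]).all()

    def test_weight_order_matches_delta_order(self):
        wv = rs.softmax_weights([0.2, -0.3, 0.05], rater_ids=("a", "b", "c"))
        assert np.argsort(wv.z).tolist() == np.argsort(wv.w).tolist()


class TestMajorityVote:
    def test_plurality(self):
        votes = {"c1": ["ASD", "ASD", "SLC"]}
        assert rs.majority_vote(votes)["c1"] == "ASD"

    def test_single_voter_identity(self):
        assert rs.majority_vote({"c": ["SLC"]})["c"] == "SLC"

    def test_tie_broken_by_prevalence_then_order(self):
        votes = {"c": ["ASD", "TD"]}
        assert rs.majority_vote(votes, prevalence={"TD": 10, "ASD": 5})["c"] == "TD"
        assert rs.majority_vote(votes, prevalence={"TD": 5, "ASD": 10})["c"] == "ASD"
        # equal prevalence: first in class order wins
        assert rs.majority_vote(votes, prevalence={"TD": 5, "ASD": 5},
                                class_order=["ASD", "SLC", "TD"])["c"] == "ASD"

    def test_exhaustive_three_voters_matches_brute_force(self):
        classes = ["ASD", "SLC", "TD"]
        prevalence = {"ASD": 3, "SLC": 2, "TD": 1}

        def brute(votes):
            counts = {c: votes.count(c) for c in classes}
            top = max(counts.values())
            tied = [c for c in classes if counts[c] == top]
            tied.sort(key=lambda c: (-prevalence[c], classes.index(c)))
            return tied[0]

        for votes in itertools.product(classes, repeat=3):
            got = rs.majority_vote({"c": list(votes)}, prevalence=prevalence,
                                   class_order=classes)["c"]
            assert got == brute(list(votes)), votes

    def test_no_votes_errors(self):
        with pytest.raises(ValueError):
            rs.majority_vote({"c": []})


class TestAccuracyDelta:
    def test_equal_accuracies_give_zero(self):
        y = [1, 1, 0, 0, 1, 0, 1, 0, 1, 0]
        model = [1, 1, 0, 0, 1, 0, 0, 1, 0, 1]  # 6/10
        base = [1, 1, 0, 0, 1, 1, 0, 0, 0, 1]  # 6/10
        assert rs.accuracy_delta(y, model, base) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        y = [1, 1, 1, 0, 0]
        model = [1, 1, 1, 0, 1]  # 4/5
        base = [1, 1, 0, 1, 0]  # 3/5
        assert rs.accuracy_delta(y, model, base) == pytest.approx(0.2)

    def test_boundary(self):
        y = [1, 0, 1]
        assert rs.accuracy_delta(y, y, [0, 1, 0]) == pytest.approx(1.0)

    def test_empty_validation_set_errors(self):
        with pytest.raises(ValueError):
            rs.accuracy_delta([], [], [])


class TestTrainRaterModel:
    def test_separable_training_accuracy_one(self, small_table):
        # one question fully determines the label in the separable scenario
        table = make_table(n_per_class=8, seed=3,
                          archetypes=rs.separable_archetypes(),
                          profiles=[rs.RaterProfile("R", np.ones(31), np.zeros(31))])
        labels = {c: table.diagnosis(c) for c in table.child_ids}
        m = rs.train_rater_model(table, "R", labels, {"n_estimators": 25}, seed=0)
        X, y, _ = rs.encode_matrix(table, "R")
        assert (m.predict(X) == y).all()

    def test_deterministic_given_seed(self, small_table):
        labels = {c: small_table.diagnosis(c) for c in small_table.child_ids}
        m1 = rs.train_rater_model(small_table, "R1", labels, {"n_estimators": 25}, seed=5)
        m2 = rs.train_rater_model(small_table, "R1", labels, {"n_estimators": 25}, seed=5)
        X, _, _ = rs.encode_matrix(small_table, "R1")
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_labels_error(self, small_table):
        labels = {c: "TD" for c in small_table.child_ids}
        with pytest.raises(ValueError, match="single class"):
            rs.train_rater_model(small_table, "R1", labels, {}, seed=0)

    def test_shuffled_labels_give_chance_accuracy(self):
        # permutation oracle: with labels shuffled independently of the
        # features, every held-out prediction is correct with probability
        # equal to the majority-class rate (0.5 for balanced labels)
        table = make_table(n_per_class=20, seed=6)
        ids = table.child_ids
        rng = np.random.default_rng(0)
        y = np.tile([0, 1], len(ids) // 2)  # balanced, then shuffled per rep
        accs = []
        for rep in range(50):
            shuffled = y[rng.permutation(len(ids))]
            labels = dict(zip(ids, map(int, shuffled)))
            tr = ids[: int(0.7 * len(ids))]
            te = ids[int(0.7 * len(ids)):]
            m = rs.train_rater_model(table.subset(tr), "R1", labels,
                                     {"n_estimators": 20}, seed=rep)
            X, _, te_ids = rs.encode_matrix(table.subset(te), "R1")
            accs.append(np.mean(m.predict(X) == [labels[c] for c in te_ids]))
        # 50 reps x 12 held-out children: 3 SE is about 0.06
        assert abs(np.mean(accs) - 0.5) < 0.06


class TestEnsemblePredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        table = make_table(n_per_class=10, seed=8)
        labels = {c: int(table.diagnosis(c) != "TD") for c in table.child_ids}
        est = rs.RaterEnsembleClassifier(n_estimators=40, random_state=1)
        return table, labels, est.fit(table, labels)

    @staticmethod
    def _stub_models_table(prob_rows, seed=0):
        """Stub rater models emitting fixed per-child class-1 probabilities."""
        import pandas as pd

        from raterstack.vocabulary import FeatureVocabulary, Question

        vocab = FeatureVocabulary((Question("q01", "item", ("a", "b")),))
        n_children, n_raters = prob_rows.shape
        cids = [f"c{i:02d}" for i in range(n_children)]
        rows = [(c, f"r{j}", 0) for c in cids for j in range(n_raters)]
        df = pd.DataFrame(rows, columns=["child_id", "rater_id", "q01"])
        children = {c: rs.ChildRecord(c, "TD") for c in cids}
        table = rs.AnnotationTable(df, vocab, children)

        class Stub:
            def __init__(self, rid, probs):
                self.rater_id = rid
                self.classes = np.array([0, 1])
                self._p = dict(zip(sorted(cids), probs))
                self._order = sorted(cids)

            def predict_proba(self, X):
                p = np.array([self._p[c] for c in self._order[: len(X)]])
                return np.column_stack([1 - p, p])

        models = [Stub(f"r{j}", prob_rows[:, j]) for j in range(n_raters)]
        return table, models

    def test_equal_weight_arithmetic_mean(self):
        table, models = self._stub_models_table(np.array([[0.8, 0.6]]))
        wv = rs.WeightVector(("r0", "r1"), np.zeros(2), np.array([0.5, 0.5]))
        out = rs.ensemble_predict(models, wv, table, target_class=1)
        assert out["ensemble"].iloc[0] == pytest.approx(0.7, abs=1e-12)

    def test_random_weights_match_dot_product_oracle(self):
        rng = np.random.default_rng(4)
        probs = rng.random((12, 4))
        table, models = self._stub_models_table(probs)
        raw = rng.random(4)
        w = raw / raw.sum()
        wv = rs.WeightVector(tuple(f"r{j}" for j in range(4)), np.zeros(4), w)
        out = rs.ensemble_predict(models, wv, table, target_class=1)
        np.testing.assert_allclose(out["ensemble"].to_numpy(), probs @ w, atol=1e-12)

    def test_linear_combination_exact(self, fitted):
        table, _, est = fitted
        out = est.predict_contributions(table, target_class=1)
        w = {r: out[f"w_{r}"] for r in est.rater_ids_}
        manual = sum(out[f"p_{r}"].fillna(0) * w[r] for r in est.rater_ids_)
        np.testing.assert_allclose(out["ensemble"], manual, atol=1e-12)

    def test_bounded_by_per_rater_extremes(self, fitted):
        table, _, est = fitted
        out = est.predict_contributions(table, target_class=1)
        probs = out[[f"p_{r}" for r in est.rater_ids_]]
        assert (out["ensemble"] >= probs.min(axis=1) - 1e-12).all()
        assert (out["ensemble"] <= probs.max(axis=1) + 1e-12).all()

    def test_degenerate_weight_returns_single_model(self, fitted):
        table, _, est = fitted
        models = list(est.models_.values())
        wv = rs.WeightVector(tuple(est.rater_ids_), np.zeros(3),
                             np.array([1.0, 0.0, 0.0]))
        out = rs.ensemble_predict(models, wv, table, target_class=1)
        np.testing.assert_allclose(out["ensemble"], out[f"p_{est.rater_ids_[0]}"],
                                   atol=0)

    def test_partial_coverage_renormalizes_weights(self, fitted):
        table, _, est = fitted
        # drop one child's rows for rater R1
        victim = table.child_ids[0]
        df = table.df[~((table.df["child_id"] == victim)
                        & (table.df["rater_id"] == "R1"))]
        partial = rs.AnnotationTable(df, table.vocabulary, table.children)
        out = rs.ensemble_predict(list(est.models_.values()), est.weights_,
                                  partial, target_class=1)
        assert np.isnan(out.loc[victim, "p_R1"])
        assert out.loc[victim, "w_R1"] == 0.0
        covering = [f"w_{r}" for r in est.rater_ids_ if r != "R1"]
        assert out.loc[victim, covering].sum() == pytest.approx(1.0, abs=1e-9)
        # renormalized combination still matches the covering raters
        manual = sum(out.loc[victim, f"p_{r}"] * out.loc[victim, f"w_{r}"]
                     for r in est.rater_ids_ if r != "R1")
        assert out.loc[victim, "ensemble"] == pytest.approx(manual, abs=1e-12)

    def test_child_with_no_weighted_rater_errors(self, fitted):
        table, _, est = fitted
        victim = table.child_ids[0]
        # weight only R1, then remove the victim's R1 row: no covering rater
        df = table.df[~((table.df["child_id"] == victim)
                        & (table.df["rater_id"] == "R1"))]
        partial = rs.AnnotationTable(df, table.vocabulary, table.children)
        wv = rs.WeightVector(("R1",), np.zeros(1), np.ones(1))
        with pytest.raises(ValueError, match="no annotations from any weighted"):
            rs.ensemble_predict([est.models_["R1"]], wv, partial, target_class=1)


class TestRaterEnsembleClassifier:
    def test_fit_is_deterministic(self):
        table = make_table(n_per_class=10, seed=9)
        labels = {c: int(table.diagnosis(c) != "TD") for c in table.child_ids}
        a = rs.RaterEnsembleClassifier(n_estimators=30, random_state=2).fit(table, labels)
        b = rs.RaterEnsembleClassifier(n_estimators=30, random_state=2).fit(table, labels)
        np.testing.assert_array_equal(a.z_, b.z_)
        np.testing.assert_allclose(a.predict_proba(table).to_numpy(),
                                   b.predict_proba(table).to_numpy())

    def test_class_probabilities_sum_to_one(self):
        table = make_table(n_per_class=8, seed=10)
        labels = {c: table.diagnosis(c) for c in table.child_ids}
        est = rs.RaterEnsembleClassifier(n_estimators=30, random_state=0).fit(table, labels)
        proba = est.predict_proba(table)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert set(proba.columns) == {"ASD", "SLC", "TD"}

    def test_get_set_params_round_trip(self):
        est = rs.RaterEnsembleClassifier(n_estimators=11, temperature=2.0)
        params = est.get_params()
        est2 = rs.RaterEnsembleClassifier().set_params(**params)
        assert est2.get_params() == params
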