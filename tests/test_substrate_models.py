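"""Classifier training, CV, model selection, consensus voting."""

import numpy as np
import pytest
from rdkit import Chem

from ugtsom.evaluate import auc
from ugtsom.substrate_models import (ClassifierSpec, ConsensusModel,
                                     ConsensusSpec, CVResult, EarlyStopPolicy,
                                     FeatureSpec, ModelError, build_features,
                                     cross_validate, enumerate_consensus,
                                     load_trained_model, save_trained_model,
                                     select_top_models, soft_vote,
                                     split_dataset, train_graph_classifier,
                                     train_traditional, y_randomization)

MORGAN = FeatureSpec(kind="fingerprint", fp_kind="morgan", nbits=1024)
GRAPH = FeatureSpec(kind="graph", scheme="classifier")


def _toy_separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, size=(n // 2, 4)),
                   rng.normal(4, 0.3, size=(n // 2, 4))])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestSpecs:
    def test_graph_method_rejects_vector_feature(self):
        with pytest.raises(ValueError):
            ClassifierSpec(method="GCN", feature=MORGAN)

    def test_traditional_method_rejects_graph_feature(self):
        with pytest.raises(ValueError):
            ClassifierSpec(method="RF", feature=GRAPH)

    def test_unimplemented_variants_raise_at_train_time(self):
        spec = ClassifierSpec(method="GAT", feature=GRAPH)
        with pytest.raises(NotImplementedError):
            train_graph_classifier(spec, [], [])


class TestSplitDataset:
    def test_seeded_and_stable(self):
        items = list(range(10))
        a = split_dataset(items, (0.8, 0.2), seed=1)
        b = split_dataset(items, (0.8, 0.2), seed=1)
        assert a == b
        assert len(a[0]) == 8 and len(a[1]) == 2

    def test_groups_never_straddle_partitions(self):
        items = [(i, i // 2) for i in range(40)]  # pairs share a group
        parts = split_dataset(items, (0.8, 0.1, 0.1), seed=3,
                              group_key=lambda t: t[1])
        for part in parts:
            groups = {g for _, g in part}
            for other in parts:
                if other is not part:
                    assert groups.isdisjoint({g for _, g in other})

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (0.5, 0.6), seed=0)

    def test_oversized_group_rejected(self):
        items = [(i, 0) for i in range(10)]
        with pytest.raises(ValueError):
            split_dataset(items, (0.5, 0.5), seed=0,
                          group_key=lambda t: t[1])


class TestTraditional:
    @pytest.mark.parametrize("method", ["RF", "ET"])
    def test_separable_data_perfect_training_accuracy(self, method):
        X, y = _toy_separable()
        model = train_traditional(
            ClassifierSpec(method=method, feature=MORGAN, seed=0), X, y)
        assert (model.predict(X) == y).all()

    def test_constant_features_give_class_prior(self):
        X = np.ones((40, 3))
        y = np.repeat([0, 1], [10, 30])  # prior 0.75
        model = train_traditional(
            ClassifierSpec(method="LR", feature=MORGAN, seed=0), X, y)
        probs = model.predict_proba(X)
        np.testing.assert_allclose(probs, 0.75, atol=0.01)

    def test_refit_same_seed_identical_predictions(self):
        X, y = _toy_separable(40, seed=2)
        spec = ClassifierSpec(method="NN", feature=MORGAN, seed=7)
        p1 = train_traditional(spec, X, y).predict_proba(X)
        p2 = train_traditional(spec, X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ModelError):
            train_traditional(
                ClassifierSpec(method="RF", feature=MORGAN), X, np.ones(10))

    def test_svm_probabilities_in_unit_interval(self):
        X, y = _toy_separable(30, seed=4)
        model = train_traditional(
            ClassifierSpec(method="SVM", feature=MORGAN, seed=0), X, y)
        p = model.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()


@pytest.fixture(scope="module")
def planted_graphs(substrate_set):
    graphs = build_features([r.mol for r in substrate_set], GRAPH)
    y = np.array([r.label for r in substrate_set])
    return graphs, y


class TestGraphClassifiers:
    @pytest.mark.parametrize("method", ["GCN", "AttentiveFP"])
    def test_recovers_planted_rule(self, planted_graphs, method):
        graphs, y = planted_graphs
        spec = ClassifierSpec(method=method, feature=GRAPH,
                              hyperparams=(("hidden", 48),), seed=1)
        tr, te = np.arange(240), np.arange(240, 300)
        model = train_graph_classifier(
            spec, [graphs[i] for i in tr], y[tr],
            policy=EarlyStopPolicy(max_epochs=150))
        assert auc(model.predict_proba([graphs[i] for i in te]), y[te]) >= 0.9

    def test_shuffled_labels_give_chance_performance(self, planted_graphs,
                                                     rng):
        graphs, y = planted_graphs
        ys = rng.permutation(y[:200])
        spec = ClassifierSpec(method="GCN", feature=GRAPH,
                              hyperparams=(("hidden", 32),), seed=5)
        model = train_graph_classifier(
            spec, graphs[:200], ys, policy=EarlyStopPolicy(max_epochs=40))
        heldout_auc = auc(model.predict_proba(graphs[200:260]), y[200:260])
        assert abs(heldout_auc - 0.5) < 0.2

    def test_training_respects_epoch_cap(self, planted_graphs):
        graphs, y = planted_graphs
        spec = ClassifierSpec(method="GCN", feature=GRAPH,
                              hyperparams=(("hidden", 16),), seed=2)
        model = train_graph_classifier(
            spec, graphs[:100], y[:100],
            policy=EarlyStopPolicy(max_epochs=5, patience_train=99,
                                   patience_valid=99))
        assert model.manifest["epochs"] <= 5


class TestCrossValidation:
    def test_every_sample_validated_once(self):
        X, y = _toy_separable(100, seed=1)
        res = cross_validate(
            ClassifierSpec(method="LR", feature=MORGAN, seed=0), X, y, k=10)
        assert len(res.fold_metrics) == 10
        assert len(res.oof_probs) == 100
        # separable data: every out-of-fold prediction is on the right side
        assert res.pooled["ACC"] == 1.0 and res.pooled["MCC"] == 1.0

    def test_coin_flip_scores_give_null_auc(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))  # features carry no signal
        y = rng.integers(0, 2, size=n)
        res = cross_validate(
            ClassifierSpec(method="LR", feature=MORGAN, seed=0), X, y, k=10)
        assert abs(res.pooled["AUC"] - 0.5) < 0.12

    def test_k_below_two_rejected(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError):
            cross_validate(
                ClassifierSpec(method="LR", feature=MORGAN), X, y, k=1)


def _fake_cv(name, mcc, auc_):
    spec = ClassifierSpec(method="RF", feature=MORGAN,
                          seed=sum(map(ord, name)))
    return CVResult(spec=spec, fold_metrics=[],
                    pooled={"MCC": mcc, "AUC": auc_}, oof_probs=np.zeros(1))


class TestSelectionAndConsensus:
    def test_select_top_by_mcc(self):
        results = [_fake_cv("a", 0.9, 0.9), _fake_cv("b", 0.5, 0.9),
                   _fake_cv("c", 0.7, 0.9)]
        top = select_top_models(results, 2)
        assert [t.pooled["MCC"] for t in top] == [0.9, 0.7]

    def test_tie_broken_by_auc(self):
        results = [_fake_cv("a", 0.7, 0.80), _fake_cv("b", 0.7, 0.95)]
        top = select_top_models(results, 1)
        assert top[0].pooled["AUC"] == 0.95

    def test_n_equal_to_pool_is_identity_ordering(self):
        results = [_fake_cv("a", 0.3, 0.6), _fake_cv("b", 0.8, 0.9)]
        top = select_top_models(results, 2)
        assert [t.pooled["MCC"] for t in top] == [0.8, 0.3]

    def test_n_larger_than_pool_rejected(self):
        with pytest.raises(ValueError):
            select_top_models([_fake_cv("a", 0.5, 0.5)], 2)

    @pytest.mark.parametrize("m,expected", [(2, 3), (3, 7), (10, 1023)])
    def test_consensus_enumeration_counts_all_nonempty_subsets(
            self, m, expected):
        """The default family is every non-empty member subset: 2^m - 1
        committees, which is the reported 1023 for ten top models."""
        specs = enumerate_consensus([f"model{i}" for i in range(m)])
        assert len(specs) == expected
        assert len(specs) == 2 ** m - 1

    @pytest.mark.parametrize("m,expected", [(2, 1), (3, 4), (10, 1013)])
    def test_strict_multimember_enumeration(self, m, expected):
        """Restricting to genuine combinations of >= 2 members gives
        C(m,2)+...+C(m,m) = 2^m - m - 1."""
        specs = enumerate_consensus([f"model{i}" for i in range(m)],
                                    min_size=2)
        assert len(specs) == expected
        assert len(specs) == 2 ** m - m - 1

    def test_consensus_subsets_are_distinct_and_sized(self):
        specs = enumerate_consensus([f"m{i}" for i in range(5)])
        assert len({s.members for s in specs}) == len(specs)
        assert all(1 <= len(s.members) <= 5 for s in specs)

    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(ValueError):
            enumerate_consensus(["only"])


class TestSoftVote:
    def test_boundary_inclusive(self):
        prob, label = soft_vote([[0.6], [0.4]])
        assert prob[0] == pytest.approx(0.5)
        assert label[0] == 1  # mean exactly 0.5 is called substrate

    def test_all_zero(self):
        prob, label = soft_vote([[0.0], [0.0]])
        assert prob[0] == 0.0 and label[0] == 0

    def test_identical_members_equal_single_model(self, rng):
        p = rng.random(20)
        prob, _ = soft_vote([p, p, p])
        np.testing.assert_allclose(prob, p)

    def test_probability_bounded_by_member_extremes(self, rng):
        P = rng.random((5, 30))
        prob, _ = soft_vote(P)
        assert (prob >= P.min(axis=0) - 1e-12).all()
        assert (prob <= P.max(axis=0) + 1e-12).all()

    def test_duplicate_agreeing_member_keeps_label(self, rng):
        a = rng.random(25)
        _, l2 = soft_vote([a, a])
        _, l3 = soft_vote([a, a, a])
        np.testing.assert_array_equal(l2, l3)

    def test_member_failure_fails_consensus(self):
        with pytest.raises(ModelError):
            soft_vote([[0.5], [float("nan")]])

    def test_consensus_spec_validation(self):
        with pytest.raises(ValueError):
            ConsensusSpec(members=())
        with pytest.raises(ValueError):
            ConsensusSpec(members=("a", "a"))


class TestYRandomization:
    def test_planted_signal_beats_all_shuffles(self, substrate_set):
        mols = [r.mol for r in substrate_set[:150]]
        y = np.array([r.label for r in substrate_set[:150]])
        X = build_features(mols, MORGAN)
        spec = ClassifierSpec(method="LR", feature=MORGAN, seed=0)
        report = y_randomization(spec, X, y, n_rounds=5, seed=1, k=5)
        assert report["true_mcc"] > max(report["shuffled_mcc"])
        assert report["true_quantile"] == 1.0
        assert abs(report["shuffled_mean"]) < 0.2

    def test_single_round_reported(self, substrate_set):
        mols = [r.mol for r in substrate_set[:60]]
        y = np.array([r.label for r in substrate_set[:60]])
        X = build_features(mols, MORGAN)
        spec = ClassifierSpec(method="LR", feature=MORGAN, seed=0)
        report = y_randomization(spec, X, y, n_rounds=1, seed=2, k=5)
        assert len(report["shuffled_mcc"]) == 1


class TestPersistence:
    def test_traditional_round_trip(self, tmp_path):
        X, y = _toy_separable(40, seed=9)
        spec = ClassifierSpec(method="RF", feature=MORGAN, seed=4)
        model = train_traditional(spec, X, y)
        save_trained_model(model, str(tmp_path / "rf"))
        loaded = load_trained_model(str(tmp_path / "rf"))
        np.testing.assert_array_equal(loaded.predict_proba(X),
                                      model.predict_proba(X))

    def test_graph_round_trip(self, tmp_path, substrate_set):
        graphs = build_features([r.mol for r in substrate_set[:60]], GRAPH)
        y = np.array([r.label for r in substrate_set[:60]])
        spec = ClassifierSpec(method="GCN", feature=GRAPH,
                              hyperparams=(("hidden", 16),), seed=1)
        model = train_graph_classifier(spec, graphs, y,
                                       policy=EarlyStopPolicy(max_epochs=3))
        save_trained_model(model, str(tmp_path / "gcn"))
        loaded = load_trained_model(str(tmp_path / "gcn"))
        np.testing.assert_allclose(loaded.predict_proba(graphs),
                                   model.predict_proba(graphs), atol=1e-6)
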