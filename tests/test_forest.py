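"""Balanced random forest: bootstraps, votes, OOB emissions, determinism."""

import numpy as np
import pytest

from wristml import forest as rf
from wristml.signal import ValidationError
from conftest import gaussian_fixture

TWO = rf.ClassScheme(("active", "rest"))


@pytest.fixture(scope="module")
def separable():
    """Two well-separated Gaussian classes, 500 rows each."""
    X, y = gaussian_fixture([500, 500], {"active": 0.0, "rest": 4.0}, seed=1)
    return X, y


@pytest.fixture(scope="module")
def separable_forest(separable):
    X, y = separable
    model = rf.train_balanced_forest(
        X, y, rf.TrainingConfig(n_trees=100, seed=7), TWO
    )
    return model, X, y


def test_every_bag_is_balanced():
    scheme = rf.ClassScheme(tuple("abcdef"))
    counts = [20, 30, 40, 50, 60, 70]
    X, y = gaussian_fixture(
        counts, {c: 2.0 * i for i, c in enumerate(scheme.classes)}, seed=2
    )
    model = rf.train_balanced_forest(
        X, y, rf.TrainingConfig(n_trees=10, seed=0), scheme
    )
    assert model.n_rare == 20
    enc = scheme.encode(y)
    for tree in model.trees:
        assert len(tree.in_bag) == 20 * 6
        bag_classes = enc[tree.in_bag]
        assert all((bag_classes == k).sum() == 20 for k in range(6))


def test_feature_subspace_size_is_sqrt_f(separable_forest):
    model, _, _ = separable_forest
    m = int(np.sqrt(model.n_features))
    for tree in model.trees:
        assert len(tree.feature_subspace) == m
        assert len(set(tree.feature_subspace.tolist())) == m
        used = set(tree.feature[tree.feature >= 0].tolist())
        assert used <= set(tree.feature_subspace.tolist())


def test_oob_accuracy_on_separable_fixture(separable_forest):
    model, X, y = separable_forest
    votes = rf.oob_votes(model, X)
    covered = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    acc = (pred[covered] == TWO.encode(y)[covered]).mean()
    assert acc > 0.95


def test_missing_class_is_named():
    X, y = gaussian_fixture([50], {"active": 0.0}, seed=3)
    with pytest.raises(ValidationError, match="rest"):
        rf.train_balanced_forest(X, y, rf.TrainingConfig(n_trees=5), TWO)


class TestPredictVotes:
    def test_single_tree_probabilities_are_one_hot(self, separable):
        X, y = separable
        model = rf.train_balanced_forest(
            X, y, rf.TrainingConfig(n_trees=1, seed=0), TWO
        )
        _, probs, _ = rf.predict_votes(model, X[:20])
        assert set(np.unique(probs)) <= {0.0, 1.0}
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_probabilities_are_normalised_votes(self, separable_forest):
        model, X, _ = separable_forest
        votes, probs, pred = rf.predict_votes(model, X[:50])
        assert (votes.sum(axis=1) == model.n_trees).all()
        assert np.allclose(probs, votes / model.n_trees)
        assert np.array_equal(pred, votes.argmax(axis=1))

    def test_dimension_mismatch_rejected(self, separable_forest):
        model, _, _ = separable_forest
        with pytest.raises(ValidationError):
            rf.predict_votes(model, np.zeros((2, model.n_features + 1)))


def test_determinism_for_fixed_seed(separable):
    X, y = separable
    cfg = rf.TrainingConfig(n_trees=20, seed=123)
    a = rf.train_balanced_forest(X, y, cfg, TWO)
    b = rf.train_balanced_forest(X, y, cfg, TWO)
    assert a.to_dict() == b.to_dict()
    ea = rf.oob_emission_matrix(a, X, y)
    eb = rf.oob_emission_matrix(b, X, y)
    assert np.array_equal(ea.probs, eb.probs)


class TestOobEmissions:
    def test_separable_fixture_gives_near_identity(self, separable_forest):
        model, X, y = separable_forest
        em = rf.oob_emission_matrix(model, X, y)
        assert np.abs(em.probs - np.eye(2)).max() < 0.05

    def test_rows_sum_to_one(self, separable_forest):
        model, X, y = separable_forest
        em = rf.oob_emission_matrix(model, X, y)
        assert np.allclose(em.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_in_bag_rows_are_excluded(self):
        """With a single tree, its bagged rows must not enter the estimate."""
        X, y = gaussian_fixture([5, 5], {"active": 0.0, "rest": 6.0}, seed=4)
        model = rf.train_balanced_forest(
            X, y, rf.TrainingConfig(n_trees=1, seed=1), TWO
        )
        votes = rf.oob_votes(model, X)
        assert (votes[np.unique(model.trees[0].in_bag)] == 0).all()


def test_more_trees_do_not_hurt_oob_accuracy(separable):
    X, y = separable
    enc = TWO.encode(y)

    def oob_acc(n_trees):
        model = rf.train_balanced_forest(
            X, y, rf.TrainingConfig(n_trees=n_trees, seed=5), TWO
        )
        votes = rf.oob_votes(model, X)
        covered = votes.sum(axis=1) > 0
        return (votes.argmax(axis=1)[covered] == enc[covered]).mean()

    assert oob_acc(100) >= oob_acc(5)


def test_imbalanced_training_keeps_per_class_recall():
    """95:5 imbalance must not crush minority-class recall (the point of
    balancing the bootstraps)."""
    X, y = gaussian_fixture([950, 50], {"active": 0.0, "rest": 3.0}, seed=6)
    model = rf.train_balanced_forest(
        X, y, rf.TrainingConfig(n_trees=100, seed=2), TWO
    )
    enc = TWO.encode(y)
    votes = rf.oob_votes(model, X)
    covered = votes.sum(axis=1) > 0
    pred = votes.argmax(axis=1)
    for k in range(2):
        m = covered & (enc == k)
        assert (pred[m] == k).mean() > 0.8


def test_serialisation_round_trip(separable_forest):
    model, X, _ = separable_forest
    back = rf.ForestModel.from_dict(model.to_dict())
    _, pa, _ = rf.predict_votes(model, X[:100])
    _, pb, _ = rf.predict_votes(back, X[:100])
    assert np.array_equal(pa, pb)
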