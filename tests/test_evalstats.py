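"""Agreement statistics and leave-one-subject-out machinery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from wristml import evalstats as ev, simulate as sim
from wristml.forest import ClassScheme
from wristml.signal import ValidationError

AB = ClassScheme(("A", "B"))


def _sequences_from_counts(counts):
    """Expand a confusion-count table into (truth, predicted) sequences."""
    truth, pred = [], []
    for i, row in enumerate(counts):
        for j, n in enumerate(row):
            truth += [i] * n
            pred += [j] * n
    return np.array(truth), np.array(pred)


class TestKappa:
    def test_identical_sequences_give_one(self):
        with pytest.warns(UserWarning):
            assert ev.cohens_kappa(["a"] * 5, ["a"] * 5) == 1.0
        assert ev.cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_hand_computed_two_class_table(self):
        truth, pred = _sequences_from_counts([[45, 5], [15, 35]])
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        assert ev.cohens_kappa(truth, pred) == pytest.approx(0.6)

    def test_constant_prediction_scores_zero(self):
        truth = np.array([0] * 70 + [1] * 30)
        pred = np.zeros(100, dtype=int)
        assert ev.cohens_kappa(truth, pred) == pytest.approx(0.0)

    def test_independent_sequences_score_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 100_000)
        b = rng.integers(0, 4, 100_000)
        assert abs(ev.cohens_kappa(a, b)) < 0.02

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, 500)
        pred = np.where(rng.random(500) < 0.7, truth, rng.integers(0, 3, 500))
        assert ev.cohens_kappa(truth, pred) == pytest.approx(
            cohen_kappa_score(truth, pred), abs=1e-12
        )

    def test_bounded_in_minus_one_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            if np.array_equal(np.unique(a), np.unique(b)) and len(np.unique(a)) == 1:
                continue
            assert -1.0 - 1e-12 <= ev.cohens_kappa(a, b) <= 1.0 + 1e-12


class TestConfusion:
    def test_perfect_agreement_is_100_diagonal(self):
        pct, empty = ev.confusion_rownorm(["A", "B"], ["A", "B"], AB)
        assert np.allclose(pct, 100 * np.eye(2))
        assert not empty.any()

    def test_row_percentages(self):
        truth, pred = _sequences_from_counts([[45, 5], [15, 35]])
        labels = np.array(["A", "B"], dtype=object)
        pct, _ = ev.confusion_rownorm(labels[truth], labels[pred], AB)
        assert np.allclose(pct, [[90.0, 10.0], [30.0, 70.0]])

    def test_absent_class_row_is_flagged(self):
        pct, empty = ev.confusion_rownorm(["A", "A"], ["A", "B"], AB)
        assert empty[1] and np.all(pct[1] == 0.0)


class TestMetAgreement:
    def test_identical_series(self):
        rmse, r = ev.met_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r == pytest.approx(1.0)

    def test_hand_computed_rmse(self):
        rmse, _ = ev.met_agreement([1.0, 3.0], [2.0, 2.0 + 1e-9])
        assert rmse == pytest.approx(1.0)

    def test_constant_prediction_has_no_correlation(self):
        with pytest.raises(ValidationError):
            ev.met_agreement([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        assert ev.bland_altman([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        bias, lo, hi = ev.bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_single_day_rejected(self):
        with pytest.raises(ValidationError):
            ev.bland_altman([1.0], [2.0])


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert ev.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_unit_effect(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(20_000) + 1.0
        b = rng.standard_normal(20_000)
        assert ev.cohens_d(a, b) == pytest.approx(1.0, abs=0.03)

    def test_constant_groups_rejected(self):
        with pytest.raises(ValidationError):
            ev.cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBehaviourProfile:
    def test_single_behaviour_profile_is_constant_one(self):
        ts = pd.date_range("2015-01-06", periods=48, freq="30min")
        prof = ev.behaviour_profile(ts, ["sleep"] * 48)
        assert (prof["fraction"] == 1.0).all()
        assert set(prof["class"]) == {"sleep"}

    def test_fractions_sum_to_one_per_bin(self):
        rng = np.random.default_rng(4)
        ts = pd.date_range("2015-01-06", periods=500, freq="30s")
        preds = rng.choice(["a", "b", "c"], 500)
        prof = ev.behaviour_profile(ts, preds)
        sums = prof.groupby(["stratum", "bin"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_disjoint_strata_profiles_are_indicators(self):
        ts = pd.date_range("2015-01-06", periods=40, freq="30s")
        preds = ["walk"] * 20 + ["sit"] * 20
        strata = ["young"] * 20 + ["old"] * 20
        prof = ev.behaviour_profile(ts, preds, strata)
        young = prof[prof["stratum"] == "young"]
        assert set(young["class"]) == {"walk"} and (young["fraction"] == 1.0).all()


class TestLoso:
    def test_requires_two_subjects(self, small_cohort):
        with pytest.raises(ValidationError):
            ev.loso_cv(small_cohort[:1])

    def test_fold_bookkeeping_and_pooling(self, small_cohort):
        res = ev.loso_cv(
            small_cohort, ev.EvalConfig(n_trees=20, seed=1, include_met=False)
        )
        assert len(res.per_subject) == len(small_cohort)
        assert np.array_equal(
            res.pooled_confusion, np.sum(res.per_subject_confusion, axis=0)
        )
        total = res.pooled_confusion.sum()
        assert total == res.per_subject["n_epochs"].sum()
        # pooled accuracy = trace / total
        acc = np.trace(res.pooled_confusion) / total
        assert 0.0 <= acc <= 1.0

    def test_separable_two_class_cohort_scores_kappa_one(self):
        """Labels a deterministic function of the signal -> pooled kappa 1."""
        profiles = {
            "sleep": sim.ActivityProfile(
                "sleep", [0.0, 0.0, 1.0], 0.0, 0.0, 0.005, [("sleep", 0.95, 1.0)]
            ),
            "walking": sim.ActivityProfile(
                "walking", [1.0, 0.0, 0.0], 2.0, 0.4, 0.005, [("walking", 3.5, 1.0)]
            ),
        }
        chain = sim.ChainSpec(
            ("sleep", "walking"), [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]]
        )
        cohort = sim.simulate_cohort(3, 0.5, chain=chain, profiles=profiles, seed=8)
        res = ev.loso_cv(cohort, ev.EvalConfig(n_trees=20, seed=2, include_met=False))
        assert res.pooled_kappa_smoothed == pytest.approx(1.0)


def test_minute_level_confusion_totals():
    truth = ["A", "A", "B", "B", "A"]
    pred = ["A", "B", "B", "B", "A"]
    counts = ev.minute_level_confusion(truth, pred, AB)
    assert counts.sum() == 2  # 5 epochs -> 2 whole minutes
    assert counts[0, 0] == 1 and counts[1, 1] == 1
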