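"""HMM: transition estimation, Viterbi and forward-backward vs brute force."""

import itertools

import numpy as np
import pytest

from wristml import hmm as H
from wristml.forest import ClassScheme
from wristml.signal import ValidationError

AB = ClassScheme(("A", "B"))
ABC = ClassScheme(("A", "B", "C"))


def brute_force(model, obs):
    """Exhaustive enumeration oracle: best path and exact marginals."""
    k = model.scheme.k
    n = len(obs)
    best, best_p = None, -1.0
    marg = np.zeros((n, k))
    for path in itertools.product(range(k), repeat=n):
        p = model.initial[path[0]] * model.emission[path[0], obs[0]]
        for t in range(1, n):
            p *= model.transition[path[t - 1], path[t]] * model.emission[path[t], obs[t]]
        for t, s in enumerate(path):
            marg[t, s] += p
        if p > best_p:
            best_p, best = p, np.array(path)
    return best, marg / marg.sum(axis=1, keepdims=True)


class TestEstimateTransitions:
    def test_hand_counted_bigrams(self):
        tm = H.estimate_transitions([np.array([0, 0, 0, 1, 1])], 2)
        assert np.allclose(tm.probs, [[2 / 3, 1 / 3], [0.0, 1.0]])
        assert np.array_equal(tm.counts, [[2, 1], [0, 1]])

    def test_single_class_sequence_gives_identity_row(self):
        tm = H.estimate_transitions([np.zeros(5, dtype=int)], 2)
        assert np.allclose(tm.probs[0], [1.0, 0.0])
        # class B never seen: one-hot on self by convention
        assert np.allclose(tm.probs[1], [0.0, 1.0])

    def test_no_counts_across_subject_boundaries(self):
        tm = H.estimate_transitions([np.array([0, 0]), np.array([1, 1])], 2)
        assert tm.counts[0, 1] == 0
        assert tm.counts[0, 0] == 1 and tm.counts[1, 1] == 1

    def test_all_short_sequences_rejected(self):
        with pytest.raises(ValidationError):
            H.estimate_transitions([np.array([0]), np.array([1])], 2)


def _model(pi, T, E, scheme=AB):
    return H.HmmModel(scheme, np.asarray(pi), np.asarray(T), np.asarray(E))


class TestViterbi:
    def test_identity_emission_returns_observations(self):
        m = _model([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], np.eye(2))
        obs = np.array([0, 1, 1, 0])
        assert np.array_equal(H.viterbi(m, obs), obs)

    def test_blip_is_smoothed_away(self):
        """obs A,B,A decodes to A,A,A under sticky transitions + noisy emissions."""
        m = _model([0.5, 0.5], [[0.99, 0.01], [0.01, 0.99]], [[0.8, 0.2], [0.2, 0.8]])
        assert np.array_equal(H.viterbi(m, [0, 1, 0]), [0, 0, 0])
        # the full 8-path enumeration agrees
        best, _ = brute_force(m, np.array([0, 1, 0]))
        assert np.array_equal(best, [0, 0, 0])

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            m = _model(
                rng.dirichlet(np.ones(3)),
                rng.dirichlet(np.ones(3), 3),
                rng.dirichlet(np.ones(3), 3),
                scheme=ABC,
            )
            obs = rng.integers(0, 3, int(rng.integers(1, 9)))
            best, _ = brute_force(m, obs)
            assert np.array_equal(H.viterbi(m, obs), best)

    def test_forbidden_transitions_never_decoded(self):
        rng = np.random.default_rng(1)
        T = np.array([[0.7, 0.3, 0.0], [0.2, 0.6, 0.2], [0.0, 0.4, 0.6]])
        E = H.floor_emissions(np.eye(3) * 0.8 + 0.1)
        m = _model([1 / 3] * 3, T, E, scheme=ABC)
        for _ in range(20):
            path = H.viterbi(m, rng.integers(0, 3, 50))
            pairs = set(zip(path[:-1], path[1:]))
            assert (0, 2) not in pairs and (2, 0) not in pairs

    def test_viterbi_path_at_least_as_probable_as_raw_observations(self):
        rng = np.random.default_rng(2)
        m = _model(
            [0.4, 0.3, 0.3],
            rng.dirichlet(np.ones(3) * 5, 3),
            H.floor_emissions(np.eye(3) * 0.7 + 0.1),
            scheme=ABC,
        )
        obs = rng.integers(0, 3, 40)
        path = H.viterbi(m, obs)
        assert H.path_log_probability(m, path, obs) >= H.path_log_probability(
            m, obs, obs
        )


class TestForwardBackward:
    def test_marginals_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = _model(
            rng.dirichlet(np.ones(3)),
            rng.dirichlet(np.ones(3), 3),
            rng.dirichlet(np.ones(3), 3),
            scheme=ABC,
        )
        g = H.forward_backward(m, rng.integers(0, 3, 200))
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)

    def test_identity_model_gives_one_hot_marginals(self):
        m = _model([0.5, 0.5], np.eye(2), np.eye(2))
        obs = np.array([1, 1, 1])
        g = H.forward_backward(m, obs)
        assert np.allclose(g, np.eye(2)[obs])

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            m = _model(
                rng.dirichlet(np.ones(3)),
                rng.dirichlet(np.ones(3), 3),
                rng.dirichlet(np.ones(3), 3),
                scheme=ABC,
            )
            obs = rng.integers(0, 3, int(rng.integers(1, 9)))
            _, marg = brute_force(m, obs)
            assert np.abs(H.forward_backward(m, obs) - marg).max() < 1e-10


def test_emission_flooring_preserves_rows_and_support():
    E = np.array([[1.0, 0.0], [0.3, 0.7]])
    out = H.floor_emissions(E)
    assert np.allclose(out.sum(axis=1), 1.0)
    assert (out > 0).all()
    assert out[0, 1] == pytest.approx(H.EMISSION_FLOOR / (1 + H.EMISSION_FLOOR))


def test_build_hmm_keeps_transition_zeros():
    T = H.TransitionMatrix(np.array([[1.0, 0.0], [0.5, 0.5]]), np.zeros((2, 2)))
    m = H.build_hmm(AB, [0.5, 0.5], T, np.eye(2))
    assert m.transition[0, 1] == 0.0
    assert (m.emission > 0).all()
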