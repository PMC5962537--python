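"""Discrete hidden Markov model over behaviour classes.

The hidden state z_t is the true behaviour in epoch t; the observation y_t
is the (noisy) class the balanced random forest predicted.  Transitions
T_ij = p(z_t = c_j | z_{t-1} = c_i) are estimated by counting adjacent
label pairs in training sequences (never across subject boundaries); the
emission distribution p(y_t | z_t) is the forest's out-of-bag confusion
matrix.  Decoding the most probable state path (Viterbi) smooths away
implausible blips — e.g. one epoch of bicycling inside a sleep bout — and
the forward–backward marginals feed MET prediction.

Structural zeros in the transition matrix ("forbidden transitions", pairs
never seen in training) are preserved exactly and can never appear in a
decoded path.  Emission zeros, by contrast, arise from finite out-of-bag
sampling, so they are floored at 1e-6 and the rows renormalised: otherwise
a single unlucky observation would make the whole sequence impossible.
All recursions run in log space with explicit -inf handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import ClassScheme, EmissionMatrix
from .signal import ValidationError

EMISSION_FLOOR = 1e-6


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities with the raw pair counts."""

    probs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(self.probs < 0) or np.any(
            np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValidationError("transition rows must sum to 1")


@dataclass
class HmmModel:
    """Class scheme, initial distribution, transitions and emissions."""

    scheme: ClassScheme
    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        k = self.scheme.k
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        for name, arr, shape in (
            ("initial", self.initial[None, :], (1, k)),
            ("transition", self.transition, (k, k)),
            ("emission", self.emission, (k, k)),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{name} has wrong shape {arr.shape}")
            if np.any(arr < 0) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
                raise ValidationError(f"{name} rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "scheme": list(self.scheme.classes),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            scheme=ClassScheme(tuple(d["scheme"])),
            initial=np.asarray(d["initial"]),
            transition=np.asarray(d["transition"]),
            emission=np.asarray(d["emission"]),
        )


def floor_emissions(emission: np.ndarray, floor: float = EMISSION_FLOOR) -> np.ndarray:
    """Replace zero emission entries with ``floor`` and renormalise rows."""
    e = np.asarray(emission, dtype=np.float64).copy()
    e[e <= 0] = floor
    return e / e.sum(axis=1, keepdims=True)


def empirical_initial(label_sequences: list[np.ndarray], k: int) -> np.ndarray:
    """Initial distribution = empirical class prevalence over all sequences."""
    counts = np.zeros(k)
    for seq in label_sequences:
        counts += np.bincount(np.asarray(seq, dtype=np.intp), minlength=k)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no labels to estimate the initial distribution")
    return counts / total


def estimate_transitions(
    label_sequences: list[np.ndarray], k: int
) -> TransitionMatrix:
    """Count adjacent state pairs within sequences and row-normalise.

    Pairs never cross sequence (subject / wear-bout) boundaries.  A state
    with no outgoing pair gets a one-hot self-transition row; observed
    zeros stay exactly zero — these are the forbidden transitions.
    """
    counts = np.zeros((k, k), dtype=np.int64)
    any_long = False
    for seq in label_sequences:
        seq = np.asarray(seq, dtype=np.intp)
        if len(seq) >= 2:
            any_long = True
            np.add.at(counts, (seq[:-1], seq[1:]), 1)
    if not any_long:
        raise ValidationError("need at least one sequence of length >= 2")
    probs = np.zeros((k, k), dtype=np.float64)
    row_sums = counts.sum(axis=1)
    for i in range(k):
        if row_sums[i] == 0:
            probs[i, i] = 1.0
        else:
            probs[i] = counts[i] / row_sums[i]
    return TransitionMatrix(probs=probs, counts=counts)


def build_hmm(
    scheme: ClassScheme,
    initial: np.ndarray,
    transition: TransitionMatrix | np.ndarray,
    emission: EmissionMatrix | np.ndarray,
    emission_floor: float = EMISSION_FLOOR,
) -> HmmModel:
    """Assemble an HmmModel, flooring emission zeros but not transition zeros."""
    trans = transition.probs if isinstance(transition, TransitionMatrix) else transition
    emit = emission.probs if isinstance(emission, EmissionMatrix) else emission
    return HmmModel(
        scheme=scheme,
        initial=np.asarray(initial, dtype=np.float64),
        transition=np.asarray(trans, dtype=np.float64),
        emission=floor_emissions(emit, emission_floor),
    )


def _check_obs(model: HmmModel, observations) -> np.ndarray:
    obs = np.asarray(observations, dtype=np.intp)
    if obs.ndim != 1:
        raise ValidationError("observations must be a 1-D index sequence")
    if len(obs) and (obs.min() < 0 or obs.max() >= model.scheme.k):
        raise ValidationError("observation index outside the class scheme")
    return obs


def viterbi(model: HmmModel, observations) -> np.ndarray:
    """Most probable hidden-state path given observed predicted classes.

    Log-space dynamic programme; zero probabilities contribute -inf and ties
    break toward the lowest state index at every backtrack step.
    """
    obs = _check_obs(model, observations)
    n, k = len(obs), model.scheme.k
    if n == 0:
        return np.array([], dtype=np.intp)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.initial)
        log_T = np.log(model.transition)
        log_E = np.log(model.emission)
    delta = log_pi + log_E[:, obs[0]]
    psi = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + log_T  # cand[i, j]
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(k)] + log_E[:, obs[t]]
    path = np.empty(n, dtype=np.intp)
    if not np.isfinite(delta.max()):
        raise ValidationError("no state path has positive probability")
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def forward_backward(model: HmmModel, observations) -> np.ndarray:
    """Per-epoch marginal state probabilities p(z_t | y_1..y_n).

    Scaled forward–backward; each returned row sums to 1.
    """
    obs = _check_obs(model, observations)
    n, k = len(obs), model.scheme.k
    if n == 0:
        return np.empty((0, k))
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    scale = np.empty(n)
    alpha[0] = model.initial * model.emission[:, obs[0]]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        raise ValidationError("no state path has positive probability")
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ model.transition) * model.emission[:, obs[t]]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0:
            raise ValidationError("no state path has positive probability")
        alpha[t] /= scale[t]
    # beta is renormalised by its own sum each step: gamma is rescaled per
    # epoch below, so any per-step scalar on beta cancels, and this keeps
    # states with negligible forward mass from overflowing the recursion
    beta[-1] = 1.0 / k
    for t in range(n - 2, -1, -1):
        b = model.transition @ (model.emission[:, obs[t + 1]] * beta[t + 1])
        total = b.sum()
        if total <= 0:
            raise ValidationError("no state path has positive probability")
        beta[t] = b / total
    gamma = alpha * beta
    return gamma / gamma.sum(axis=1, keepdims=True)


def path_log_probability(model: HmmModel, states, observations) -> float:
    """Joint log p(states, observations) under the model (useful invariant)."""
    z = np.asarray(states, dtype=np.intp)
    obs = _check_obs(model, observations)
    with np.errstate(divide="ignore"):
        lp = np.log(model.initial[z[0]]) + np.log(model.emission[z[0], obs[0]])
        lp += np.sum(np.log(model.transition[z[:-1], z[1:]]))
        lp += np.sum(np.log(model.emission[z[1:], obs[1:]]))
    return float(lp)
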