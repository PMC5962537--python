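"""Balanced random forest with out-of-bag emission estimation.

Class imbalance is endemic in free-living behaviour data (sleep dominates,
bicycling is rare).  Instead of bootstrapping N rows per tree, each tree
here trains on a *balanced* bootstrap: n_rare rows drawn with replacement
from every class, where n_rare is the size of the rarest class.  Each tree
additionally sees only a random subspace of floor(sqrt(F)) features, drawn
without replacement (per tree, not per node).

A tree casts a unit (one-hot) vote; forest probabilities are votes
normalised by the number of trees.  Because each tree sees only a fraction
of the data, the rows a tree did NOT train on (its out-of-bag rows) give an
unbiased estimate of the forest's confusion behaviour: the row-normalised
matrix p(predicted class | true class) estimated this way is exactly the
discrete emission distribution the downstream hidden Markov model needs.

CART growth itself (Gini impurity, best-split threshold search at midpoints)
is delegated to scikit-learn; fitted trees are converted to plain arrays at
once and every prediction — in memory or after deserialisation — runs
through the same vectorised traversal in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .signal import ValidationError


@dataclass(frozen=True)
class ClassScheme:
    """Ordered, unique behaviour-class names."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("class names must be unique")
        if len(self.classes) < 2:
            raise ValidationError("a scheme needs at least 2 classes")

    @property
    def k(self) -> int:
        return len(self.classes)

    def encode(self, labels) -> np.ndarray:
        """Map label strings to integer indices, validating membership."""
        lut = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.fromiter(
                (lut[str(l)] for l in labels), dtype=np.intp, count=len(labels)
            )
        except KeyError as err:
            raise ValidationError(f"label {err} not in scheme") from err


@dataclass
class TrainingConfig:
    """Forest training knobs.

    ``features_per_tree`` defaults to floor(sqrt(F)) at fit time; trees grow
    to purity unless ``min_leaf`` stops them earlier.
    """

    n_trees: int = 100
    features_per_tree: int | None = None
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")


@dataclass
class TreeModel:
    """One CART tree as plain arrays.

    ``feature`` holds global feature indices at split nodes and -1 at
    leaves; ``leaf_class`` holds the voted class index at leaves (-1 at
    split nodes).  ``in_bag`` is the multiset of training-row ids the tree
    was fitted on; ``feature_subspace`` the features it was allowed to use.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray
    in_bag: np.ndarray
    feature_subspace: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Vectorised traversal: the voted class index for each row of X."""
        node = np.zeros(len(X), dtype=np.intp)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                break
            idx = np.flatnonzero(active)
            nd = node[idx]
            left = X[idx, feat[idx]] <= self.threshold[nd]
            node[idx] = np.where(
                left, self.children_left[nd], self.children_right[nd]
            )
        return self.leaf_class[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "in_bag": self.in_bag.tolist(),
            "feature_subspace": self.feature_subspace.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.intp),
            children_right=np.asarray(d["children_right"], dtype=np.intp),
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.intp),
            in_bag=np.asarray(d["in_bag"], dtype=np.intp),
            feature_subspace=np.asarray(d["feature_subspace"], dtype=np.intp),
        )


@dataclass
class EmissionMatrix:
    """Row-stochastic p(predicted c_j | true c_i) with per-row support."""

    probs: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("emission rows must sum to 1")


@dataclass
class ForestModel:
    """Ensemble of balanced CART trees over a class scheme."""

    trees: list[TreeModel]
    scheme: ClassScheme
    n_rare: int
    n_features: int
    emission: EmissionMatrix | None = field(default=None)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_dict(self, include_bags: bool = True) -> dict:
        return {
            "scheme": list(self.scheme.classes),
            "n_rare": int(self.n_rare),
            "n_features": int(self.n_features),
            "trees": [
                {**t.to_dict(), **({} if include_bags else {"in_bag": []})}
                for t in self.trees
            ],
            "emission": None
            if self.emission is None
            else {
                "probs": self.emission.probs.tolist(),
                "support": self.emission.support.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        em = d.get("emission")
        return cls(
            trees=[TreeModel.from_dict(t) for t in d["trees"]],
            scheme=ClassScheme(tuple(d["scheme"])),
            n_rare=int(d["n_rare"]),
            n_features=int(d["n_features"]),
            emission=None
            if em is None
            else EmissionMatrix(
                probs=np.asarray(em["probs"]),
                support=np.asarray(em["support"], dtype=np.intp),
            ),
        )


def _convert_tree(
    clf: DecisionTreeClassifier,
    subspace: np.ndarray,
    rows: np.ndarray,
) -> TreeModel:
    t = clf.tree_
    feature = np.where(t.feature >= 0, subspace[np.maximum(t.feature, 0)], -1)
    is_leaf = t.children_left == -1
    # vote = majority class in the leaf; ties resolve to the lowest index
    votes = t.value[:, 0, :]
    leaf_class = np.where(
        is_leaf, clf.classes_[np.argmax(votes, axis=1)], -1
    )
    return TreeModel(
        children_left=t.children_left.astype(np.intp),
        children_right=t.children_right.astype(np.intp),
        feature=feature.astype(np.intp),
        threshold=t.threshold.astype(np.float64),
        leaf_class=leaf_class.astype(np.intp),
        in_bag=np.sort(rows).astype(np.intp),
        feature_subspace=np.sort(subspace).astype(np.intp),
    )


def train_balanced_forest(
    features: np.ndarray,
    labels,
    config: TrainingConfig,
    scheme: ClassScheme,
) -> ForestModel:
    """Fit a balanced random forest.

    Every tree receives a fresh balanced bootstrap — n_rare rows with
    replacement from each class, n_rare being the rarest class's count in
    ``labels`` — and a fresh subspace of ``features_per_tree`` features
    drawn without replacement.  Deterministic for a fixed config seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = scheme.encode(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("features must be (n_rows, F) matching labels")
    if not np.isfinite(X).all():
        raise ValidationError("training features must be finite")
    counts = np.bincount(y, minlength=scheme.k)
    absent = [c for c, n in zip(scheme.classes, counts) if n == 0]
    if absent:
        raise ValidationError(f"scheme class(es) absent from labels: {absent}")
    n_rare = int(counts.min())
    n_feat = X.shape[1]
    m = config.features_per_tree or max(1, int(np.sqrt(n_feat)))
    if not 1 <= m <= n_feat:
        raise ValidationError("features_per_tree out of range")

    class_rows = [np.flatnonzero(y == c) for c in range(scheme.k)]
    rng = np.random.default_rng(config.seed)
    trees: list[TreeModel] = []
    for _ in range(config.n_trees):
        rows = np.concatenate(
            [cr[rng.integers(0, len(cr), size=n_rare)] for cr in class_rows]
        )
        subspace = rng.choice(n_feat, size=m, replace=False)
        clf = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.min_leaf,
            max_features=None,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(X[rows][:, subspace], y[rows])
        trees.append(_convert_tree(clf, subspace, rows))
    return ForestModel(
        trees=trees, scheme=scheme, n_rare=n_rare, n_features=n_feat
    )


def predict_votes(
    model: ForestModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate unit tree votes for each row of X.

    Returns ``(votes, probs, predicted)``: integer votes summing to the
    tree count, probabilities votes/T, and the argmax class index with
    lowest-index tie-break.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    votes = np.zeros((len(X), model.scheme.k), dtype=np.int64)
    rows = np.arange(len(X))
    for tree in model.trees:
        votes[rows, tree.apply(X)] += 1
    probs = votes / model.n_trees
    return votes, probs, np.argmax(votes, axis=1)


def oob_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Per-row votes aggregated only over trees whose bag excludes the row."""
    X = np.asarray(X, dtype=np.float64)
    votes = np.zeros((len(X), model.scheme.k), dtype=np.int64)
    for tree in model.trees:
        mask = np.ones(len(X), dtype=bool)
        mask[tree.in_bag] = False
        if mask.any():
            idx = np.flatnonzero(mask)
            votes[idx, tree.apply(X[idx])] += 1
    return votes


def oob_emission_matrix(
    model: ForestModel, features: np.ndarray, labels
) -> EmissionMatrix:
    """Estimate p(predicted | true) from out-of-bag forest predictions.

    Must be called with the forest's own training data.  Rows with no OOB
    tree are excluded (with a warning); a true class losing all its rows
    that way raises — grow more trees.
    """
    y = model.scheme.encode(labels)
    votes = oob_votes(model, features)
    covered = votes.sum(axis=1) > 0
    n_dropped = int((~covered).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} row(s) had no out-of-bag tree and were excluded "
            "from emission estimation",
            stacklevel=2,
        )
    pred = np.argmax(votes, axis=1)
    k = model.scheme.k
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y[covered], pred[covered]), 1)
    support = counts.sum(axis=1)
    empty = [model.scheme.classes[i] for i in np.flatnonzero(support == 0)]
    if empty:
        raise ValidationError(
            f"no out-of-bag coverage for class(es) {empty}; increase n_trees"
        )
    probs = counts / support[:, None]
    return EmissionMatrix(probs=probs, support=support)
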