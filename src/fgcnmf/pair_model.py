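"""Node-pair features, negative sampling, classifier backends, ranking.

A (microbe, disease) pair is represented by combining the two nodes' final
embedding rows (concatenation by default).  Unobserved pairs are treated as
unlabeled and sampled uniformly as negatives.  Seven classifier backends are
supported; extremely randomized trees is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .graph import AssociationMatrix
from .mf import EmbeddingMatrix

__all__ = [
    "PAIR_OPS",
    "CLASSIFIERS",
    "ClassifierSpec",
    "TrainedModel",
    "pair_features",
    "sample_negatives",
    "train",
    "rank_candidates",
]

PAIR_OPS = ("concat", "hadamard", "mean")

CLASSIFIERS = (
    "extra_trees",
    "random_forest",
    "xgboost",
    "gbdt",
    "adaboost",
    "svm",
    "logistic_regression",
)


@dataclass
class ClassifierSpec:
    """Which classifier backend to train, with hyperparameters and seed."""

    algorithm: str = "extra_trees"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.algorithm!r}; choose from {CLASSIFIERS}"
            )


@dataclass
class TrainedModel:
    """A fitted classifier scoring pair features with P(association)."""

    spec: ClassifierSpec
    estimator: object
    feature_dim: int

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dim {features.shape[1]} != trained dim {self.feature_dim}"
            )
        return self.estimator.predict_proba(features)[:, 1]


def pair_features(
    F: EmbeddingMatrix,
    pairs,
    n_m: int,
    pair_op: str = "concat",
) -> np.ndarray:
    """Feature matrix for (microbe_index, disease_index) pairs.

    Disease rows are addressed at offset ``n_m`` in the node-ordered
    embedding.  ``concat`` yields 2d-length features [microbe || disease];
    ``hadamard`` and ``mean`` are elementwise alternatives of length d.
    """
    if pair_op not in PAIR_OPS:
        raise ValueError(f"unknown pair_op {pair_op!r}")
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
    n_nodes = F.vectors.shape[0]
    if pairs.size and (
        pairs[:, 0].min() < 0
        or pairs[:, 0].max() >= n_m
        or pairs[:, 1].min() < 0
        or pairs[:, 1].max() >= n_nodes - n_m
    ):
        raise IndexError("pair index out of range")
    m_rows = F.vectors[pairs[:, 0]]
    d_rows = F.vectors[n_m + pairs[:, 1]]
    if pair_op == "concat":
        return np.hstack([m_rows, d_rows])
    if pair_op == "hadamard":
        return m_rows * d_rows
    return (m_rows + d_rows) / 2.0


def sample_negatives(
    MD: AssociationMatrix,
    n_neg: int,
    seed: int,
    exclude=(),
) -> list[tuple[int, int]]:
    """Uniform sample of unlabeled (MD == 0) pairs, without replacement.

    ``exclude`` removes already-claimed pairs (e.g. another split's
    negatives) from the candidate pool.  Deterministic for a fixed seed.
    """
    exclude = set(map(tuple, exclude))
    zi, zj = np.nonzero(MD.values == 0)
    candidates = [(int(i), int(j)) for i, j in zip(zi, zj) if (i, j) not in exclude]
    if n_neg > len(candidates):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} unlabeled "
            "pairs are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    return [candidates[i] for i in chosen]


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.algorithm == "extra_trees":
        hp.setdefault("n_estimators", 200)
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "xgboost":
        hp.setdefault("n_estimators", 200)
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **hp
        )
    if spec.algorithm == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.algorithm == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if spec.algorithm == "logistic_regression":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **hp)
    raise ValueError(spec.algorithm)  # unreachable; spec validates


def train(features: np.ndarray, labels, spec: ClassifierSpec) -> TrainedModel:
    """Fit the requested classifier on labeled pair features."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    est = _build_estimator(spec)
    est.fit(features, labels)
    return TrainedModel(spec=spec, estimator=est, feature_dim=features.shape[1])


def rank_candidates(
    model: TrainedModel,
    F: EmbeddingMatrix,
    disease_index: int,
    known: AssociationMatrix,
    top_k: int,
    pair_op: str = "concat",
) -> list[tuple[str, float]]:
    """Top-k novel microbe candidates for one disease.

    Scores every microbe against the disease, drops pairs already known,
    and returns (microbe_id, score) sorted by descending score with ties
    broken by ascending microbe index.
    """
    n_m = known.n_microbes
    if not 0 <= disease_index < known.n_diseases:
        raise IndexError(f"disease index {disease_index} out of range")
    candidates = [m for m in range(n_m) if known.values[m, disease_index] == 0]
    if not candidates:
        return []
    feats = pair_features(F, [(m, disease_index) for m in candidates], n_m, pair_op)
    scores = model.predict_scores(feats)
    if top_k > len(candidates):
        warnings.warn(
            f"top_k={top_k} exceeds {len(candidates)} candidates; returning all",
            stacklevel=2,
        )
    order = sorted(range(len(candidates)), key=lambda i: (-scores[i], candidates[i]))
    return [
        (known.microbe_ids[candidates[i]], float(scores[i])) for i in order[:top_k]
    ]
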