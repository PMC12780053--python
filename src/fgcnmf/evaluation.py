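"""Leakage-safe repeated k-fold cross-validation with 1:1 negative sampling.

Known links are partitioned into k folds.  For each fold the test links are
removed from the association matrix *before* the network is assembled, so
the whole embedding pipeline (proximity matrix, randomized SVD, propagation)
sees only training links; an assertion verifies that no test edge reaches
the adjacency.  Train and test negatives are drawn disjointly from the
unlabeled pairs, 1:1 with the positives on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig, derive_seed
from .graph import AssociationMatrix, RawSimilarity, assemble_network, sparsify_topn
from .mf import EmbeddingMatrix, build_proximity, initial_embedding, randomized_svd
from .pair_model import ClassifierSpec, pair_features, sample_negatives, train
from .propagation import enhance

__all__ = [
    "Dataset",
    "FoldSplit",
    "CVResult",
    "build_embedding",
    "make_folds",
    "make_fold_splits",
    "run_fold",
    "auc",
    "aupr",
    "repeat_cv",
]


@dataclass
class Dataset:
    """Raw similarities plus the binary association matrix."""

    sim_m: RawSimilarity
    sim_d: RawSimilarity
    MD: AssociationMatrix

    def positives(self) -> list[tuple[int, int]]:
        pi, pj = np.nonzero(self.MD.values == 1)
        return [(int(i), int(j)) for i, j in zip(pi, pj)]


@dataclass
class FoldSplit:
    """One fold's positive/negative train-test partition (index pairs)."""

    fold_id: int
    train_positives: list[tuple[int, int]]
    test_positives: list[tuple[int, int]]
    train_negatives: list[tuple[int, int]]
    test_negatives: list[tuple[int, int]]


@dataclass
class CVResult:
    """Raw per-repeat, per-fold metrics plus repeat-level summaries.

    ``auc_folds`` and ``aupr_folds`` have shape (n_repeats, k_folds); the
    summary is mean +/- sample std of the fold-averaged metric across
    repeats (std reported as 0 with ``single_repeat`` set when there is
    only one repeat).
    """

    auc_folds: np.ndarray
    aupr_folds: np.ndarray
    base_seed: int

    @property
    def n_repeats(self) -> int:
        return self.auc_folds.shape[0]

    @property
    def single_repeat(self) -> bool:
        return self.n_repeats == 1

    def _summary(self, folds: np.ndarray) -> tuple[float, float]:
        per_repeat = folds.mean(axis=1)
        std = 0.0 if self.single_repeat else float(per_repeat.std(ddof=1))
        return float(per_repeat.mean()), std

    @property
    def auc_mean(self) -> float:
        return self._summary(self.auc_folds)[0]

    @property
    def auc_std(self) -> float:
        return self._summary(self.auc_folds)[1]

    @property
    def aupr_mean(self) -> float:
        return self._summary(self.aupr_folds)[0]

    @property
    def aupr_std(self) -> float:
        return self._summary(self.aupr_folds)[1]

    def to_dict(self) -> dict:
        return {
            "base_seed": self.base_seed,
            "n_repeats": self.n_repeats,
            "k_folds": self.auc_folds.shape[1],
            "single_repeat": self.single_repeat,
            "auc_folds": self.auc_folds.tolist(),
            "aupr_folds": self.aupr_folds.tolist(),
            "summary": {
                "auc_mean": self.auc_mean,
                "auc_std": self.auc_std,
                "aupr_mean": self.aupr_mean,
                "aupr_std": self.aupr_std,
            },
        }


def build_embedding(
    sim_m: RawSimilarity,
    sim_d: RawSimilarity,
    MD: AssociationMatrix,
    config: RunConfig,
    seed: int,
):
    """Run the embedding pipeline on one association matrix.

    Sparsifies the similarities, assembles the network, builds the proximity
    matrix, factorizes it and propagates; returns (network, final embedding).
    """
    SM = sparsify_topn(sim_m, config.top_n)
    SD = sparsify_topn(sim_d, config.top_n)
    net = assemble_network(SM, SD, MD)
    prox = build_proximity(
        net,
        neg_exponent=config.neg_exponent,
        clip_nonnegative=config.clip_nonnegative,
    )
    fact = randomized_svd(
        prox,
        d=config.dim,
        seed=seed,
        oversample=config.oversample,
        power_iters=config.power_iters,
    )
    F0 = initial_embedding(fact, net.node_ids)
    F = enhance(net, F0, config.layers, include_layer0=config.include_layer0)
    return net, F


def make_folds(positives, k: int, seed: int) -> list[list[tuple[int, int]]]:
    """Seeded partition of the positive pairs into k near-equal folds."""
    positives = [tuple(p) for p in positives]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(positives):
        raise ValueError(f"k={k} exceeds {len(positives)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    return [
        [positives[i] for i in chunk] for chunk in np.array_split(order, k)
    ]


def make_fold_splits(
    MD: AssociationMatrix, k: int, seed: int, neg_ratio: float = 1.0
) -> list[FoldSplit]:
    """Fold partitions with disjoint per-fold negative samples."""
    pi, pj = np.nonzero(MD.values == 1)
    positives = [(int(i), int(j)) for i, j in zip(pi, pj)]
    folds = make_folds(positives, k, seed)
    splits = []
    for fold_id, test_pos in enumerate(folds):
        train_pos = [p for p in positives if p not in set(test_pos)]
        n_test = len(test_pos)
        n_train = int(round(neg_ratio * len(train_pos)))
        neg_seed = derive_seed(seed, 1, fold_id)
        combined = sample_negatives(MD, n_test + n_train, neg_seed)
        splits.append(
            FoldSplit(
                fold_id=fold_id,
                train_positives=train_pos,
                test_positives=list(test_pos),
                train_negatives=combined[n_test:],
                test_negatives=combined[:n_test],
            )
        )
    return splits


def auc(scores, labels) -> float:
    """ROC AUC with the midrank tie convention.

    Equals P(score+ > score-) + 0.5 P(score+ = score-) over all
    positive-negative pairs.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (descending-score sweep,
    ties grouped, step integration without trapezoids)."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def run_fold(
    dataset: Dataset,
    fold: FoldSplit,
    config: RunConfig,
    seed: int = 0,
    leak_test_edges: bool = False,
    embedding_transform=None,
) -> tuple[float, float]:
    """Train on one fold's training graph and score its held-out pairs.

    The test positives are zeroed out of the association matrix before any
    network construction; an assertion confirms none of them contributes an
    edge to the adjacency used for embedding.  ``leak_test_edges`` is a
    test-only hook that deliberately skips the removal so the leakage trap
    can be exercised; ``embedding_transform`` (test-only) maps the final
    embedding before features are built.
    """
    md_train = dataset.MD.values.copy()
    if not leak_test_edges:
        for i, j in fold.test_positives:
            md_train[i, j] = 0
    MD_train = AssociationMatrix(
        dataset.MD.microbe_ids, dataset.MD.disease_ids, md_train
    )
    net, F = build_embedding(dataset.sim_m, dataset.sim_d, MD_train, config, seed)
    n_m = net.n_m
    if not leak_test_edges:
        for i, j in fold.test_positives:
            if net.H[i, n_m + j] != 0:
                raise AssertionError(
                    f"leakage: test link ({i}, {j}) present in the training adjacency"
                )
    if embedding_transform is not None:
        F = embedding_transform(F)

    train_pairs = fold.train_positives + fold.train_negatives
    train_labels = [1] * len(fold.train_positives) + [0] * len(fold.train_negatives)
    test_pairs = fold.test_positives + fold.test_negatives
    test_labels = [1] * len(fold.test_positives) + [0] * len(fold.test_negatives)

    X_train = pair_features(F, train_pairs, n_m, config.pair_op)
    X_test = pair_features(F, test_pairs, n_m, config.pair_op)
    spec = ClassifierSpec(algorithm=config.classifier, seed=derive_seed(seed, 2))
    model = train(X_train, train_labels, spec)
    scores = model.predict_scores(X_test)
    return auc(scores, test_labels), aupr(scores, test_labels)


def repeat_cv(
    dataset: Dataset,
    config: RunConfig,
    n_repeats: int,
    base_seed: int,
) -> CVResult:
    """Repeat k-fold CV with seeds base_seed .. base_seed + n_repeats - 1."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    k = config.k_folds
    aucs = np.zeros((n_repeats, k))
    auprs = np.zeros((n_repeats, k))
    for r in range(n_repeats):
        seed_r = base_seed + r
        splits = make_fold_splits(dataset.MD, k, seed_r, config.neg_ratio)
        for f, fold in enumerate(splits):
            fold_seed = derive_seed(seed_r, 3, f)
            aucs[r, f], auprs[r, f] = run_fold(dataset, fold, config, seed=fold_seed)
    return CVResult(auc_folds=aucs, aupr_folds=auprs, base_seed=base_seed)
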