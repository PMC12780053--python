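"""Model/Results interface over the embedding + classification pipeline.

``FGCNMFModel`` is built from an association matrix and the two
within-space similarity matrices; ``fit`` runs the full pipeline on all
known links (sparsify, assemble, factorize, propagate, train a classifier
on positives plus 1:1 sampled negatives) and returns an ``FGCNMFResults``
that scores arbitrary pairs, ranks novel candidates per disease, and
prints a summary.  ``cross_validate`` runs the leakage-safe repeated
k-fold protocol and returns its raw and summarized metrics.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig, derive_seed
from .evaluation import CVResult, Dataset, build_embedding, repeat_cv
from .graph import AssociationMatrix, RawSimilarity, density_stats
from .mf import EmbeddingMatrix
from .pair_model import (
    ClassifierSpec,
    TrainedModel,
    pair_features,
    rank_candidates,
    sample_negatives,
    train,
)

__all__ = ["FGCNMFModel", "FGCNMFResults"]


class FGCNMFModel:
    """Link-prediction model for a microbe-disease association network.

    Parameters
    ----------
    association : AssociationMatrix
        Binary microbe x disease matrix of known links.
    microbe_similarity, disease_similarity : RawSimilarity
        Within-space similarity matrices; sparsified to top-n neighbor
        graphs during fitting.
    config : RunConfig, optional
        Pipeline hyperparameters (defaults to the HM-style setting).
    """

    def __init__(
        self,
        association: AssociationMatrix,
        microbe_similarity: RawSimilarity,
        disease_similarity: RawSimilarity,
        config: RunConfig | None = None,
    ):
        if microbe_similarity.entity_ids != association.microbe_ids:
            raise ValueError("microbe similarity ids do not match association rows")
        if disease_similarity.entity_ids != association.disease_ids:
            raise ValueError("disease similarity ids do not match association columns")
        self.association = association
        self.microbe_similarity = microbe_similarity
        self.disease_similarity = disease_similarity
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, assoc_path, sim_m_path, sim_d_path, config=None):
        """Build a model from the TSV/CSV dialects on disk."""
        from .io import read_association, read_similarity

        MD = read_association(assoc_path)
        sim_m = read_similarity(sim_m_path)
        sim_d = read_similarity(sim_d_path)
        sim_m = RawSimilarity(
            MD.microbe_ids, _reindex(sim_m, MD.microbe_ids)
        )
        sim_d = RawSimilarity(
            MD.disease_ids, _reindex(sim_d, MD.disease_ids)
        )
        return cls(MD, sim_m, sim_d, config)

    @property
    def dataset(self) -> Dataset:
        return Dataset(self.microbe_similarity, self.disease_similarity, self.association)

    def fit(self, seed: int | None = None) -> "FGCNMFResults":
        """Run the full pipeline on all known links and train the classifier."""
        seed = self.config.seed if seed is None else seed
        net, F = build_embedding(
            self.microbe_similarity,
            self.disease_similarity,
            self.association,
            self.config,
            derive_seed(seed, 0),
        )
        pos = list(zip(*np.nonzero(self.association.values == 1)))
        pos = [(int(i), int(j)) for i, j in pos]
        n_neg = int(round(self.config.neg_ratio * len(pos)))
        neg = sample_negatives(self.association, n_neg, derive_seed(seed, 1))
        X = pair_features(F, pos + neg, net.n_m, self.config.pair_op)
        y = [1] * len(pos) + [0] * len(neg)
        spec = ClassifierSpec(
            algorithm=self.config.classifier, seed=derive_seed(seed, 2)
        )
        clf = train(X, y, spec)
        return FGCNMFResults(self, net, F, clf, seed)

    def cross_validate(
        self, n_repeats: int | None = None, seed: int | None = None
    ) -> CVResult:
        """Leakage-safe repeated k-fold cross-validation."""
        n_repeats = self.config.repeats if n_repeats is None else n_repeats
        seed = self.config.seed if seed is None else seed
        return repeat_cv(self.dataset, self.config, n_repeats, seed)


def _reindex(sim: RawSimilarity, ids: list[str]) -> np.ndarray:
    index = {e: i for i, e in enumerate(sim.entity_ids)}
    missing = [e for e in ids if e not in index]
    if missing:
        raise ValueError(f"similarity matrix missing ids: {missing[:5]}")
    order = [index[e] for e in ids]
    return sim.values[np.ix_(order, order)]


class FGCNMFResults:
    """Fitted pipeline: network, final embeddings and trained classifier."""

    def __init__(self, model, network, embedding: EmbeddingMatrix,
                 classifier: TrainedModel, seed: int):
        self.model = model
        self.network = network
        self.embedding = embedding
        self.classifier = classifier
        self.seed = seed

    def predict(self, pairs) -> np.ndarray:
        """Association scores in [0, 1] for (microbe_index, disease_index) pairs."""
        X = pair_features(
            self.embedding, pairs, self.network.n_m, self.model.config.pair_op
        )
        return self.classifier.predict_scores(X)

    def predict_ids(self, id_pairs) -> np.ndarray:
        """Association scores for (microbe_id, disease_id) string pairs."""
        m_index = {e: i for i, e in enumerate(self.model.association.microbe_ids)}
        d_index = {e: i for i, e in enumerate(self.model.association.disease_ids)}
        return self.predict([(m_index[a], d_index[b]) for a, b in id_pairs])

    def rank_candidates(self, disease, top_k: int = 20):
        """Top-k novel microbe candidates for a disease (id or index),
        known links filtered out."""
        if isinstance(disease, str):
            disease = self.model.association.disease_ids.index(disease)
        return rank_candidates(
            self.classifier,
            self.embedding,
            disease,
            self.model.association,
            top_k,
            self.model.config.pair_op,
        )

    def summary(self) -> str:
        """Plain-text summary of the data, configuration and fitted state."""
        cfg = self.model.config
        stats = density_stats(self.model.association)
        lines = [
            "FGCNMF link-prediction results",
            "=" * 46,
            f"{'microbes':<28}{stats['n_microbes']:>18}",
            f"{'diseases':<28}{stats['n_diseases']:>18}",
            f"{'known links':<28}{stats['n_links']:>18}",
            f"{'sparseness':<28}{stats['sparseness']:>18.4f}",
            f"{'network edges (H nnz)':<28}{self.network.H.nnz:>18}",
            "-" * 46,
            f"{'top-n neighbors':<28}{cfg.top_n:>18}",
            f"{'embedding dim d':<28}{cfg.dim:>18}",
            f"{'propagation layers l':<28}{cfg.layers:>18}",
            f"{'pair operator':<28}{cfg.pair_op:>18}",
            f"{'classifier':<28}{cfg.classifier:>18}",
            f"{'seed':<28}{self.seed:>18}",
            "=" * 46,
        ]
        return "\n".join(lines)
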