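"""Run configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .pair_model import CLASSIFIERS, PAIR_OPS

__all__ = ["RunConfig", "derive_seed"]


@dataclass
class RunConfig:
    """Hyperparameters for the full pipeline.

    Defaults follow the HM-style setting: top_n=5 similarity neighbors,
    d=32 embedding dimensions, l=3 propagation layers, 5-fold CV repeated
    30 times with 1:1 negative sampling and an extra-trees classifier.
    The pair operator defaults to the Hadamard (elementwise) product of the
    two nodes' embeddings: SVD embeddings are defined only up to rotation,
    so the cross-space signal lives in vector alignment, which the product
    exposes to axis-aligned tree splits; raw concatenation is also
    available but degrades tree ensembles at curated-dataset sample sizes.
    """

    top_n: int = 5
    dim: int = 32
    layers: int = 3
    pair_op: str = "hadamard"
    classifier: str = "extra_trees"
    neg_ratio: float = 1.0
    seed: int = 0
    oversample: int = 0
    power_iters: int = 0
    include_layer0: bool = False
    clip_nonnegative: bool = False
    neg_exponent: float = 1.0
    repeats: int = 30
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.pair_op not in PAIR_OPS:
            raise ValueError(f"pair_op must be one of {PAIR_OPS}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.oversample < 0 or self.power_iters < 0:
            raise ValueError("oversample and power_iters must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic sub-seed for a pipeline stage.

    All randomness in a run flows from one base seed; each stage (and each
    repeat/fold within it) gets an independent stream keyed by its indices.
    """
    ss = np.random.SeedSequence([int(base_seed) % (2**31), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2**31))
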