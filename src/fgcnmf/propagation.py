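"""Parameter-free spatial convolution over the normalized adjacency.

Each round multiplies the embedding by Hhat = D^{-1/2} H D^{-1/2}; the final
representation averages the l propagated layers, which mixes neighborhood
smoothing at several radii and mitigates over-smoothing without any
trainable weights.
"""

from __future__ import annotations

import numpy as np

from .graph import HeteroNetwork
from .mf import EmbeddingMatrix

__all__ = ["propagate_once", "enhance"]


def propagate_once(net: HeteroNetwork, F_in: EmbeddingMatrix) -> EmbeddingMatrix:
    """One propagation round: returns Hhat @ F_in.

    Rows of isolated nodes come out all-zero (their normalized degree is
    treated as a pseudo-inverse).
    """
    if F_in.vectors.shape[0] != net.n_nodes:
        raise ValueError(
            f"embedding has {F_in.vectors.shape[0]} rows, network has {net.n_nodes} nodes"
        )
    out = net.H_norm @ F_in.vectors
    return EmbeddingMatrix(F_in.node_ids, out, layer_tag="propagated")


def enhance(
    net: HeteroNetwork,
    F0: EmbeddingMatrix,
    l: int,
    include_layer0: bool = False,
) -> EmbeddingMatrix:
    """Average of the l propagated layers F(k) = Hhat^k F0, k = 1..l.

    F0 itself is excluded from the average unless ``include_layer0`` is set,
    in which case layers 0..l are averaged over l+1 terms.
    """
    if l < 1:
        raise ValueError("number of propagation layers must be >= 1")
    if F0.vectors.shape[0] != net.n_nodes:
        raise ValueError("embedding row count does not match network size")
    acc = F0.vectors.copy() if include_layer0 else np.zeros_like(F0.vectors)
    cur = F0.vectors
    for _ in range(l):
        cur = net.H_norm @ cur
        acc += cur
    n_terms = l + 1 if include_layer0 else l
    return EmbeddingMatrix(F0.node_ids, acc / n_terms, layer_tag="final")
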