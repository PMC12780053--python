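"""Readers and writers for the package's plain-text (TSV/CSV/YAML) dialects.

All artifacts are text: association lists are two-column TSV, similarity
matrices are labelled square TSV/CSV, networks are sparse triplet TSV plus a
node table, embeddings are one node per row.  Ids are opaque UTF-8 strings.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .config import RunConfig
from .graph import AssociationMatrix, HeteroNetwork, RawSimilarity
from .mf import EmbeddingMatrix

__all__ = [
    "read_association",
    "write_association",
    "read_similarity",
    "write_similarity",
    "write_network",
    "read_network",
    "read_embedding",
    "write_embedding",
    "load_config",
]

log = logging.getLogger("fgcnmf")

_HEADER_TOKENS = {"microbe_id", "microbe", "disease_id", "disease", "drug_id", "drug"}


def read_association(path) -> AssociationMatrix:
    """Read a two-column `microbe_id<TAB>disease_id` link list.

    Ids are ordered by first appearance; duplicate links collapse to a
    single 1 with a warning.  An optional header row is recognized by its
    column names.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed association row {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a.lower() in _HEADER_TOKENS:
                continue
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path}: no association rows")
    microbe_ids: list[str] = []
    disease_ids: list[str] = []
    m_index: dict[str, int] = {}
    d_index: dict[str, int] = {}
    for a, b in pairs:
        if a not in m_index:
            m_index[a] = len(microbe_ids)
            microbe_ids.append(a)
        if b not in d_index:
            d_index[b] = len(disease_ids)
            disease_ids.append(b)
    values = np.zeros((len(microbe_ids), len(disease_ids)), dtype=np.int8)
    n_dup = 0
    for a, b in pairs:
        if values[m_index[a], d_index[b]]:
            n_dup += 1
        values[m_index[a], d_index[b]] = 1
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate link(s) collapsed", stacklevel=2)
    return AssociationMatrix(microbe_ids, disease_ids, values)


def write_association(MD: AssociationMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("microbe_id\tdisease_id\n")
        for i, j in zip(*np.nonzero(MD.values == 1)):
            fh.write(f"{MD.microbe_ids[i]}\t{MD.disease_ids[j]}\n")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_similarity(path) -> RawSimilarity:
    """Read a labelled square similarity matrix (TSV or CSV by extension).

    Row and column ids must match; a non-symmetric matrix is symmetrized as
    (S + S^T)/2 with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    ids_row = [str(i) for i in df.index]
    ids_col = [str(c) for c in df.columns]
    if ids_row != ids_col:
        raise ValueError(f"{path}: row ids do not match column ids")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square")
    if not np.allclose(values, values.T, atol=1e-12):
        warnings.warn(f"{path}: matrix not symmetric; averaging with transpose",
                      stacklevel=2)
        values = (values + values.T) / 2.0
    return RawSimilarity(ids_row, values)


def write_similarity(S: RawSimilarity, path) -> None:
    path = Path(path)
    df = pd.DataFrame(S.values, index=S.entity_ids, columns=S.entity_ids)
    df.to_csv(path, sep=_sep_for(path), float_format="%.12g")


def write_network(net: HeteroNetwork, out_dir) -> None:
    """Write a network as sparse triplet TSVs plus a typed node table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "nodes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("node_id\tnode_type\tdegree\n")
        for idx, node in enumerate(net.node_ids):
            kind = "microbe" if idx < net.n_m else "disease"
            fh.write(f"{node}\t{kind}\t{int(net.D[idx])}\n")
    coo = net.H.tocoo()
    with (out_dir / "adjacency.tsv").open("w", encoding="utf-8") as fh:
        fh.write("row\tcol\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def read_network(net_dir) -> HeteroNetwork:
    """Rebuild a HeteroNetwork from the triplet/nodes files."""
    from .graph import HeteroNetwork  # local to keep the namespace tight

    net_dir = Path(net_dir)
    nodes = pd.read_csv(net_dir / "nodes.tsv", sep="\t", dtype={"node_id": str})
    node_ids = nodes["node_id"].tolist()
    n_m = int((nodes["node_type"] == "microbe").sum())
    n_d = len(node_ids) - n_m
    trip = pd.read_csv(net_dir / "adjacency.tsv", sep="\t")
    n = len(node_ids)
    H = sp.csr_matrix(
        (trip["value"].to_numpy(float), (trip["row"].to_numpy(int), trip["col"].to_numpy(int))),
        shape=(n, n),
    )
    D = np.asarray(H.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_inv = np.where(D > 0, 1.0 / np.sqrt(np.where(D > 0, D, 1.0)), 0.0)
    Dinv = sp.diags(d_inv)
    return HeteroNetwork(node_ids, H, D, (Dinv @ H @ Dinv).tocsr(), n_m, n_d)


def write_embedding(F: EmbeddingMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for node, row in zip(F.node_ids, F.vectors):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{node}\t{vals}\n")


def read_embedding(path, layer_tag: str = "final") -> EmbeddingMatrix:
    path = Path(path)
    node_ids: list[str] = []
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            node_ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    return EmbeddingMatrix(node_ids, np.array(rows, dtype=float), layer_tag=layer_tag)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config, apply keyword overrides, log the config hash."""
    data: dict = {}
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig.from_dict(data)
    log.info("config hash %s: %s", cfg.config_hash(), cfg.to_dict())
    return cfg
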