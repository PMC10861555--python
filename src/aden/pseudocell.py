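"""Micropooling: partition a cell neighbor graph into pseudocells.

Single-nucleus ATAC (and to a lesser degree RNA) matrices are extremely
sparse; averaging small neighborhoods of cells ("pseudocells") before
stage-1 regression trades a little resolution for much better-conditioned
responses. Cells are first grouped into communities by Louvain modularity
clustering of the supplied joint neighbor graph (or of a kNN graph built
from a low-dimensional embedding), then each community is split by
k-means into ceil(size / target_size) pools, so no pseudocell ever mixes
communities. Typical targets: 10 cells for RNA, 100 for ATAC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from .containers import OmicsMatrix

__all__ = ["PseudocellAssignment", "build_pseudocells", "aggregate"]


@dataclass
class PseudocellAssignment:
    assignment: dict[str, str]  # cell_id -> pseudocell_id
    sizes: dict[str, int]
    target_size: int
    seed: int
    communities: dict[str, int] | None = None  # cell_id -> community label

    def __post_init__(self):
        counts: dict[str, int] = {}
        for pc in self.assignment.values():
            counts[pc] = counts.get(pc, 0) + 1
        if counts != self.sizes:
            raise ValueError("sizes inconsistent with assignment")

    @property
    def n_pseudocells(self) -> int:
        return len(self.sizes)

    @property
    def pseudocell_ids(self) -> list[str]:
        # numeric-suffix order so target_size=1 reproduces the input order
        return sorted(self.sizes, key=lambda s: (len(s), s))


def _knn_graph_from_embedding(embedding: np.ndarray, k: int) -> sparse.csr_matrix:
    k = min(k, embedding.shape[0] - 1)
    adj = kneighbors_graph(embedding, n_neighbors=max(k, 1), mode="distance")
    # similarity weights, symmetrized
    adj.data = 1.0 / (1.0 + adj.data)
    return adj.maximum(adj.T)


def build_pseudocells(cell_ids: list[str], *, graph=None, embedding=None,
                      target_size: int = 10, seed: int = 0,
                      knn: int = 20) -> PseudocellAssignment:
    """Assign every cell to a pseudocell of roughly ``target_size`` members.

    Parameters
    ----------
    graph : (n, n) weighted adjacency (sparse or dense), optional
        Joint neighbor graph over ``cell_ids``. If absent, a kNN graph
        (``knn`` neighbors) is built from ``embedding``.
    embedding : (n, d) array, optional
        Low-dimensional coordinates used for the within-community k-means
        split. If only a graph is given, a spectral embedding of the graph
        stands in.

    Deterministic for a fixed seed.
    """
    n = len(cell_ids)
    if n == 0:
        raise ValueError("no cells")
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if graph is None and embedding is None:
        raise ValueError("need a graph or an embedding")

    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape[0] != n:
            raise ValueError("embedding does not cover all cells")
    if graph is None:
        adj = _knn_graph_from_embedding(embedding, knn)
    else:
        adj = sparse.csr_matrix(graph)
        if adj.shape != (n, n):
            raise ValueError("graph does not cover all cells")

    if target_size == 1:
        assignment = {c: f"pc{idx}" for idx, c in enumerate(cell_ids)}
        return PseudocellAssignment(
            assignment=assignment,
            sizes={pc: 1 for pc in assignment.values()},
            target_size=1, seed=seed,
            communities={c: 0 for c in cell_ids},
        )

    g = nx.from_scipy_sparse_array(adj)
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])

    if embedding is None:
        # coordinates for k-means: spectral embedding of the graph
        from sklearn.manifold import SpectralEmbedding
        dim = min(10, n - 2) if n > 2 else 1
        embedding = SpectralEmbedding(
            n_components=max(dim, 1), affinity="precomputed",
            random_state=seed,
        ).fit_transform(adj.toarray())

    assignment: dict[str, str] = {}
    communities: dict[str, int] = {}
    pc_counter = 0
    for ci, members in enumerate(comms):
        for m in members:
            communities[cell_ids[m]] = ci
        k = math.ceil(len(members) / target_size)
        if k <= 1 or len(members) <= 1:
            labels = np.zeros(len(members), dtype=int)
            k = 1
        else:
            km = KMeans(n_clusters=k, init="k-means++", n_init=5,
                        random_state=seed + ci)
            labels = km.fit_predict(embedding[members])
        for m, lab in zip(members, labels):
            assignment[cell_ids[m]] = f"pc{pc_counter + lab}"
        pc_counter += k

    # k-means may leave a cluster empty; compact ids so sizes are exact
    used = sorted({pc for pc in assignment.values()},
                  key=lambda s: int(s[2:]))
    remap = {pc: f"pc{idx}" for idx, pc in enumerate(used)}
    assignment = {c: remap[pc] for c, pc in assignment.items()}
    sizes: dict[str, int] = {}
    for pc in assignment.values():
        sizes[pc] = sizes.get(pc, 0) + 1
    return PseudocellAssignment(assignment=assignment, sizes=sizes,
                                target_size=target_size, seed=seed,
                                communities=communities)


def aggregate(matrix: OmicsMatrix, assignment: PseudocellAssignment) -> OmicsMatrix:
    """Average member rows within each pseudocell.

    The output's cell ids are the pseudocell ids (sorted); the
    size-weighted mean of the output rows equals the global cell mean.
    """
    missing = [c for c in matrix.cell_ids if c not in assignment.assignment]
    if missing:
        raise ValueError(f"cells not covered by assignment: {missing[:5]}")
    pc_ids = assignment.pseudocell_ids
    pc_pos = {pc: i for i, pc in enumerate(pc_ids)}
    rows = np.array(
        [pc_pos[assignment.assignment[c]] for c in matrix.cell_ids]
    )
    n_pc = len(pc_ids)
    # pooling matrix P (n_pc x n_cells) with 1/size entries
    inv_size = np.array(
        [1.0 / assignment.sizes[pc] for pc in pc_ids]
    )
    P = sparse.csr_matrix(
        (inv_size[rows], (rows, np.arange(matrix.n_cells))),
        shape=(n_pc, matrix.n_cells),
    )
    values = P @ matrix.values
    return OmicsMatrix(values=sparse.csc_matrix(values), cell_ids=pc_ids,
                       feature_ids=list(matrix.feature_ids),
                       modality=matrix.modality)


def write_assignment(assignment: PseudocellAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tpseudocell_id\n")
        for c, pc in assignment.assignment.items():
            fh.write(f"{c}\t{pc}\n")


def read_assignment(path, target_size: int = 0, seed: int = 0
                    ) -> PseudocellAssignment:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cell_id"):
            raise ValueError(f"{path}: not an assignment table")
        for line in fh:
            if line.strip():
                c, pc = line.rstrip("\n").split("\t")
                assignment[c] = pc
    sizes: dict[str, int] = {}
    for pc in assignment.values():
        sizes[pc] = sizes.get(pc, 0) + 1
    return PseudocellAssignment(assignment=assignment, sizes=sizes,
                                target_size=target_size or max(sizes.values()),
                                seed=seed)
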