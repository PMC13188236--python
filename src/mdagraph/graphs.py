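"""Graph construction and initial node features.

Three graphs feed the encoders: a miRNA KNN similarity graph, a disease
KNN similarity graph, and the bipartite association graph built from
training positives only.  KNN edges are mutual-or: an undirected edge
exists if either node is in the other's top-K list; self-loops are kept
explicitly.  Similarity ties are broken by ascending node index and a
node never occupies a slot of its own top-K list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .similarity import AssociationTable, SimilarityTable

__all__ = ["KnnGraph", "BipartiteGraph", "FeatureMatrix", "build_knn_graph",
           "init_similarity_features", "init_association_features",
           "make_projection", "project_features"]


@dataclass
class KnnGraph:
    node_labels: list[str]
    edges: set[tuple[int, int]]  # undirected, stored with u <= v; includes self-loops
    K: int
    includes_self_loops: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def neighbors(self, i: int) -> list[int]:
        """Neighbours of node ``i`` excluding itself."""
        out = set()
        for u, v in self.edges:
            if u == i and v != i:
                out.add(v)
            elif v == i and u != i:
                out.add(u)
        return sorted(out)

    def adjacency(self, include_self: bool = False) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            if u == v:
                if include_self:
                    a[u, u] = 1.0
            else:
                a[u, v] = a[v, u] = 1.0
        return a


@dataclass
class BipartiteGraph:
    mirna_labels: list[str]
    disease_labels: list[str]
    edges: set[tuple[int, int]]  # (mirna index, disease index)

    def __post_init__(self) -> None:
        m, d = len(self.mirna_labels), len(self.disease_labels)
        for i, j in self.edges:
            if not (0 <= i < m and 0 <= j < d):
                raise ValueError(f"edge {(i, j)} outside label cross-product")

    @classmethod
    def from_association(cls, assoc: AssociationTable) -> "BipartiteGraph":
        edges = {(int(i), int(j)) for i, j in assoc.positive_edges()}
        return cls(list(assoc.mirna_labels), list(assoc.disease_labels), edges)

    def adjacency_block(self) -> np.ndarray:
        """Symmetric (M+D) x (M+D) adjacency with miRNAs first."""
        m, d = len(self.mirna_labels), len(self.disease_labels)
        a = np.zeros((m + d, m + d))
        for i, j in self.edges:
            a[i, m + j] = a[m + j, i] = 1.0
        return a


@dataclass
class FeatureMatrix:
    node_labels: list[str]
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.node_labels):
            raise ValueError("one feature row per node required")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature entries")


def build_knn_graph(sim: SimilarityTable, K: int = 20) -> KnnGraph:
    """Mutual-or KNN graph over a similarity table.

    ``(i, j)`` is an edge iff ``j`` is among the K most similar nodes to
    ``i`` or vice versa.  Ties break by ascending index; self-similarity
    is excluded from the candidate list and self-connectivity comes only
    from the explicit self-loop.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    s = sim.values
    n = s.shape[0]
    if K >= n:
        warnings.warn(f"K={K} >= number of nodes {n}; KNN graph is complete")
    edges: set[tuple[int, int]] = {(i, i) for i in range(n)}
    for i in range(n):
        order = np.argsort(-s[i], kind="stable")  # stable => ties by ascending index
        topk = [int(j) for j in order if j != i][:K]
        for j in topk:
            edges.add((min(i, j), max(i, j)))
    return KnnGraph(node_labels=list(sim.labels), edges=edges, K=K)


def init_similarity_features(entity: str, fs: SimilarityTable,
                             isd: SimilarityTable,
                             labels: list[str] | None = None) -> FeatureMatrix:
    """Initial features for the similarity graphs.

    miRNA nodes carry their row of the raw functional-similarity matrix;
    disease nodes carry their row of the integrated disease similarity.
    (The two entity types are deliberately asymmetric: miRNAs use the
    un-backfilled FS, diseases the GIP-backfilled integrated matrix.)
    """
    if entity == "mirna":
        table = fs
    elif entity == "disease":
        table = isd
    else:
        raise ValueError("entity must be 'mirna' or 'disease'")
    labels = labels if labels is not None else list(table.labels)
    missing = [l for l in labels if l not in table.labels]
    if missing:
        raise KeyError(f"labels missing from similarity table: {missing}")
    rows = [table.index_of(l) for l in labels]
    return FeatureMatrix(node_labels=labels, values=table.values[rows],
                         source="fs_row" if entity == "mirna" else "isd_row")


def init_association_features(assoc: AssociationTable):
    """Association-profile features: miRNA rows and disease columns."""
    if assoc.n_mirna == 0 or assoc.n_disease == 0:
        raise ValueError("empty association table")
    fm = FeatureMatrix(list(assoc.mirna_labels), assoc.values.astype(float),
                       source="assoc_row")
    fd = FeatureMatrix(list(assoc.disease_labels), assoc.values.T.astype(float),
                       source="assoc_col")
    return fm, fd


def make_projection(in_dim: int, out_dim: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded linear-map initialisation, uniform in ``[-1/sqrt(F), 1/sqrt(F)]``."""
    if out_dim < 1:
        raise ValueError("out_dim must be >= 1")
    bound = 1.0 / np.sqrt(in_dim)
    return rng.uniform(-bound, bound, size=(in_dim, out_dim))


def project_features(features: FeatureMatrix, weight: np.ndarray) -> FeatureMatrix:
    """Apply a (trainable) linear projection to a feature matrix."""
    out = features.values @ np.asarray(weight)
    return FeatureMatrix(list(features.node_labels), out, source="projected")
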