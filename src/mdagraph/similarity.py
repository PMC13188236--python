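"""Similarity computation for miRNAs and diseases.

Four similarity sources feed the downstream graphs:

* **Disease semantic similarity** ``S_D`` from an ontology DAG.  Each
  disease is represented by the sub-DAG of its term and all ancestors.
  Two per-node contribution schemes are combined: an exponential-decay
  scheme (contribution ``lambda**depth`` along the best descending path)
  and an information-content scheme (``-log(f(u)/|V|)`` where ``f(u)``
  counts the per-disease DAGs containing ``u``).
* **miRNA functional similarity** ``FS`` (Wang-style best-match average
  over the diseases each miRNA is associated with).
* **Gaussian interaction-profile (GIP) kernel** similarity for both
  entity types, with a bandwidth adapted to the mean squared profile
  norm.
* **Integrated similarities** ``IS_M`` / ``IS_D``: the semantic or
  functional value where it is positive, backfilled by the GIP kernel
  where it is zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

__all__ = [
    "AssociationTable", "DiseaseOntology", "SemanticWeights",
    "SimilarityTable", "GipParams", "ancestor_closure",
    "decay_contributions", "ic_contributions", "pair_semantic_similarity",
    "disease_semantic_similarity", "mirna_functional_similarity",
    "gip_kernel", "integrate_similarity",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Binary miRNA x disease association matrix with ordered labels."""

    mirna_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        m, d = self.values.shape
        if m != len(self.mirna_labels) or d != len(self.disease_labels):
            raise ValueError("label/matrix shape mismatch")
        if len(set(self.mirna_labels)) != m or len(set(self.disease_labels)) != d:
            raise ValueError("labels must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_disease(self) -> int:
        return len(self.disease_labels)

    def row_profile(self, i: int) -> np.ndarray:
        """Interaction profile of miRNA ``i`` (length D)."""
        return self.values[i, :].astype(float)

    def col_profile(self, j: int) -> np.ndarray:
        """Interaction profile of disease ``j`` (length M)."""
        return self.values[:, j].astype(float)

    def disease_set(self, i: int) -> np.ndarray:
        """Indices of diseases associated with miRNA ``i``."""
        return np.flatnonzero(self.values[i, :])

    def positive_edges(self) -> np.ndarray:
        """(n_pos, 2) array of (mirna index, disease index) pairs."""
        return np.argwhere(self.values == 1)


@dataclass
class DiseaseOntology:
    """Disease term DAG with directed child -> parent edges."""

    terms: set[str]
    edges: list[tuple[str, str]]
    disease_to_term: dict[str, str]

    def __post_init__(self) -> None:
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.terms)
        self._g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValueError("cyclic ontology")
        missing = [d for d, t in self.disease_to_term.items() if t not in self.terms]
        if missing:
            raise ValueError(f"diseases mapped to unknown terms: {missing}")
        self._freq: dict[str, int] | None = None
        self._total_nodes: int | None = None

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def _ensure_frequencies(self) -> None:
        if self._freq is not None:
            return
        freq: dict[str, int] = {}
        total = 0
        for disease in self.disease_to_term:
            nodes, _ = ancestor_closure(self, disease)
            total += len(nodes)
            for u in nodes:
                freq[u] = freq.get(u, 0) + 1
        self._freq = freq
        self._total_nodes = total

    def frequency(self, u: str) -> int:
        """Number of per-disease DAGs containing node ``u``."""
        self._ensure_frequencies()
        return self._freq.get(u, 0)

    @property
    def total_nodes(self) -> int:
        """Multiset total ``sum_d |V(d)|`` over all diseases."""
        self._ensure_frequencies()
        return self._total_nodes


@dataclass
class SemanticWeights:
    """Per-node contributions of one disease's ancestor sub-DAG."""

    disease: str
    phi: dict[str, float]
    sv: float
    scheme: str  # "decay" | "information_content"
    decay_factor: float = 0.5


@dataclass
class SimilarityTable:
    """Square symmetric similarity matrix over one entity type."""

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class GipParams:
    gamma_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")


# ---------------------------------------------------------------------------
# Ontology-based semantic similarity
# ---------------------------------------------------------------------------

def ancestor_closure(ontology: DiseaseOntology, disease: str):
    """Sub-DAG of a disease's term and all of its ontology ancestors.

    Returns ``(V, E)``: the node set containing the term plus the
    transitive closure of its parents, and the edge set induced on it.
    """
    if disease not in ontology.disease_to_term:
        raise KeyError(f"unmapped disease: {disease!r}")
    term = ontology.disease_to_term[disease]
    # edges run child -> parent, so ancestors are the descendants of the
    # term in the child->parent digraph
    nodes = {term} | nx.descendants(ontology.graph, term)
    edges = {(u, v) for u, v in ontology.graph.edges if u in nodes and v in nodes}
    return nodes, edges


def decay_contributions(dag, disease_term: str,
                        decay_factor: float = 0.5) -> SemanticWeights:
    """Exponential-decay contributions over a disease sub-DAG.

    The disease's own term contributes 1; every ancestor ``u``
    contributes ``max(decay * phi[c])`` over its children ``c`` inside
    the sub-DAG, i.e. ``decay ** depth`` along the shortest descending
    path to the term.
    """
    nodes, edges = dag
    if not 0 < decay_factor <= 1:
        raise ValueError("decay factor must lie in (0, 1]")
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cyclic ontology")
    phi: dict[str, float] = {}

    def visit(u: str) -> float:
        if u in phi:
            return phi[u]
        if u == disease_term:
            phi[u] = 1.0
            return 1.0
        children = [c for c, _ in g.in_edges(u)]
        if not children:
            # unreachable from the term: cannot happen for a true
            # ancestor closure, guard for hand-built sub-DAGs
            phi[u] = 0.0
            return 0.0
        phi[u] = max(decay_factor * visit(c) for c in children)
        return phi[u]

    # iterate in sorted order so float summation is independent of set
    # iteration order (and hence of the interpreter's hash seed)
    for u in sorted(nodes):
        visit(u)
    sv = float(sum(phi[u] for u in sorted(phi)))
    return SemanticWeights(disease=disease_term, phi=phi, sv=sv,
                           scheme="decay", decay_factor=decay_factor)


def ic_contributions(ontology: DiseaseOntology, dag) -> SemanticWeights:
    """Information-content contributions ``-log(f(u)/|V|)`` over a sub-DAG.

    ``f(u)`` counts per-disease DAGs containing ``u`` and ``|V|`` is the
    multiset total of nodes over all per-disease DAGs; the contribution
    of a node is therefore independent of which disease's DAG it sits in.
    Natural logarithm.
    """
    nodes, _ = dag
    total = ontology.total_nodes
    phi: dict[str, float] = {}
    for u in sorted(nodes):  # order-stable summation
        f = ontology.frequency(u)
        if f == 0:
            raise ValueError(f"node {u!r} appears in a DAG but has zero frequency")
        phi[u] = float(-np.log(f / total))
    return SemanticWeights(disease="", phi=phi, sv=float(sum(phi.values())),
                           scheme="information_content")


def pair_semantic_similarity(weights_i: SemanticWeights,
                             weights_j: SemanticWeights) -> float:
    """Shared-ancestor similarity of two diseases under one scheme."""
    if weights_i.scheme != weights_j.scheme:
        raise ValueError("mismatched contribution schemes")
    denom = weights_i.sv + weights_j.sv
    if denom == 0:
        warnings.warn("degenerate semantic weights (sv sum is 0); similarity set to 0")
        return 0.0
    shared = sorted(weights_i.phi.keys() & weights_j.phi.keys())
    num = sum(weights_i.phi[k] + weights_j.phi[k] for k in shared)
    return float(num / denom)


def disease_semantic_similarity(ontology: DiseaseOntology,
                                diseases: Sequence[str],
                                decay_factor: float = 0.5) -> SimilarityTable:
    """Mean of the decay-based and information-content similarities."""
    dags = {d: ancestor_closure(ontology, d) for d in diseases}
    w1 = {d: decay_contributions(dags[d], ontology.disease_to_term[d], decay_factor)
          for d in diseases}
    w2 = {d: ic_contributions(ontology, dags[d]) for d in diseases}
    n = len(diseases)
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s1 = pair_semantic_similarity(w1[diseases[i]], w1[diseases[j]])
            s2 = pair_semantic_similarity(w2[diseases[i]], w2[diseases[j]])
            s[i, j] = s[j, i] = 0.5 * (s1 + s2)
    return SimilarityTable(labels=list(diseases), values=s, kind="S_D")


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------

def mirna_functional_similarity(assoc: AssociationTable,
                                disease_sim: SimilarityTable) -> SimilarityTable:
    """Best-match-average functional similarity between miRNAs.

    For miRNAs with disease sets ``DM_i`` (size p) and ``DM_j`` (size q),
    each disease contributes its maximum similarity to the *other* set
    and the sum is normalised by ``p + q``.  Pairs where either set is
    empty get similarity 0 (logged).
    """
    if disease_sim.labels != assoc.disease_labels:
        order = [disease_sim.index_of(d) for d in assoc.disease_labels]
        sd = disease_sim.values[np.ix_(order, order)]
    else:
        sd = disease_sim.values
    m = assoc.n_mirna
    sets = [assoc.disease_set(i) for i in range(m)]
    empty = [i for i in range(m) if sets[i].size == 0]
    if empty:
        log.warning("%d miRNA(s) have empty disease sets; their functional "
                    "similarity is defined as 0", len(empty))
    fs = np.zeros((m, m))
    for i in range(m):
        di = sets[i]
        if di.size == 0:
            continue
        for j in range(i, m):
            dj = sets[j]
            if dj.size == 0:
                continue
            block = sd[np.ix_(di, dj)]
            num = block.max(axis=1).sum() + block.max(axis=0).sum()
            fs[i, j] = fs[j, i] = num / (di.size + dj.size)
    return SimilarityTable(labels=list(assoc.mirna_labels), values=fs, kind="FS")


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------

def gip_kernel(profiles: np.ndarray, labels: Sequence[str],
               params: GipParams | None = None,
               kind: str = "GIP_m") -> SimilarityTable:
    """Gaussian interaction-profile kernel over binary profiles.

    The bandwidth ``eta = gamma' / mean(||IP_i||^2)`` adapts to the
    density of the profile set; ``K(i, j) = exp(-eta ||IP_i - IP_j||^2)``.
    """
    params = params or GipParams()
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float(np.mean((profiles ** 2).sum(axis=1)))
    if mean_sq == 0:
        raise ValueError("degenerate profiles: all interaction profiles are zero")
    eta = params.gamma_prime / mean_sq
    sq = cdist(profiles, profiles, metric="sqeuclidean")
    k = np.exp(-eta * sq)
    k = 0.5 * (k + k.T)
    np.fill_diagonal(k, 1.0)
    return SimilarityTable(labels=list(labels), values=k, kind=kind)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_similarity(primary: SimilarityTable,
                         backfill: SimilarityTable,
                         kind: str | None = None) -> SimilarityTable:
    """Piecewise integration: primary where positive, else backfill."""
    if primary.labels != backfill.labels:
        raise ValueError("label mismatch between primary and backfill tables")
    out = np.where(primary.values > 0, primary.values, backfill.values)
    if kind is None:
        kind = "IS_D" if primary.kind in ("S_D", "IS_D") else "IS_M"
    return SimilarityTable(labels=list(primary.labels), values=out, kind=kind)


def integrated_similarities(assoc: AssociationTable,
                            ontology: DiseaseOntology,
                            decay_factor: float = 0.5,
                            gip_params: GipParams | None = None):
    """Convenience: compute ``(FS, S_D, IS_M, IS_D)`` for one association table.

    GIP kernels and functional similarity depend on the association
    matrix and must be recomputed from training-only associations inside
    any evaluation fold; pass the fold's training table here.
    """
    s_d = disease_semantic_similarity(ontology, assoc.disease_labels, decay_factor)
    fs = mirna_functional_similarity(assoc, s_d)
    gip_m = gip_kernel(assoc.values.astype(float), assoc.mirna_labels,
                       gip_params, kind="GIP_m")
    gip_d = gip_kernel(assoc.values.T.astype(float), assoc.disease_labels,
                       gip_params, kind="GIP_d")
    is_m = integrate_similarity(fs, gip_m, kind="IS_M")
    is_d = integrate_similarity(s_d, gip_d, kind="IS_D")
    return fs, s_d, is_m, is_d
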