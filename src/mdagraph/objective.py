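"""Joint training objective: triplet metric learning plus cross-entropy.

Triplets are anchored on miRNAs: the positive is a disease linked to
the anchor in the training graph, the negative a disease with no such
link.  Negatives are drawn degree-balanced (probability proportional to
``1 / (degree + 1)`` so zero-degree diseases stay sampleable) or, when
current embeddings are available, by semi-hard mining within the batch:
among non-positive diseases whose squared distance to the anchor lies
in ``(d_pos, d_pos + margin)``, the closest is taken; if the band is
empty the caller falls back to the degree-balanced draw.

The total loss is the unweighted sum of the mean binary cross-entropy
over scored pairs and the mean triplet hinge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, relu

__all__ = ["TripletBatch", "NegativeSamplerState", "degree_balanced_sample",
           "semi_hard_mine", "triplet_loss", "bce_loss", "total_loss"]

PRED_CLIP = 1e-7  # predictions clipped to [PRED_CLIP, 1 - PRED_CLIP]


@dataclass
class TripletBatch:
    anchors: np.ndarray    # miRNA indices
    positives: np.ndarray  # disease indices
    negatives: np.ndarray  # disease indices
    margin: float = 1.0


@dataclass
class NegativeSamplerState:
    """Degree table and per-anchor negative pools over the training graph."""

    positive_sets: list[set[int]]  # per miRNA: training-positive diseases
    degrees: np.ndarray            # per disease: training-graph degree
    n_disease: int
    positive_matrix: np.ndarray = field(default=None, repr=False)  # (M, D) bool
    _pool_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_edges(cls, edges: np.ndarray, n_mirna: int,
                   n_disease: int) -> "NegativeSamplerState":
        pos = [set() for _ in range(n_mirna)]
        deg = np.zeros(n_disease)
        mat = np.zeros((n_mirna, n_disease), dtype=bool)
        for i, j in edges:
            pos[int(i)].add(int(j))
            deg[int(j)] += 1
            mat[int(i), int(j)] = True
        return cls(positive_sets=pos, degrees=deg, n_disease=n_disease,
                   positive_matrix=mat)

    def pool(self, anchor: int) -> np.ndarray:
        return np.array([j for j in range(self.n_disease)
                         if j not in self.positive_sets[anchor]], dtype=int)

    def _pool_cumweights(self, anchor: int):
        cached = self._pool_cache.get(anchor)
        if cached is None:
            pool = self.pool(anchor)
            if pool.size == 0:
                raise ValueError(f"empty negative pool for anchor {anchor}")
            w = 1.0 / (self.degrees[pool] + 1.0)
            cached = (pool, np.cumsum(w) / w.sum())
            self._pool_cache[anchor] = cached
        return cached


def degree_balanced_sample(state: NegativeSamplerState, anchor: int,
                           rng: np.random.Generator) -> int:
    """Draw a non-positive disease with probability ~ 1/(degree + 1)."""
    pool, cumw = state._pool_cumweights(anchor)
    return int(pool[np.searchsorted(cumw, rng.random(), side="right")])


def semi_hard_mine(state: NegativeSamplerState, anchor: int,
                   anchor_embedding: np.ndarray,
                   batch_diseases: np.ndarray,
                   disease_embeddings: np.ndarray,
                   positive_distance: float,
                   margin: float) -> int | None:
    """Closest in-batch non-positive inside the semi-hard band, or None.

    The band covers squared distances strictly greater than the
    positive's but within ``margin`` of it; an empty band signals the
    caller to fall back to a degree-balanced draw.
    """
    if batch_diseases.size == 0:
        return None
    mask = np.array([int(j) not in state.positive_sets[anchor]
                     for j in batch_diseases])
    if not mask.any():
        return None
    cand = batch_diseases[mask]
    d2 = ((disease_embeddings[mask] - anchor_embedding) ** 2).sum(axis=1)
    band = (d2 > positive_distance) & (d2 < positive_distance + margin)
    if not band.any():
        return None
    sub = np.flatnonzero(band)
    return int(cand[sub[np.argmin(d2[sub])]])


def mine_batch_negatives(state: NegativeSamplerState, anchors: np.ndarray,
                         positives: np.ndarray, mirna_embeddings: np.ndarray,
                         disease_embeddings: np.ndarray, margin: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Vectorised semi-hard mining with degree-balanced fallback.

    Equivalent to calling :func:`semi_hard_mine` anchor by anchor over
    the batch's positive diseases and falling back to
    :func:`degree_balanced_sample` when the band is empty.
    """
    from scipy.spatial.distance import cdist

    batch_dis = np.unique(positives)
    za = mirna_embeddings[anchors]
    d2 = cdist(za, disease_embeddings[batch_dis], metric="sqeuclidean")
    d_pos = ((za - disease_embeddings[positives]) ** 2).sum(axis=1)
    non_pos = ~state.positive_matrix[np.ix_(anchors, batch_dis)]
    band = non_pos & (d2 > d_pos[:, None]) & (d2 < (d_pos + margin)[:, None])
    masked = np.where(band, d2, np.inf)
    pick = masked.argmin(axis=1)
    has_band = band.any(axis=1)
    negs = np.empty(len(anchors), dtype=int)
    negs[has_band] = batch_dis[pick[has_band]]
    for t in np.flatnonzero(~has_band):
        negs[t] = degree_balanced_sample(state, int(anchors[t]), rng)
    return negs


def triplet_loss(z_a: Tensor, z_p: Tensor, z_n: Tensor,
                 margin: float = 1.0) -> Tensor:
    """Hinge on the anchor-positive vs anchor-negative squared distances.

    Accepts single embeddings or row-aligned batches; batches are
    averaged.
    """
    z_a = z_a if isinstance(z_a, Tensor) else Tensor(z_a)
    z_p = z_p if isinstance(z_p, Tensor) else Tensor(z_p)
    z_n = z_n if isinstance(z_n, Tensor) else Tensor(z_n)
    axis = 1 if z_a.data.ndim == 2 else None
    d_pos = ((z_a - z_p) ** 2).sum(axis=axis)
    d_neg = ((z_a - z_n) ** 2).sum(axis=axis)
    hinge = relu(d_pos - d_neg + margin)
    return hinge.mean() if axis == 1 else hinge


def bce_loss(predictions: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with clipped predictions."""
    p = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
    p = p.clip(PRED_CLIP, 1.0 - PRED_CLIP)
    y = np.asarray(labels, dtype=float)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()


def total_loss(bce: Tensor, tri: Tensor) -> Tensor:
    """Unweighted sum of the two objective terms."""
    bce = bce if isinstance(bce, Tensor) else Tensor(bce)
    tri = tri if isinstance(tri, Tensor) else Tensor(tri)
    return bce + tri
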