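"""Gated multi-view fusion.

Two fusion stages act on the encoder outputs:

* :func:`adaptive_fuse` combines the two view-specific embeddings of one
  entity type through a learned per-node scalar gate, yielding a convex
  combination of the views for every node.
* :func:`global_context_fuse` mixes every node's embedding with the
  dataset-mean embedding through a learned scalar gate, injecting global
  context while preserving the column means exactly.

Separate parameter instances are used for miRNAs and diseases — no
weight sharing across entity types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat, relu, sigmoid

__all__ = ["FusionParams", "GlobalContextParams", "adaptive_fuse",
           "global_context_fuse"]


@dataclass
class FusionParams:
    mix_weight: Tensor   # W1: (2d, h)
    gate_weight: Tensor  # W2: (h, 1) -> per-node scalar gate

    @classmethod
    def create(cls, dim: int, rng: np.random.Generator,
               hidden: int | None = None) -> "FusionParams":
        hidden = hidden or dim
        return cls(mix_weight=nn.glorot(rng, 2 * dim, hidden),
                   gate_weight=nn.glorot(rng, hidden, 1))


@dataclass
class GlobalContextParams:
    fc1: Tensor  # (d, h)
    fc2: Tensor  # (h, 1)

    @classmethod
    def create(cls, dim: int, rng: np.random.Generator,
               hidden: int | None = None) -> "GlobalContextParams":
        hidden = hidden or max(dim // 4, 1)
        return cls(fc1=nn.glorot(rng, dim, hidden),
                   fc2=nn.glorot(rng, hidden, 1))


def adaptive_fuse(x1: Tensor, x2: Tensor, params: FusionParams) -> Tensor:
    """Gated convex combination of two same-shape embedding matrices.

    ``H = ReLU(W1 [X1 ; X2])``, ``alpha = sigmoid(W2 H)`` as a per-node
    scalar broadcast across embedding dimensions, and
    ``Z = alpha * X1 + (1 - alpha) * X2``.
    """
    x1 = x1 if isinstance(x1, Tensor) else Tensor(x1)
    x2 = x2 if isinstance(x2, Tensor) else Tensor(x2)
    if x1.shape != x2.shape:
        raise ValueError("view embeddings must have identical shapes")
    h = relu(concat([x1, x2], axis=1) @ params.mix_weight)
    alpha = sigmoid(h @ params.gate_weight)  # (N, 1), strictly in (0, 1)
    return alpha * x1 + (1.0 - alpha) * x2


def global_context_fuse(f: Tensor, params: GlobalContextParams) -> Tensor:
    """Gated mix of node embeddings with the global mean embedding.

    ``g`` is the column-wise mean over nodes; a two-layer ReLU/sigmoid
    network maps it to a scalar gate, and every row becomes
    ``alpha * f_i + (1 - alpha) * g``.  The column means of the output
    equal those of the input for any gate value.
    """
    f = f if isinstance(f, Tensor) else Tensor(f)
    if f.shape[0] == 0:
        raise ValueError("empty embedding matrix")
    g = f.mean(axis=0, keepdims=True)  # (1, d)
    alpha = sigmoid(relu(g @ params.fc1) @ params.fc2)  # (1, 1) scalar gate
    return alpha * f + (1.0 - alpha) * g
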