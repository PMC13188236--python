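"""Residual GraphSAGE encoder.

Three layers of mean-neighbourhood aggregation.  At each layer a node's
own state is concatenated with the mean of its neighbours' states
(neighbours exclude the node itself; its own state enters only via the
concatenation), passed through a trainable matrix and an ELU, and a
linear residual projection of the layer input is added on top of a
second ELU.  Dropout is applied after each layer's residual sum during
training only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graphs import BipartiteGraph, KnnGraph
from .nn import Tensor, concat, elu

__all__ = ["SageLayerParams", "EncoderConfig", "SageEncoder",
           "mean_aggregation_matrix", "neighbor_mean", "sage_update",
           "residual_update"]


@dataclass
class SageLayerParams:
    weight: Tensor        # (2 * in_dim, out_dim)
    residual_map: Tensor  # (in_dim, out_dim)

    def __post_init__(self) -> None:
        if self.weight.shape[0] != 2 * self.residual_map.shape[0]:
            raise ValueError("weight input width must be 2 x layer input width")
        if self.weight.shape[1] != self.residual_map.shape[1]:
            raise ValueError("weight and residual_map output widths differ")


@dataclass
class EncoderConfig:
    hidden_dims: tuple[int, ...] = (128, 64, 128)
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.hidden_dims):
            raise ValueError("hidden dims must be positive")


def mean_aggregation_matrix(graph: KnnGraph | BipartiteGraph) -> np.ndarray:
    """Row-normalised neighbour-mean operator (self excluded).

    Isolated nodes get an all-zero row, so they aggregate the zero
    vector instead of raising.
    """
    if isinstance(graph, BipartiteGraph):
        adj = graph.adjacency_block()
    else:
        adj = graph.adjacency(include_self=False)
    deg = adj.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(deg > 0, adj / deg, 0.0)
    return a


def neighbor_mean(features, graph, node: int) -> np.ndarray:
    """Mean of the neighbours' feature vectors for one node."""
    vals = features.values if hasattr(features, "values") else np.asarray(features)
    if isinstance(graph, BipartiteGraph):
        adj = graph.adjacency_block()
        nbrs = np.flatnonzero(adj[node])
    else:
        nbrs = graph.neighbors(node)
    if len(nbrs) == 0:
        return np.zeros(vals.shape[1])
    return vals[list(nbrs)].mean(axis=0)


def sage_update(own: Tensor, agg: Tensor, params: SageLayerParams) -> Tensor:
    """ELU(W [own || agg]) — the concatenation update."""
    own = own if isinstance(own, Tensor) else Tensor(own)
    agg = agg if isinstance(agg, Tensor) else Tensor(agg)
    if own.shape[-1] + agg.shape[-1] != params.weight.shape[0]:
        raise ValueError("dimension mismatch in concatenation update")
    return elu(concat([own, agg], axis=-1 if own.data.ndim > 1 else 0) @ params.weight)


def residual_update(pre_activation_out: Tensor, layer_input: Tensor,
                    params: SageLayerParams) -> Tensor:
    """ELU(h_next) + W_r h_prev — linear residual on top of the update.

    Note the composition stacks a second ELU on the already-activated
    concatenation update; this follows the published update rule as
    printed.
    """
    pre = pre_activation_out if isinstance(pre_activation_out, Tensor) else Tensor(pre_activation_out)
    inp = layer_input if isinstance(layer_input, Tensor) else Tensor(layer_input)
    return elu(pre) + inp @ params.residual_map


class SageEncoder:
    """Stack of residual mean-aggregation layers over one graph."""

    def __init__(self, in_dim: int, config: EncoderConfig,
                 rng: np.random.Generator):
        self.config = config
        self.layers: list[SageLayerParams] = []
        prev = in_dim
        for out in config.hidden_dims:
            self.layers.append(SageLayerParams(
                weight=nn.glorot(rng, 2 * prev, out),
                residual_map=nn.glorot(rng, prev, out)))
            prev = out
        self.out_dim = prev

    def parameters(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out += [layer.weight, layer.residual_map]
        return out

    def encode(self, features: Tensor, agg_matrix: np.ndarray,
               training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        h = features if isinstance(features, Tensor) else Tensor(features)
        a = Tensor(agg_matrix)
        for layer in self.layers:
            agg = a @ h
            h_next = sage_update(h, agg, layer)
            h = residual_update(h_next, h, layer)
            if training and self.config.dropout > 0:
                if rng is None:
                    raise ValueError("training-mode encoding needs an rng for dropout")
                keep = 1.0 - self.config.dropout
                mask = rng.random(h.shape) < keep
                h = h * Tensor(mask / keep)
        return h


def encode_graph(features, graph, encoder: SageEncoder,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Encode a feature matrix over a graph with a configured encoder."""
    vals = features.values if hasattr(features, "values") else features
    x = vals if isinstance(vals, Tensor) else Tensor(vals)
    return encoder.encode(x, mean_aggregation_matrix(graph), training=training, rng=rng)
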