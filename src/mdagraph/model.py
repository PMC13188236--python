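"""End-to-end model: encoders, fusion units, image branch, prediction head.

The model embeds miRNAs and diseases through three residual GraphSAGE
encoders (miRNA similarity graph, disease similarity graph, and the
bipartite association graph encoded as one homogeneous graph over
M + D nodes), fuses the two views per entity type with a gated convex
combination, injects global context, and scores a pair by concatenating
the miRNA embedding, the disease embedding and the disease's image
feature into a two-layer prediction head with a final sigmoid.

Ablation variants switch off individual components:

``similarity_only`` / ``association_only``
    keep a single graph view (no adaptive fusion),
``no_image``
    drop the image feature from the head input,
``concat_fusion``
    replace the gated fusion by plain concatenation of the two views,
``no_triplet``
    train with cross-entropy only (handled by the trainer).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .fusion import FusionParams, GlobalContextParams, adaptive_fuse, global_context_fuse
from .graphs import (BipartiteGraph, build_knn_graph,
                     init_association_features, init_similarity_features)
from .morphology import ImageEmbedding
from .nn import Tensor, concat, relu, sigmoid
from .sage import EncoderConfig, SageEncoder, mean_aggregation_matrix
from .similarity import AssociationTable, DiseaseOntology, integrated_similarities

__all__ = ["TrainConfig", "ModelInputs", "MDAModel", "prepare_inputs",
           "VARIANTS"]

VARIANTS = ("full", "similarity_only", "association_only", "no_image",
            "concat_fusion", "no_triplet")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    dropout: float = 0.3
    weight_decay: float = 1e-3
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 512
    seed: int = 0
    K: int = 20
    hidden_dims: tuple[int, ...] = (128, 64, 128)
    margin: float = 1.0
    val_fraction: float = 0.1
    image_dim: int = 128
    backbone_dim: int = 512
    variant: str = "full"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.learning_rate <= 0 or self.patience < 0 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")

    @property
    def embed_dim(self) -> int:
        return self.hidden_dims[-1]

    def rng(self, *key: int) -> np.random.Generator:
        """Sub-stream of the master seed (counter-keyed fan-out)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key))

    @classmethod
    def scaled_demo(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Configuration for the scaled-down synthetic studies.

        Full-batch edge losses with a moderately larger step size, no
        dropout and a bounded epoch budget: at a few hundred nodes the
        full-scale configuration's stochastic regularisation keeps the
        validation metric from improving within any tractable number of
        epochs, so the demonstration runs rely on weight decay and early
        stopping instead.
        """
        kwargs = dict(learning_rate=3e-4, dropout=0.0, max_epochs=300,
                      patience=40, batch_size=1_000_000, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ModelInputs:
    """Fold-specific, training-only derived inputs for the model."""

    assoc: AssociationTable          # training-visible associations
    feat_sim_m: np.ndarray           # (M, M) FS rows
    feat_sim_d: np.ndarray           # (D, D) integrated-similarity rows
    feat_assoc_m: np.ndarray         # (M, D) association rows
    feat_assoc_d: np.ndarray         # (D, M) association columns
    agg_sim_m: np.ndarray            # neighbour-mean operators
    agg_sim_d: np.ndarray
    agg_assoc: np.ndarray            # (M+D, M+D)
    image_raw: np.ndarray | None = None   # (D, backbone_dim) pooled class vectors
    image_mask: np.ndarray | None = None  # (D, 1) 1 where imagery exists


def prepare_inputs(assoc_train: AssociationTable, ontology: DiseaseOntology,
                   K: int = 20,
                   image_embedding: ImageEmbedding | None = None,
                   disease_to_class: dict[str, str] | None = None,
                   ) -> ModelInputs:
    """Similarities, KNN graphs and initial features from training data.

    Everything that depends on the association matrix (functional
    similarity, GIP kernels, the bipartite graph) is derived from the
    training table passed in, never from the full matrix.
    """
    fs, s_d, is_m, is_d = integrated_similarities(assoc_train, ontology)
    knn_m = build_knn_graph(is_m, K)
    knn_d = build_knn_graph(is_d, K)
    bip = BipartiteGraph.from_association(assoc_train)
    fm = init_similarity_features("mirna", fs, is_d, labels=assoc_train.mirna_labels)
    fd = init_similarity_features("disease", fs, is_d, labels=assoc_train.disease_labels)
    am, ad = init_association_features(assoc_train)
    image_raw = image_mask = None
    if image_embedding is not None:
        d2c = disease_to_class or {}
        rows, mask = [], []
        for dl in assoc_train.disease_labels:
            vec = image_embedding.class_vectors.get(d2c.get(dl, dl))
            if vec is None:
                rows.append(np.zeros(image_embedding.width))
                mask.append(0.0)
            else:
                rows.append(np.asarray(vec))
                mask.append(1.0)
        image_raw = np.asarray(rows)
        image_mask = np.asarray(mask)[:, None]
    return ModelInputs(assoc=assoc_train,
                       feat_sim_m=fm.values, feat_sim_d=fd.values,
                       feat_assoc_m=am.values, feat_assoc_d=ad.values,
                       agg_sim_m=mean_aggregation_matrix(knn_m),
                       agg_sim_d=mean_aggregation_matrix(knn_d),
                       agg_assoc=mean_aggregation_matrix(bip),
                       image_raw=image_raw, image_mask=image_mask)


class MDAModel:
    """All trainable components, seeded and variant-aware."""

    def __init__(self, n_mirna: int, n_disease: int, config: TrainConfig):
        self.config = config
        self.n_mirna = n_mirna
        self.n_disease = n_disease
        cfg = config
        rng = cfg.rng(10)
        latent = cfg.hidden_dims[0]
        enc_cfg = EncoderConfig(hidden_dims=cfg.hidden_dims, dropout=cfg.dropout)
        d = cfg.embed_dim
        v = cfg.variant
        self.use_sim_view = v != "association_only"
        self.use_assoc_view = v != "similarity_only"
        self.use_images = v != "no_image"
        self.gated_fusion = v != "concat_fusion"
        self.use_triplet = v != "no_triplet"

        self.params: dict[str, Tensor] = {}

        def reg(name: str, t: Tensor) -> Tensor:
            self.params[name] = t
            return t

        if self.use_sim_view:
            self.proj_sim_m = reg("proj_sim_m", nn.uniform_init(rng, n_mirna, latent))
            self.proj_sim_d = reg("proj_sim_d", nn.uniform_init(rng, n_disease, latent))
            self.enc_sim_m = SageEncoder(latent, enc_cfg, rng)
            self.enc_sim_d = SageEncoder(latent, enc_cfg, rng)
            self._reg_encoder("enc_sim_m", self.enc_sim_m)
            self._reg_encoder("enc_sim_d", self.enc_sim_d)
        if self.use_assoc_view:
            self.proj_assoc_m = reg("proj_assoc_m", nn.uniform_init(rng, n_disease, latent))
            self.proj_assoc_d = reg("proj_assoc_d", nn.uniform_init(rng, n_mirna, latent))
            self.enc_assoc = SageEncoder(latent, enc_cfg, rng)
            self._reg_encoder("enc_assoc", self.enc_assoc)

        two_views = self.use_sim_view and self.use_assoc_view
        if two_views and self.gated_fusion:
            self.fuse_m = FusionParams.create(d, rng)
            self.fuse_d = FusionParams.create(d, rng)
            self.params.update(fuse_m_w1=self.fuse_m.mix_weight,
                               fuse_m_w2=self.fuse_m.gate_weight,
                               fuse_d_w1=self.fuse_d.mix_weight,
                               fuse_d_w2=self.fuse_d.gate_weight)
            self.embed_dim = d
        elif two_views:
            self.embed_dim = 2 * d  # plain concatenation of the views
        else:
            self.embed_dim = d
        self.gc_m = GlobalContextParams.create(self.embed_dim, rng)
        self.gc_d = GlobalContextParams.create(self.embed_dim, rng)
        self.params.update(gc_m_fc1=self.gc_m.fc1, gc_m_fc2=self.gc_m.fc2,
                           gc_d_fc1=self.gc_d.fc1, gc_d_fc2=self.gc_d.fc2)

        head_in = 2 * self.embed_dim
        if self.use_images:
            self.img_proj = reg("img_proj", nn.glorot(rng, cfg.backbone_dim, cfg.image_dim))
            # shared trainable embedding for diseases without imagery; a
            # zero vector would silently bias the head
            self.null_embedding = reg("null_embedding", Tensor(
                rng.normal(scale=0.01, size=(1, cfg.image_dim)), requires_grad=True))
            head_in += cfg.image_dim
        self.head_w1 = reg("head_w1", nn.glorot(rng, head_in, d))
        self.head_b1 = reg("head_b1", Tensor(np.zeros(d), requires_grad=True))
        self.head_w2 = reg("head_w2", nn.glorot(rng, d, 1))
        self.head_b2 = reg("head_b2", Tensor(np.zeros(1), requires_grad=True))

    def _reg_encoder(self, name: str, enc: SageEncoder) -> None:
        for i, layer in enumerate(enc.layers):
            self.params[f"{name}_l{i}_w"] = layer.weight
            self.params[f"{name}_l{i}_r"] = layer.residual_map

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward -------------------------------------------------------------

    def forward(self, inputs: ModelInputs, training: bool = False,
                rng: np.random.Generator | None = None):
        """Return ``(F_m, F_d, F_img)`` embedding tensors.

        ``F_img`` is None when the image branch is disabled.
        """
        m, dn = self.n_mirna, self.n_disease
        views_m, views_d = [], []
        if self.use_sim_view:
            xm = Tensor(self.feat(inputs, "feat_sim_m")) @ self.proj_sim_m
            xd = Tensor(self.feat(inputs, "feat_sim_d")) @ self.proj_sim_d
            views_m.append(self.enc_sim_m.encode(xm, inputs.agg_sim_m, training, rng))
            views_d.append(self.enc_sim_d.encode(xd, inputs.agg_sim_d, training, rng))
        if self.use_assoc_view:
            xa = concat([Tensor(inputs.feat_assoc_m) @ self.proj_assoc_m,
                         Tensor(inputs.feat_assoc_d) @ self.proj_assoc_d], axis=0)
            ha = self.enc_assoc.encode(xa, inputs.agg_assoc, training, rng)
            views_m.append(ha[np.arange(m)])
            views_d.append(ha[np.arange(m, m + dn)])
        if len(views_m) == 2 and self.gated_fusion:
            fm = adaptive_fuse(views_m[0], views_m[1], self.fuse_m)
            fd = adaptive_fuse(views_d[0], views_d[1], self.fuse_d)
        elif len(views_m) == 2:
            fm = concat(views_m, axis=1)
            fd = concat(views_d, axis=1)
        else:
            fm, fd = views_m[0], views_d[0]
        fm = global_context_fuse(fm, self.gc_m)
        fd = global_context_fuse(fd, self.gc_d)
        fimg = None
        if self.use_images:
            if inputs.image_raw is not None:
                mask = Tensor(inputs.image_mask)
                proj = Tensor(inputs.image_raw) @ self.img_proj
                fimg = mask * proj + (1.0 - mask) * self.null_embedding
            else:
                fimg = Tensor(np.ones((dn, 1))) * self.null_embedding
        return fm, fd, fimg

    @staticmethod
    def feat(inputs: ModelInputs, name: str) -> np.ndarray:
        return getattr(inputs, name)

    def score_pairs(self, fm: Tensor, fd: Tensor, fimg: Tensor | None,
                    pairs: np.ndarray) -> Tensor:
        """Probabilities for (miRNA, disease) index pairs, shape (n,)."""
        pairs = np.asarray(pairs).reshape(-1, 2)
        blocks = [fm[pairs[:, 0]], fd[pairs[:, 1]]]
        if self.use_images:
            blocks.append(fimg[pairs[:, 1]])
        x = concat(blocks, axis=1)
        h = relu(x @ self.head_w1 + self.head_b1)
        logits = h @ self.head_w2 + self.head_b2
        return sigmoid(logits).reshape(-1)

    def forward_pair(self, inputs: ModelInputs, mirna: int, disease: int) -> float:
        """Eval-mode probability for one pair."""
        fm, fd, fimg = self.forward(inputs, training=False)
        return float(self.score_pairs(fm, fd, fimg, np.array([[mirna, disease]])).data[0])

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=float)

    def save(self, path: str) -> None:
        meta = dict(n_mirna=self.n_mirna, n_disease=self.n_disease,
                    config=asdict(self.config))
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "MDAModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
            model = cls(meta["n_mirna"], meta["n_disease"], TrainConfig(**cfg_dict))
            model.load_state_dict({k[len("param::"):]: data[k]
                                   for k in data.files if k.startswith("param::")})
        return model
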