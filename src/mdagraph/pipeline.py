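"""Training loop, fold-level evaluation, imbalance sweeps and ranking.

Each fold trains on its training positives only: the similarity
matrices, graphs and features are rebuilt from a training-only
association table (10% of training positives are first carved out, with
matched 1:1 negatives, as a frozen validation set for early stopping —
those validation edges are also excluded from the graphs so the
monitored metric reflects truly unseen edges).  Cross-entropy negatives
are resampled 1:1 from unknown pairs every epoch; triplet negatives are
mined semi-hard within the batch with a degree-balanced fallback.
Optimisation is Adam with early stopping on validation AUC; the
best-validation parameters are restored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .evaluation import (ColdStartPlan, FoldPlan, MetricsReport,
                         aggregate_metrics, compute_metrics)
from .model import MDAModel, ModelInputs, TrainConfig, prepare_inputs
from .morphology import ImageEmbedding
from .nn import Adam
from .objective import (NegativeSamplerState, bce_loss, mine_batch_negatives,
                        total_loss, triplet_loss)
from .similarity import AssociationTable, DiseaseOntology

__all__ = ["TrainedModel", "train_fold", "score_all_pairs", "rank_candidates",
           "evaluate_fold", "run_cross_validation", "run_cold_start",
           "ratio_sweep"]


@dataclass
class TrainedModel:
    model: MDAModel
    inputs: ModelInputs
    log: list[dict]
    best_epoch: int
    best_val_auc: float

    def scores(self) -> np.ndarray:
        return score_all_pairs(self.model, self.inputs)


def _pair_ids(pairs: np.ndarray, n_disease: int) -> np.ndarray:
    pairs = np.asarray(pairs).reshape(-1, 2)
    return pairs[:, 0] * n_disease + pairs[:, 1]


def _sample_unknown(n_mirna: int, n_disease: int, forbidden: set[int],
                    n: int, rng: np.random.Generator) -> np.ndarray:
    """n pairs uniform over the cells not in ``forbidden`` (by flat id)."""
    all_ids = np.arange(n_mirna * n_disease)
    mask = np.ones(len(all_ids), dtype=bool)
    mask[list(forbidden)] = False
    pool = all_ids[mask]
    if n > len(pool):
        raise ValueError("not enough unknown pairs to sample negatives")
    chosen = rng.choice(pool, size=n, replace=False)
    return np.stack([chosen // n_disease, chosen % n_disease], axis=1)


def train_fold(assoc_full: AssociationTable, ontology: DiseaseOntology,
               train_pos: np.ndarray, config: TrainConfig,
               image_embedding: ImageEmbedding | None = None,
               disease_to_class: dict[str, str] | None = None,
               forbidden_test: np.ndarray | None = None) -> TrainedModel:
    """Train one model on the given training positives.

    ``forbidden_test`` (the fold's test positives) is used only for a
    leakage audit: training raises if any of those edges appears in the
    structures it is about to train on.
    """
    m, dn = assoc_full.n_mirna, assoc_full.n_disease
    train_pos = np.asarray(train_pos).reshape(-1, 2)
    if len(train_pos) == 0:
        raise ValueError("no training positives")
    if forbidden_test is not None and len(forbidden_test):
        overlap = set(_pair_ids(train_pos, dn).tolist()) & \
            set(_pair_ids(forbidden_test, dn).tolist())
        if overlap:
            raise AssertionError("leakage audit failed: test edges in training set")

    # -- validation carve-out -------------------------------------------
    rng_val = config.rng(20)
    n_val = max(1, int(round(config.val_fraction * len(train_pos))))
    if n_val >= len(train_pos):
        n_val = len(train_pos) - 1
    perm = rng_val.permutation(len(train_pos))
    val_pos = train_pos[perm[:n_val]]
    model_pos = train_pos[np.sort(perm[n_val:])]

    visible_ids = set(_pair_ids(model_pos, dn).tolist())
    val_ids = set(_pair_ids(val_pos, dn).tolist())
    val_neg = _sample_unknown(m, dn, visible_ids | val_ids, len(val_pos), rng_val)
    val_pairs = np.concatenate([val_pos, val_neg])
    val_labels = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])

    # -- fold inputs (training-only derived data) ------------------------
    values = np.zeros_like(assoc_full.values)
    values[model_pos[:, 0], model_pos[:, 1]] = 1
    assoc_train = AssociationTable(list(assoc_full.mirna_labels),
                                   list(assoc_full.disease_labels), values)
    if config.variant == "no_image":
        image_embedding = None
    inputs = prepare_inputs(assoc_train, ontology, K=config.K,
                            image_embedding=image_embedding,
                            disease_to_class=disease_to_class)
    model = MDAModel(m, dn, config)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    sampler = NegativeSamplerState.from_edges(model_pos, m, dn)
    rng_neg = config.rng(21)
    rng_drop = config.rng(22)

    from sklearn.metrics import roc_auc_score

    def validation_auc() -> float:
        fm, fd, fimg = model.forward(inputs, training=False)
        s = model.score_pairs(fm, fd, fimg, val_pairs).data
        return float(roc_auc_score(val_labels, s))

    best = {"auc": -np.inf, "epoch": -1, "state": model.state_dict()}
    log: list[dict] = []
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng_neg.permutation(len(model_pos))
        neg_epoch = _sample_unknown(m, dn, visible_ids, len(model_pos), rng_neg)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(model_pos), config.batch_size):
            batch_pos = model_pos[order[start:start + config.batch_size]]
            batch_neg = neg_epoch[start:start + config.batch_size]
            fm, fd, fimg = model.forward(inputs, training=True, rng=rng_drop)
            pairs = np.concatenate([batch_pos, batch_neg])
            labels = np.concatenate([np.ones(len(batch_pos)),
                                     np.zeros(len(batch_neg))])
            preds = model.score_pairs(fm, fd, fimg, pairs)
            loss = bce_loss(preds, labels)
            if model.use_triplet:
                anchors = batch_pos[:, 0]
                positives = batch_pos[:, 1]
                negs = mine_batch_negatives(sampler, anchors, positives,
                                            fm.data, fd.data, config.margin,
                                            rng_neg)
                tri = triplet_loss(fm[anchors], fd[positives], fd[negs],
                                   margin=config.margin)
                loss = total_loss(loss, tri)
            loss.backward()
            opt.step()
            opt.zero_grad()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_auc = validation_auc()
        log.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                    "val_auc": val_auc})
        if val_auc > best["auc"]:
            best = {"auc": val_auc, "epoch": epoch, "state": model.state_dict()}
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    model.load_state_dict(best["state"])
    return TrainedModel(model=model, inputs=inputs, log=log,
                        best_epoch=best["epoch"], best_val_auc=best["auc"])


def score_all_pairs(model: MDAModel, inputs: ModelInputs,
                    batch: int = 4096) -> np.ndarray:
    """Eval-mode M x D matrix of pair probabilities."""
    m, dn = model.n_mirna, model.n_disease
    fm, fd, fimg = model.forward(inputs, training=False)
    pairs = np.stack(np.meshgrid(np.arange(m), np.arange(dn),
                                 indexing="ij"), axis=-1).reshape(-1, 2)
    out = np.empty(len(pairs))
    for s in range(0, len(pairs), batch):
        out[s:s + batch] = model.score_pairs(fm, fd, fimg,
                                             pairs[s:s + batch]).data
    return out.reshape(m, dn)


def rank_candidates(trained: TrainedModel, disease: int, top_n: int = 50,
                    exclude: np.ndarray | None = None) -> list[tuple[int, float]]:
    """Top-scoring candidate miRNAs for one disease.

    Pairs listed in ``exclude`` must be absent from the training edges
    (the leave-one-out contract is enforced, not assumed); miRNAs with a
    training association to the disease are not candidates.  Ties break
    by ascending miRNA index.
    """
    inputs = trained.inputs
    dn = inputs.assoc.n_disease
    train_ids = set(_pair_ids(inputs.assoc.positive_edges(), dn).tolist())
    if exclude is not None and len(exclude):
        bad = set(_pair_ids(exclude, dn).tolist()) & train_ids
        if bad:
            raise AssertionError(
                "excluded case-study pairs found among training edges")
    scores = trained.scores()[:, disease]
    known = {i for i, j in inputs.assoc.positive_edges() if j == disease}
    cand = np.array([i for i in range(len(scores)) if i not in known])
    if top_n > len(cand):
        warnings.warn(f"top_n={top_n} exceeds {len(cand)} candidates; truncating")
        top_n = len(cand)
    order = cand[np.argsort(-scores[cand], kind="stable")][:top_n]
    return [(int(i), float(scores[i])) for i in order]


def evaluate_fold(trained: TrainedModel, test_pos: np.ndarray,
                  test_neg: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    scores = trained.scores()
    pairs = np.concatenate([test_pos, test_neg])
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
    return compute_metrics(scores[pairs[:, 0], pairs[:, 1]], labels, threshold)


def run_cross_validation(assoc: AssociationTable, ontology: DiseaseOntology,
                         plan: FoldPlan, config: TrainConfig,
                         image_embedding: ImageEmbedding | None = None,
                         disease_to_class: dict[str, str] | None = None,
                         ) -> tuple[list[MetricsReport], list[TrainedModel]]:
    reports, models = [], []
    for k in range(plan.n_folds):
        fold_cfg = _fold_config(config, k)
        trained = train_fold(assoc, ontology, plan.train_pos[k], fold_cfg,
                             image_embedding=image_embedding,
                             disease_to_class=disease_to_class,
                             forbidden_test=plan.test_pos[k])
        reports.append(evaluate_fold(trained, plan.test_pos[k],
                                     plan.test_neg(k), config.threshold))
        models.append(trained)
    return reports, models


def run_cold_start(assoc: AssociationTable, ontology: DiseaseOntology,
                   plan: ColdStartPlan, config: TrainConfig,
                   ratio: int = 1) -> list[MetricsReport]:
    reports = []
    for k in range(plan.n_folds):
        fold_cfg = _fold_config(config, k)
        trained = train_fold(assoc, ontology, plan.train_pos[k], fold_cfg,
                             forbidden_test=plan.test_pos[k])
        reports.append(evaluate_fold(trained, plan.test_pos[k],
                                     plan.test_neg(k, ratio), config.threshold))
    return reports


def ratio_sweep(plan: FoldPlan, models: list[TrainedModel],
                ratios=(1, 2, 5, 10),
                threshold: float = 0.5) -> dict[int, dict[str, tuple[float, float]]]:
    """Re-evaluate trained fold models at several negative ratios.

    Test positives are unchanged; the frozen negative ordering makes the
    1:1 evaluation identical to the default fold evaluation and larger
    ratios strict supersets of it.
    """
    out = {}
    for r in ratios:
        reports = [evaluate_fold(models[k], plan.test_pos[k],
                                 plan.test_neg(k, r), threshold)
                   for k in range(plan.n_folds)]
        out[r] = aggregate_metrics(reports)
    return out


def _fold_config(config: TrainConfig, fold: int) -> TrainConfig:
    """Per-fold sub-seed derived from the master seed."""
    from dataclasses import replace
    return replace(config, seed=int(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(100 + fold,)).generate_state(1)[0] % (2 ** 31)))
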