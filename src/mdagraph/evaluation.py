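"""Leakage-safe evaluation: cross-validation, cold-start splits, metrics,
imbalance sweeps and fold-paired significance tests.

Positive associations are partitioned into five folds; within each fold
the training association table is rebuilt from training positives only,
and test negatives are drawn from pairs unknown in the full matrix and
frozen per fold/seed so every compared method sees identical evaluation
sets.  Cold-start splits partition the *nodes* of one entity type; all
edges touching a held-out node are removed from training.  A leakage
audit (empty train/test intersection, zero training degree for held-out
nodes) is available for any plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .similarity import AssociationTable

__all__ = ["FoldPlan", "ColdStartPlan", "MetricsReport", "SignificanceReport",
           "split_five_fold", "cold_start_split", "compute_metrics",
           "aggregate_metrics", "paired_t_holm", "audit_fold_plan",
           "audit_cold_start_plan"]


def _pair_ids(edges: np.ndarray, n_disease: int) -> np.ndarray:
    edges = np.asarray(edges).reshape(-1, 2)
    return edges[:, 0] * n_disease + edges[:, 1]


@dataclass
class FoldPlan:
    n_folds: int
    train_pos: list[np.ndarray]     # per fold: (n, 2) miRNA/disease index pairs
    test_pos: list[np.ndarray]
    neg_order: list[np.ndarray]     # per fold: permuted unknown pairs, (u, 2)
    ratio: int
    seed: int
    n_mirna: int
    n_disease: int

    def test_neg(self, fold: int, ratio: int | None = None) -> np.ndarray:
        """Frozen test negatives: the first ``ratio * n_test`` of the
        fold's permuted unknown pairs, so smaller ratios are prefixes of
        larger ones and all methods see identical sets."""
        ratio = self.ratio if ratio is None else ratio
        need = ratio * len(self.test_pos[fold])
        if need > len(self.neg_order[fold]):
            raise ValueError("requested negative ratio exceeds available unknown pairs")
        return self.neg_order[fold][:need]

    def training_table(self, assoc: AssociationTable, fold: int) -> AssociationTable:
        values = np.zeros_like(assoc.values)
        tp = self.train_pos[fold]
        values[tp[:, 0], tp[:, 1]] = 1
        return AssociationTable(list(assoc.mirna_labels),
                                list(assoc.disease_labels), values)


def split_five_fold(assoc: AssociationTable, seed: int = 0, ratio: int = 1,
                    n_folds: int = 5) -> FoldPlan:
    """Seeded edge-level partition with per-fold frozen negatives."""
    pos = assoc.positive_edges()
    if len(pos) < n_folds:
        raise ValueError(f"need at least {n_folds} positive associations")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(0,)))
    perm = rng.permutation(len(pos))
    chunks = np.array_split(perm, n_folds)
    unknown = np.argwhere(assoc.values == 0)
    train_pos, test_pos, neg_order = [], [], []
    for k, chunk in enumerate(chunks):
        test = pos[np.sort(chunk)]
        train = pos[np.sort(np.concatenate([c for i, c in enumerate(chunks)
                                            if i != k]))]
        if ratio * len(test) > len(unknown):
            raise ValueError("negative ratio exceeds available unknown pairs")
        fold_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, k)))
        neg_order.append(unknown[fold_rng.permutation(len(unknown))])
        train_pos.append(train)
        test_pos.append(test)
    return FoldPlan(n_folds=n_folds, train_pos=train_pos, test_pos=test_pos,
                    neg_order=neg_order, ratio=ratio, seed=seed,
                    n_mirna=assoc.n_mirna, n_disease=assoc.n_disease)


@dataclass
class ColdStartPlan:
    entity: str                      # "mirna" | "disease"
    node_subsets: list[np.ndarray]   # disjoint node index subsets
    train_pos: list[np.ndarray]
    test_pos: list[np.ndarray]
    neg_order: list[np.ndarray]
    seed: int
    n_mirna: int
    n_disease: int

    @property
    def n_folds(self) -> int:
        return len(self.node_subsets)

    def test_neg(self, fold: int, ratio: int = 1) -> np.ndarray:
        need = ratio * len(self.test_pos[fold])
        return self.neg_order[fold][:need]

    def training_table(self, assoc: AssociationTable, fold: int) -> AssociationTable:
        values = np.zeros_like(assoc.values)
        tp = self.train_pos[fold]
        values[tp[:, 0], tp[:, 1]] = 1
        return AssociationTable(list(assoc.mirna_labels),
                                list(assoc.disease_labels), values)


def cold_start_split(assoc: AssociationTable, entity: str = "mirna",
                     seed: int = 0, n_folds: int = 5) -> ColdStartPlan:
    """Node-level split: held-out nodes contribute no training edge.

    Test negatives are unknown pairs touching a held-out node, sampled
    after the split so no training information leaks into them.
    """
    n = assoc.n_mirna if entity == "mirna" else assoc.n_disease
    col = 0 if entity == "mirna" else 1
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} {entity} nodes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    subsets = [np.sort(s) for s in np.array_split(rng.permutation(n), n_folds)]
    pos = assoc.positive_edges()
    unknown = np.argwhere(assoc.values == 0)
    train_pos, test_pos, neg_order = [], [], []
    for k, held in enumerate(subsets):
        held_set = set(held.tolist())
        is_held = np.array([e[col] in held_set for e in pos])
        train_pos.append(pos[~is_held])
        test_pos.append(pos[is_held])
        touching = np.array([e[col] in held_set for e in unknown])
        cand = unknown[touching]
        fold_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(3, k)))
        neg_order.append(cand[fold_rng.permutation(len(cand))])
    return ColdStartPlan(entity=entity, node_subsets=subsets,
                         train_pos=train_pos, test_pos=test_pos,
                         neg_order=neg_order, seed=seed,
                         n_mirna=assoc.n_mirna, n_disease=assoc.n_disease)


def write_fold_plan(path, plan: FoldPlan | ColdStartPlan,
                    ratio: int = 1) -> None:
    """Serialise a plan as a delimited edge list with fold ids and roles."""
    with open(path, "w") as fh:
        fh.write("fold\trole\tmirna\tdisease\n")
        for k in range(plan.n_folds):
            for role, edges in (("train_pos", plan.train_pos[k]),
                                ("test_pos", plan.test_pos[k]),
                                ("test_neg", plan.test_neg(k, ratio))):
                for i, j in edges:
                    fh.write(f"{k}\t{role}\t{i}\t{j}\n")


def read_fold_plan_edges(path) -> dict[tuple[int, str], np.ndarray]:
    """Read a serialised plan back as ``{(fold, role): edge array}``."""
    out: dict[tuple[int, str], list] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fold\t"):
            raise ValueError("not a fold-plan file")
        for line in fh:
            k, role, i, j = line.rstrip("\n").split("\t")
            out.setdefault((int(k), role), []).append((int(i), int(j)))
    return {key: np.asarray(v) for key, v in out.items()}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    auc: float
    auprc: float
    acc: float
    f1: float
    recall: float
    precision: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Threshold-free (AUC, AUPRC) and thresholded classification metrics.

    AUC is the tie-averaged rank statistic (Mann-Whitney); AUPRC is the
    step-wise integral of the precision-recall curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    auc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0
    return MetricsReport(auc=auc, auprc=auprc, acc=acc, f1=f1, recall=recall,
                         precision=precision, threshold=threshold,
                         tp=tp, fp=fp, tn=tn, fn=fn)


def aggregate_metrics(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean +/- SD across folds for every metric."""
    out = {}
    for name in ("auc", "auprc", "acc", "f1", "recall", "precision"):
        vals = np.array([getattr(r, name) for r in reports])
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceReport:
    baselines: list[str]
    deltas: dict[str, np.ndarray]
    raw_p: dict[str, float]
    adjusted_p: dict[str, float]
    degenerate: dict[str, bool]


def paired_t_holm(fold_scores: dict[str, np.ndarray],
                  reference: np.ndarray) -> SignificanceReport:
    """Two-sided paired t-tests against a reference, Holm-adjusted.

    Zero-variance differences: p = 1 when all fold differences are zero;
    otherwise the comparison is flagged degenerate (p reported as NaN)
    rather than yielding an infinite statistic.
    """
    reference = np.asarray(reference, dtype=float)
    baselines = list(fold_scores)
    deltas, raw, degen = {}, {}, {}
    for name in baselines:
        other = np.asarray(fold_scores[name], dtype=float)
        if other.shape != reference.shape:
            raise ValueError("fold vectors must share the reference's length")
        d = reference - other
        deltas[name] = d
        if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
            if np.allclose(d, 0.0):
                raw[name] = 1.0
                degen[name] = False
            else:
                raw[name] = float("nan")
                degen[name] = True
        else:
            raw[name] = float(stats.ttest_rel(reference, other).pvalue)
            degen[name] = False
    valid = [b for b in baselines if not degen[b]]
    adjusted = {b: float("nan") for b in baselines}
    if valid:
        _, adj, _, _ = multipletests([raw[b] for b in valid], method="holm")
        for b, p in zip(valid, adj):
            adjusted[b] = float(p)
    return SignificanceReport(baselines=baselines, deltas=deltas, raw_p=raw,
                              adjusted_p=adjusted, degenerate=degen)


# ---------------------------------------------------------------------------
# Leakage audits
# ---------------------------------------------------------------------------

def audit_fold_plan(plan: FoldPlan, assoc: AssociationTable) -> None:
    """Raise if any fold leaks: train/test overlap, bad partition, or
    negatives colliding with known positives."""
    all_pos = set(_pair_ids(assoc.positive_edges(), plan.n_disease).tolist())
    seen_test: set[int] = set()
    for k in range(plan.n_folds):
        train = set(_pair_ids(plan.train_pos[k], plan.n_disease).tolist())
        test = set(_pair_ids(plan.test_pos[k], plan.n_disease).tolist())
        if train & test:
            raise AssertionError(f"fold {k}: train/test positive overlap")
        if (train | test) != all_pos:
            raise AssertionError(f"fold {k}: folds do not partition the positives")
        if seen_test & test:
            raise AssertionError(f"fold {k}: test folds overlap")
        seen_test |= test
        neg = set(_pair_ids(plan.test_neg(k), plan.n_disease).tolist())
        if neg & all_pos:
            raise AssertionError(f"fold {k}: negative sampled from known positives")
    if seen_test != all_pos:
        raise AssertionError("union of test folds misses positives")


def audit_cold_start_plan(plan: ColdStartPlan, assoc: AssociationTable) -> None:
    """Raise if any held-out node has nonzero training degree or the
    node subsets fail to partition the entity set."""
    col = 0 if plan.entity == "mirna" else 1
    n = plan.n_mirna if plan.entity == "mirna" else plan.n_disease
    all_nodes = np.sort(np.concatenate(plan.node_subsets))
    if not np.array_equal(all_nodes, np.arange(n)):
        raise AssertionError("node subsets do not partition the node set")
    for k, held in enumerate(plan.node_subsets):
        held_set = set(held.tolist())
        for e in plan.train_pos[k]:
            if e[col] in held_set:
                raise AssertionError(
                    f"fold {k}: training edge touches held-out node {e[col]}")
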