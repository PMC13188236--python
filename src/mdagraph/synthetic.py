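"""Synthetic data with the statistical structure the model assumes.

Three generators mirror the real inputs end to end:

* a planted low-rank bipartite association matrix — latent factors for
  miRNAs and diseases, association probabilities through a sigmoid with
  a bias calibrated by bisection to a target density, Bernoulli labels
  with a fraction of true associations masked to zero (the ground-truth
  probabilities are returned so recovery and positive-unlabeled
  behaviour can be studied);
* a single-rooted disease-term DAG whose hierarchy clusters the same
  latent disease factors, with diseases mapped to leaf terms;
* class-dependent smoothed-noise ("Gaussian blob") texture images large
  enough to supply the full three-scale patch-sampling protocol.

All generators derive independent sub-streams from the master seed via
``SeedSequence`` spawn keys, so each output is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .similarity import AssociationTable, DiseaseOntology

__all__ = ["SyntheticSpec", "make_association", "make_ontology", "make_images"]


@dataclass
class SyntheticSpec:
    n_mirna: int = 150
    n_disease: int = 100
    latent_rank: int = 5
    density: float = 0.08
    noise: float = 0.02          # label-flip probability
    scale: float = 3.0           # logit scale on the latent factor product
    n_image_classes: int = 5
    # Large enough that the coarsest (512 px, stride 256) tiling yields
    # >= 300 candidate windows per class from a single source image.
    image_size: int = 4864
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if self.latent_rank < 1:
            raise ValueError("latent rank must be >= 1")

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=key))


def _calibrate_bias(logits: np.ndarray, density: float,
                    tol: float = 1e-10) -> float:
    lo, hi = -60.0, 60.0
    if not np.mean(1 / (1 + np.exp(-(logits + lo)))) < density < \
            np.mean(1 / (1 + np.exp(-(logits + hi)))):
        raise ValueError("unattainable density target")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.mean(1 / (1 + np.exp(-(logits + mid)))) < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_association(spec: SyntheticSpec):
    """Planted low-rank association matrix plus its ground truth.

    Returns ``(AssociationTable, true_probability_matrix)``.
    """
    rng = spec.rng(0)
    u = rng.standard_normal((spec.n_mirna, spec.latent_rank))
    v = rng.standard_normal((spec.n_disease, spec.latent_rank))
    logits = spec.scale * (u @ v.T)
    # Curated association databases are positive-unlabeled: recorded
    # associations are reliable, the noise is *missing* ones.  The flip
    # therefore masks true associations (1 -> 0) with the given
    # probability; the pre-mask Bernoulli rate is calibrated so the
    # observed density matches the target.
    target = spec.density / (1.0 - spec.noise)
    if not 0 < target < 1:
        raise ValueError("density target unattainable at this noise level")
    bias = _calibrate_bias(logits, target)
    probs = 1.0 / (1.0 + np.exp(-(logits + bias)))
    labels = (rng.random(probs.shape) < probs).astype(np.int8)
    if spec.noise > 0:
        masked = (rng.random(probs.shape) < spec.noise) & (labels == 1)
        labels = np.where(masked, 0, labels)
    table = AssociationTable(
        mirna_labels=[f"mir-{i:04d}" for i in range(spec.n_mirna)],
        disease_labels=[f"disease-{j:04d}" for j in range(spec.n_disease)],
        values=labels)
    return table, probs


def make_ontology(spec: SyntheticSpec) -> DiseaseOntology:
    """Single-rooted DAG whose hierarchy follows the latent disease factors.

    Real ontology-based semantic similarity is informative about
    association patterns (related diseases share miRNA programs), so the
    synthetic term hierarchy is built by agglomerative clustering of the
    same latent disease factors that generate the association matrix:
    each disease maps to a leaf term, every cluster merge becomes an
    internal term, and the final merge is the single root.  A fraction
    of leaves additionally attach to their grandparent term, so the
    result is a genuine DAG (1-2 parents per term) rather than a tree.
    """
    if spec.n_disease < 1:
        raise ValueError("need at least one disease")
    d = spec.n_disease
    if d == 1:
        return DiseaseOntology(terms={"T-root"}, edges=[],
                               disease_to_term={"disease-0000": "T-root"})
    # same latent factors as make_association (same sub-seed, same order)
    rng0 = spec.rng(0)
    rng0.standard_normal((spec.n_mirna, spec.latent_rank))  # U, discarded
    v = rng0.standard_normal((d, spec.latent_rank))
    from scipy.cluster.hierarchy import linkage

    merges = linkage(v, method="ward")
    leaf = [f"TL{j:04d}" for j in range(d)]
    internal = [f"TI{k:04d}" for k in range(d - 1)]

    def name(node_id: int) -> str:
        return leaf[node_id] if node_id < d else internal[node_id - d]

    edges: list[tuple[str, str]] = []
    parent_of: dict[str, str] = {}
    for k, (a, b, *_rest) in enumerate(merges):
        for child in (name(int(a)), name(int(b))):
            edges.append((child, internal[k]))
            parent_of[child] = internal[k]
    rng = spec.rng(1)
    for j in range(d):  # diamonds: some leaves also attach to a grandparent
        p = parent_of.get(leaf[j])
        gp = parent_of.get(p) if p else None
        if gp is not None and rng.random() < 0.3:
            edges.append((leaf[j], gp))
    disease_labels = [f"disease-{j:04d}" for j in range(d)]
    mapping = {dl: leaf[j] for j, dl in enumerate(disease_labels)}
    return DiseaseOntology(terms=set(leaf) | set(internal), edges=edges,
                           disease_to_term=mapping)


def _class_texture(rng: np.random.Generator, size: int, cls: int) -> np.ndarray:
    # class identity is carried by blob scale and mean intensity; the
    # intensity spacing is wide relative to the texture amplitude so
    # even small patches are attributable to their class
    sigma = 2.0 + 4.0 * (cls % 5)
    base = 0.12 + 0.18 * (cls % 5)
    noise = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma)
    noise /= max(np.abs(noise).max(), 1e-12)
    img = np.clip(base + 0.08 * noise, 0.0, 1.0)
    return (img * 255).astype(np.uint8)


def make_images(spec: SyntheticSpec, out_dir: str | Path,
                images_per_class: int = 1) -> dict[str, list[Path]]:
    """Write class-dependent texture images under ``<class>/<image>.png``."""
    if spec.n_image_classes < 1:
        raise ValueError("need at least one image class")
    out_dir = Path(out_dir)
    written: dict[str, list[Path]] = {}
    for c in range(spec.n_image_classes):
        cls = f"class-{c}"
        cls_dir = out_dir / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        written[cls] = []
        for k in range(images_per_class):
            rng = spec.rng(2, c, k)
            img = _class_texture(rng, spec.image_size, c)
            path = cls_dir / f"img_{k}.png"
            Image.fromarray(img, mode="L").save(path)
            written[cls].append(path)
    return written


def make_images_arrays(spec: SyntheticSpec,
                       images_per_class: int = 1) -> dict[str, dict[str, np.ndarray]]:
    """In-memory variant of :func:`make_images` (same seeded content)."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for c in range(spec.n_image_classes):
        cls = f"class-{c}"
        out[cls] = {}
        for k in range(images_per_class):
            rng = spec.rng(2, c, k)
            out[cls][f"img_{k}.png"] = _class_texture(rng, spec.image_size, c)
    return out
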