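"""Histopathology feature branch: tiling, sampling, encoding, fusion.

Source images for a disease class are tiled with a sliding window at
three scales (512, 256 and 16 pixels, each at 50% overlap by default),
a fixed number of patches per scale is sampled, and each patch is
encoded to a fixed-width vector by a pluggable backbone.  The default
backbone is a seeded random linear projection of 32x32-downsampled
grayscale pixels — deterministic and dependency-free; a pretrained CNN
can be dropped in through the same contract (patch array -> vector).

Scale fusion uses single-head cross-attention with the 512-scale
features as queries against the finer scales as keys/values; the
attention outputs and the raw 512-scale features are pooled and
averaged into one vector per class, which a trainable linear layer
later projects to the image-feature width.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from PIL import Image

from .graphs import FeatureMatrix

__all__ = ["PatchSpec", "PatchSet", "ScaleFeatures", "ImageEmbedding",
           "DEFAULT_SPECS", "tile_image", "sample_patches", "StubBackbone",
           "encode_patches", "cross_attention", "fuse_scales",
           "assign_image_features", "extract_class_features"]


@dataclass(frozen=True)
class PatchSpec:
    scale: int
    stride: int

    def __post_init__(self) -> None:
        if not 1 <= self.stride <= self.scale:
            raise ValueError("stride must satisfy 1 <= stride <= scale")


# 50% overlap at every scale: strides 256 / 128 / 8.
DEFAULT_SPECS = (PatchSpec(512, 256), PatchSpec(256, 128), PatchSpec(16, 8))


@dataclass
class PatchSet:
    disease_class: str
    scale: int
    patches: list[tuple[str, int, int]]  # (image id, x origin, y origin)

    @property
    def count(self) -> int:
        return len(self.patches)


@dataclass
class ScaleFeatures:
    features: dict[int, np.ndarray]  # scale -> (n_patches, width)

    def __post_init__(self) -> None:
        widths = {f.shape[1] for f in self.features.values()}
        if len(widths) > 1:
            raise ValueError("backbone output width inconsistent across scales")


@dataclass
class ImageEmbedding:
    class_vectors: dict[str, np.ndarray]  # disease class -> pooled feature
    width: int


def _axis_origins(length: int, scale: int, stride: int) -> list[int]:
    # regular grid plus a final window flush with the border when the
    # last regular origin does not reach it; windows are half-open
    # [x, x + scale) in 0-based pixel coordinates
    origins = list(range(0, length - scale + 1, stride))
    if origins and origins[-1] != length - scale:
        origins.append(length - scale)
    return origins


def tile_image(image: np.ndarray, spec: PatchSpec,
               image_id: str = "img", disease_class: str = "") -> PatchSet:
    """Enumerate sliding-window origins for one image at one scale."""
    h, w = np.asarray(image).shape[:2]
    if h < spec.scale or w < spec.scale:
        warnings.warn(f"image {image_id!r} ({h}x{w}) smaller than scale "
                      f"{spec.scale}; no patches produced")
        return PatchSet(disease_class=disease_class, scale=spec.scale, patches=[])
    patches = [(image_id, x, y)
               for y in _axis_origins(h, spec.scale, spec.stride)
               for x in _axis_origins(w, spec.scale, spec.stride)]
    return PatchSet(disease_class=disease_class, scale=spec.scale, patches=patches)


def sample_patches(candidates: PatchSet, n_per_scale: int,
                   rng: np.random.Generator) -> PatchSet:
    """Seeded uniform sample without replacement from a candidate pool."""
    if n_per_scale < 1:
        raise ValueError("n_per_scale must be >= 1")
    if candidates.count <= n_per_scale:
        if candidates.count < n_per_scale:
            warnings.warn(f"only {candidates.count} candidates at scale "
                          f"{candidates.scale}; taking all")
        chosen = list(candidates.patches)
    else:
        idx = rng.choice(candidates.count, size=n_per_scale, replace=False)
        chosen = [candidates.patches[i] for i in sorted(idx)]
    return PatchSet(disease_class=candidates.disease_class,
                    scale=candidates.scale, patches=chosen)


class StubBackbone:
    """Seeded random-projection patch encoder.

    Downsamples a patch to 32x32 grayscale by block averaging and maps
    the flattened pixels through a fixed random matrix to a 512-wide
    vector.  Deterministic in eval mode by construction.
    """

    def __init__(self, out_dim: int = 512, seed: int = 0, grid: int = 32):
        self.out_dim = out_dim
        self.grid = grid
        rng = np.random.default_rng(seed)
        self.weight = rng.standard_normal((grid * grid, out_dim)) / np.sqrt(grid * grid)

    def _downsample(self, patch: np.ndarray) -> np.ndarray:
        p = np.asarray(patch, dtype=float)
        if p.ndim == 3:
            p = p.mean(axis=2)
        h, w = p.shape
        g = self.grid
        if h < g or w < g:
            # upsample tiny patches by repetition so the grid is filled
            p = np.kron(p, np.ones(((g + h - 1) // h, (g + w - 1) // w)))
            h, w = p.shape
        bh, bw = h // g, w // g
        p = p[:bh * g, :bw * g].reshape(g, bh, g, bw).mean(axis=(1, 3))
        return p

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self._downsample(patch).ravel() @ self.weight


def encode_patches(patches: PatchSet, images: Mapping[str, np.ndarray],
                   backbone: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Encode every patch of a set; one feature row per patch."""
    rows = []
    width = None
    for image_id, x, y in patches.patches:
        img = np.asarray(images[image_id])
        s = patches.scale
        vec = np.asarray(backbone(img[y:y + s, x:x + s]))
        if width is None:
            width = vec.shape[0]
        elif vec.shape[0] != width:
            raise ValueError("backbone output width inconsistent")
        rows.append(vec)
    return np.asarray(rows) if rows else np.zeros((0, 0))


def cross_attention(query: np.ndarray, key: np.ndarray,
                    value: np.ndarray) -> np.ndarray:
    """Single-head scaled dot-product attention.

    Rows of the output are convex combinations of the value rows with
    row-stochastic softmax weights.
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (query, key, value))
    if k.shape[0] == 0:
        raise ValueError("empty key set")
    if k.shape[0] != v.shape[0]:
        raise ValueError("key and value must be row-aligned")
    logits = q @ k.T / np.sqrt(q.shape[1])
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    return w @ v


def fuse_scales(scale_features: ScaleFeatures,
                projection: np.ndarray | None = None) -> np.ndarray:
    """Pool multi-scale features into one vector per class.

    The coarsest-scale features (512 by default) query each finer scale
    separately; the attention outputs and the raw query features are
    each pooled by a mean over patch rows, averaged across the scale
    axis, and (when a projection is supplied) linearly mapped to the
    image-feature width.  Scales missing from the input (e.g. source
    images smaller than the patch size) simply drop out of the average.
    """
    present = {s: f for s, f in scale_features.features.items() if f.size > 0}
    if not present:
        raise ValueError("no non-empty scale features to fuse")
    q_scale = max(present)
    fq = present[q_scale]
    pooled = [fq.mean(axis=0)]
    for scale in sorted((s for s in present if s != q_scale), reverse=True):
        att = cross_attention(fq, present[scale], present[scale])
        pooled.append(att.mean(axis=0))
    fused = np.mean(pooled, axis=0)
    if projection is not None:
        fused = fused @ np.asarray(projection)
    return fused


def assign_image_features(embeddings: ImageEmbedding,
                          diseases: Sequence[str],
                          null_embedding: np.ndarray,
                          disease_to_class: Mapping[str, str] | None = None,
                          ) -> FeatureMatrix:
    """Per-disease image-feature matrix.

    Diseases with imagery receive their class vector; every other
    disease receives the shared (trainable) null embedding.
    """
    disease_to_class = disease_to_class or {}
    rows = []
    for d in diseases:
        cls = disease_to_class.get(d, d)
        vec = embeddings.class_vectors.get(cls)
        rows.append(np.asarray(vec) if vec is not None else np.asarray(null_embedding))
    return FeatureMatrix(list(diseases), np.asarray(rows), source="image")


def write_patch_manifest(path: str | os.PathLike,
                         patch_sets: list[PatchSet]) -> None:
    """Delimited manifest of sampled patches: image id, x, y, scale."""
    with open(path, "w") as fh:
        fh.write("image_id\tx\ty\tscale\n")
        for ps in patch_sets:
            for image_id, x, y in ps.patches:
                fh.write(f"{image_id}\t{x}\t{y}\t{ps.scale}\n")


def load_class_images(root: str | os.PathLike) -> dict[str, dict[str, np.ndarray]]:
    """Load ``<class>/<image>.png`` directories into arrays."""
    root = Path(root)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        imgs = {}
        for f in sorted(cls_dir.rglob("*")):
            if f.suffix.lower() in (".png", ".tif", ".tiff"):
                imgs[str(f.relative_to(cls_dir))] = np.asarray(Image.open(f))
        if imgs:
            out[cls_dir.name] = imgs
    return out


def extract_class_features(images_by_class: Mapping[str, Mapping[str, np.ndarray]],
                           specs: Sequence[PatchSpec] = DEFAULT_SPECS,
                           n_per_scale: int = 300,
                           seed: int = 0,
                           backbone: Callable | None = None,
                           ) -> tuple[ImageEmbedding, dict[str, dict[int, PatchSet]]]:
    """Tile, sample, encode and fuse: one pooled vector per disease class.

    Returns the per-class embeddings (pre-projection) and the sampled
    patch manifests keyed by class and scale.
    """
    backbone = backbone or StubBackbone()
    class_vectors: dict[str, np.ndarray] = {}
    manifests: dict[str, dict[int, PatchSet]] = {}
    for ci, (cls, imgs) in enumerate(sorted(images_by_class.items())):
        feats: dict[int, np.ndarray] = {}
        manifests[cls] = {}
        for si, spec in enumerate(specs):
            pool = PatchSet(disease_class=cls, scale=spec.scale, patches=[])
            for image_id in sorted(imgs):
                pool.patches.extend(
                    tile_image(imgs[image_id], spec, image_id=image_id,
                               disease_class=cls).patches)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, si)))
            sampled = sample_patches(pool, n_per_scale, rng) if pool.count else pool
            manifests[cls][spec.scale] = sampled
            if sampled.count:
                feats[spec.scale] = encode_patches(sampled, imgs, backbone)
        class_vectors[cls] = fuse_scales(ScaleFeatures(features=feats))
    width = len(next(iter(class_vectors.values()))) if class_vectors else 0
    return ImageEmbedding(class_vectors=class_vectors, width=width), manifests
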