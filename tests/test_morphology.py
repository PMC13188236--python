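"""Patch tiling, sampling, encoding and cross-attention fusion."""

import numpy as np
import pytest

from mdagraph.morphology import (DEFAULT_SPECS, ImageEmbedding, PatchSet,
                                 PatchSpec, ScaleFeatures, StubBackbone,
                                 assign_image_features, cross_attention,
                                 encode_patches, extract_class_features,
                                 fuse_scales, sample_patches, tile_image)


class TestTiling:
    def test_default_strides_follow_half_overlap(self):
        by_scale = {s.scale: s.stride for s in DEFAULT_SPECS}
        assert by_scale[256] == 128
        assert by_scale[16] == 8
        assert by_scale[512] == 256

    def test_three_by_three_grid(self):
        img = np.zeros((512, 512))
        ps = tile_image(img, PatchSpec(256, 128))
        assert ps.count == 9
        # brute-force window enumeration oracle
        expect = {(x, y) for x in (0, 128, 256) for y in (0, 128, 256)}
        assert {(x, y) for _, x, y in ps.patches} == expect

    def test_flush_border_window_added(self):
        img = np.zeros((300, 300))
        ps = tile_image(img, PatchSpec(256, 128))
        origins = sorted({x for _, x, _ in ps.patches})
        assert origins == [0, 44]  # 300 - 256 = 44 flush origin

    def test_windows_never_cross_borders_and_cover(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            h = int(rng.integers(16, 90))
            w = int(rng.integers(16, 90))
            spec = PatchSpec(16, int(rng.integers(1, 17)))
            ps = tile_image(np.zeros((h, w)), spec)
            covered = np.zeros((h, w), dtype=bool)
            for _, x, y in ps.patches:
                assert 0 <= x <= w - 16 and 0 <= y <= h - 16
                covered[y:y + 16, x:x + 16] = True
            assert covered.all()

    def test_too_small_image_warns_empty(self):
        with pytest.warns(UserWarning, match="smaller than scale"):
            ps = tile_image(np.zeros((8, 8)), PatchSpec(16, 8))
        assert ps.count == 0

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            PatchSpec(16, 0)
        with pytest.raises(ValueError):
            PatchSpec(16, 17)


class TestSampling:
    def _pool(self, n):
        return PatchSet("c", 16, [("img", 8 * i, 0) for i in range(n)])

    def test_seeded_sample_is_deterministic(self):
        pool = self._pool(100)
        a = sample_patches(pool, 10, np.random.default_rng(3))
        b = sample_patches(pool, 10, np.random.default_rng(3))
        assert a.patches == b.patches
        assert a.count == 10

    def test_small_pool_taken_whole_with_warning(self):
        with pytest.warns(UserWarning, match="taking all"):
            out = sample_patches(self._pool(4), 10, np.random.default_rng(0))
        assert out.count == 4

    def test_sample_without_replacement(self):
        out = sample_patches(self._pool(50), 30, np.random.default_rng(1))
        assert len(set(out.patches)) == 30


class TestBackboneAndAttention:
    def test_stub_backbone_deterministic(self):
        bb = StubBackbone(out_dim=32, seed=5)
        patch = np.full((64, 64), 128.0)
        assert np.array_equal(bb(patch), bb(patch))
        assert bb(patch).shape == (32,)

    def test_stub_backbone_matches_hand_projection(self):
        # 2x2 grayscale patch is upsampled to the 32-grid by repetition,
        # so the projection sees each pixel repeated over a 16x16 block
        bb = StubBackbone(out_dim=8, seed=0)
        patch = np.array([[1.0, 2.0], [3.0, 4.0]])
        grid = np.kron(patch, np.ones((16, 16)))
        expect = grid.ravel() @ bb.weight
        assert np.allclose(bb(patch), expect)

    def test_encode_patches_row_count(self):
        img = np.arange(32 * 32, dtype=float).reshape(32, 32)
        ps = tile_image(img, PatchSpec(16, 8), image_id="i")
        feats = encode_patches(ps, {"i": img}, StubBackbone(out_dim=16))
        assert feats.shape == (ps.count, 16)

    def test_single_key_returns_value_row(self):
        q = np.random.default_rng(0).standard_normal((4, 3))
        k = np.array([[1.0, 0.0, 0.0]])
        v = np.array([[7.0, -2.0, 3.0]])
        out = cross_attention(q, k, v)
        assert np.allclose(out, np.tile(v, (4, 1)))

    def test_identical_values_collapse(self):
        rng = np.random.default_rng(1)
        v = np.tile([2.0, 5.0], (6, 1))
        out = cross_attention(rng.standard_normal((3, 2)),
                              rng.standard_normal((6, 2)), v)
        assert np.allclose(out, np.tile([2.0, 5.0], (3, 1)))

    def test_two_key_hand_softmax(self):
        q = np.array([[1.0]])
        k = np.array([[2.0], [-1.0]])
        v = np.array([[10.0], [20.0]])
        logits = np.array([2.0, -1.0])  # d = 1 so sqrt(d) = 1
        w = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(cross_attention(q, k, v), [[w @ v.ravel()]])

    def test_attention_rows_stochastic_and_convex(self):
        rng = np.random.default_rng(2)
        q, k = rng.standard_normal((5, 4)), rng.standard_normal((7, 4))
        v = rng.standard_normal((7, 4))
        out = cross_attention(q, k, v)
        assert np.all(out >= v.min(axis=0) - 1e-9)
        assert np.all(out <= v.max(axis=0) + 1e-9)

    def test_empty_keys_raise(self):
        with pytest.raises(ValueError, match="empty key"):
            cross_attention(np.ones((1, 2)), np.zeros((0, 2)), np.zeros((0, 2)))


class TestScaleFusion:
    def test_mean_then_projection(self):
        f = {512: np.tile([1.0, 3.0], (4, 1)),
             256: np.tile([1.0, 3.0], (5, 1)),
             16: np.tile([1.0, 3.0], (6, 1))}
        fused = fuse_scales(ScaleFeatures(features=f))
        assert np.allclose(fused, [1.0, 3.0])
        proj = fuse_scales(ScaleFeatures(features=f), projection=2 * np.eye(2))
        assert np.allclose(proj, [2.0, 6.0])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        f = {512: rng.standard_normal((3, 4)),
             256: rng.standard_normal((5, 4)),
             16: rng.standard_normal((6, 4))}
        fused = fuse_scales(ScaleFeatures(features=f))
        pooled = [f[512].mean(axis=0),
                  cross_attention(f[512], f[256], f[256]).mean(axis=0),
                  cross_attention(f[512], f[16], f[16]).mean(axis=0)]
        assert np.allclose(fused, np.mean(pooled, axis=0))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            ScaleFeatures(features={512: np.ones((2, 4)), 16: np.ones((2, 3))})


class TestAssignImageFeatures:
    def test_imaged_vs_null(self):
        emb = ImageEmbedding(class_vectors={"c0": np.array([1.0, 2.0])}, width=2)
        null = np.array([9.0, 9.0])
        fm = assign_image_features(emb, ["dA", "dB"], null,
                                   disease_to_class={"dA": "c0"})
        assert np.allclose(fm.values[0], [1.0, 2.0])
        assert np.allclose(fm.values[1], null)

    def test_permutation_audit(self):
        rng = np.random.default_rng(4)
        classes = {f"c{i}": rng.standard_normal(3) for i in range(4)}
        emb = ImageEmbedding(class_vectors=classes, width=3)
        diseases = [f"d{i}" for i in range(4)]
        mapping = {d: f"c{i}" for i, d in enumerate(diseases)}
        perm = rng.permutation(4)
        shuffled = {d: f"c{perm[i]}" for i, d in enumerate(diseases)}
        a = assign_image_features(emb, diseases, np.zeros(3), mapping).values
        b = assign_image_features(emb, diseases, np.zeros(3), shuffled).values
        # every class vector still appears exactly once after the shuffle
        assert sorted(map(tuple, a)) == sorted(map(tuple, b))


def test_patch_manifest_written_as_delimited_text(tmp_path):
    from mdagraph.morphology import write_patch_manifest
    ps = PatchSet("c0", 16, [("img_0.png", 0, 8), ("img_0.png", 8, 8)])
    path = tmp_path / "manifest.tsv"
    write_patch_manifest(path, [ps])
    lines = path.read_text().splitlines()
    assert lines[0] == "image_id\tx\ty\tscale"
    assert lines[1] == "img_0.png\t0\t8\t16"
    assert len(lines) == 3


def test_morphology_branch_end_to_end_on_tiny_images(tiny_spec):
    """64x64 source images: only the 16 px scale tiles; the branch still
    produces one embedding per class."""
    from mdagraph.synthetic import make_images_arrays
    imgs = make_images_arrays(tiny_spec)
    with pytest.warns(UserWarning):
        emb, manifests = extract_class_features(imgs, n_per_scale=40, seed=0)
    assert set(emb.class_vectors) == {"class-0", "class-1"}
    for cls in emb.class_vectors:
        assert np.isfinite(emb.class_vectors[cls]).all()
        assert manifests[cls][16].count == 40
        assert manifests[cls][512].count == 0
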