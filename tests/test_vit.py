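"""Multi-scale windowed-attention transformer tests."""

import numpy as np
import pytest

from acovit.vit import (
    ModelConfig,
    PatchGrid,
    ViTClassifier,
    content_weights,
    count_attention_pairs,
    embed_multiscale,
    extract_patches,
    forward_classify,
    init_params,
    neighbor_table,
    neighborhood,
    windowed_attention,
)


def tiny_config(**kw):
    base = dict(scales=(8, 16), d=32, heads=4, blocks=2, window_radius=1,
                dense_neurons=64, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestPatches:
    def test_exact_tiling(self):
        img = np.arange(64).reshape(8, 8) / 64.0
        patches, grid = extract_patches(img, 4)
        assert grid.rows == grid.cols == 2 and len(patches) == 4
        np.testing.assert_array_equal(patches[0], img[:4, :4])
        np.testing.assert_array_equal(patches[3], img[4:, 4:])

    def test_reflect_padding_matches_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.random((6, 6))
        patches, grid = extract_patches(img, 4)
        padded = np.pad(img, ((0, 2), (0, 2)), mode="reflect")
        assert (grid.rows, grid.cols) == (2, 2)
        reassembled = np.block(
            [[patches[0], patches[1]], [patches[2], patches[3]]]
        )
        np.testing.assert_array_equal(reassembled, padded)

    def test_patch_size_equal_to_image(self):
        img = np.random.default_rng(1).random((8, 8))
        patches, grid = extract_patches(img, 8)
        assert grid.token_count == 1
        np.testing.assert_array_equal(patches[0], img)


class TestEmbedding:
    def test_token_count_formula(self):
        cfg = ModelConfig(scales=(4, 8), d=16, heads=2, dense_neurons=8, seed=0)
        img = np.random.default_rng(0).random((16, 16))
        emb = embed_multiscale(img, cfg)
        assert [t.shape[0] for t in emb.tokens] == [16, 4]
        assert emb.token_count == 20

    def test_single_whole_image_scale(self):
        cfg = ModelConfig(scales=(16,), d=8, heads=2, dense_neurons=8, seed=0)
        emb = embed_multiscale(np.zeros((16, 16)), cfg)
        assert emb.token_count == 1

    def test_all_tokens_have_dimension_d(self):
        cfg = tiny_config()
        emb = embed_multiscale(np.zeros((64, 64)), cfg)
        assert all(t.shape[1] == cfg.d for t in emb.tokens)


class TestNeighborhood:
    def test_interior_full_window(self):
        grid = PatchGrid((1, 1), 5, 5)
        assert len(neighborhood(12, grid, 1)) == 9

    def test_corner_matches_enumeration(self):
        grid = PatchGrid((1, 1), 4, 4)
        nb = set(neighborhood(0, grid, 1).tolist())
        brute = {
            i for i in range(16)
            if max(abs(i // 4 - 0), abs(i % 4 - 0)) <= 1
        }
        assert nb == brute

    def test_large_radius_covers_grid(self):
        grid = PatchGrid((1, 1), 3, 4)
        assert len(neighborhood(5, grid, 4)) == 12

    @pytest.mark.parametrize("r,expected", [(0, 16), (1, 100), (4, 256)])
    def test_pair_counts(self, r, expected):
        grid = PatchGrid((1, 1), 4, 4)
        assert count_attention_pairs(grid, r) == expected
        assert count_attention_pairs(grid, r) <= grid.token_count * (2 * r + 1) ** 2

    def test_pair_count_linear_in_tokens_at_fixed_radius(self):
        for n in (4, 8, 16):
            grid = PatchGrid((1, 1), n, n)
            assert count_attention_pairs(grid, 1) <= grid.token_count * 9


class TestContentWeights:
    def test_constant_patch_zero(self):
        patches = np.stack([np.full((4, 4), 0.5), np.random.default_rng(0).random((4, 4))])
        w = content_weights(patches)
        assert w[0] == 0.0 and w[1] == 1.0

    def test_two_variances_map_to_zero_one(self):
        lo = np.zeros((2, 2))
        lo[0, 0] = 0.2  # var 0.01
        hi = np.zeros((2, 2))
        hi[0, 0] = 0.4  # var 0.04
        w = content_weights(np.stack([lo, hi]))
        np.testing.assert_allclose(w, [0.0, 1.0])

    def test_identical_patches_all_zero(self):
        patches = np.stack([np.eye(3) * 0.5] * 4)
        np.testing.assert_array_equal(content_weights(patches), 0.0)


class TestWindowedAttention:
    def test_matches_dense_attention_when_window_covers_grid(self):
        rng = np.random.default_rng(0)
        n, d, heads = 16, 32, 4
        tokens = rng.normal(size=(n, d))
        grid = PatchGrid((4, 4), 4, 4)
        window = neighbor_table(grid, 4)
        params = {
            f"{nm}_{sfx}": (rng.normal(0, 0.1, size=(d, d)) if sfx == "w"
                            else rng.normal(0, 0.1, size=d))
            for nm in ("q", "k", "v", "proj") for sfx in ("w", "b")
        }
        out = windowed_attention(
            tokens, window, np.zeros((heads, window.table_size)),
            rng.random(n), heads, gamma=0.0, params=params,
        )
        dh = d // heads
        q = (tokens @ params["q_w"] + params["q_b"]).reshape(n, heads, dh).transpose(1, 0, 2)
        k = (tokens @ params["k_w"] + params["k_b"]).reshape(n, heads, dh).transpose(1, 0, 2)
        v = (tokens @ params["v_w"] + params["v_b"]).reshape(n, heads, dh).transpose(1, 0, 2)
        logits = q @ k.transpose(0, 2, 1) / np.sqrt(dh)
        a = np.exp(logits - logits.max(-1, keepdims=True))
        a /= a.sum(-1, keepdims=True)
        dense = (a @ v).transpose(1, 0, 2).reshape(n, d) @ params["proj_w"] + params["proj_b"]
        assert np.abs(out - dense).max() < 1e-5

    def test_identical_keys_give_uniform_attention(self):
        # with P == 0, gamma == 0 and all-equal keys, attention averages values
        rng = np.random.default_rng(2)
        n, d, heads = 9, 8, 2
        grid = PatchGrid((1, 1), 3, 3)
        window = neighbor_table(grid, 3)
        tokens = rng.normal(size=(n, d))
        eye = np.eye(d)
        params = {
            "q_w": eye * 0.0, "q_b": np.zeros(d),
            "k_w": eye * 0.0, "k_b": np.ones(d),  # identical keys
            "v_w": eye, "v_b": np.zeros(d),
            "proj_w": eye, "proj_b": np.zeros(d),
        }
        out = windowed_attention(
            tokens, window, np.zeros((heads, window.table_size)),
            np.zeros(n), heads, gamma=0.0, params=params,
        )
        np.testing.assert_allclose(out, np.broadcast_to(tokens.mean(0), (n, d)), atol=1e-10)

    def test_mismatched_content_weights_rejected(self):
        grid = PatchGrid((1, 1), 2, 2)
        window = neighbor_table(grid, 1)
        with pytest.raises(ValueError, match="content weights"):
            windowed_attention(
                np.zeros((4, 8)), window, np.zeros((2, 9)), np.zeros(3), 2
            )

    def test_relative_bias_translation_invariance(self):
        # same displacement -> same bias-table entry, away from borders
        grid = PatchGrid((1, 1), 6, 6)
        window = neighbor_table(grid, 1)
        i, shifted = 7, 7 + 6 + 1  # interior token and its diagonal translate
        np.testing.assert_array_equal(
            window.offset_index[i], window.offset_index[shifted]
        )


class TestForwardClassify:
    def test_probabilities_valid_and_sum_to_one(self):
        cfg = tiny_config()
        img = np.random.default_rng(0).random((64, 64))
        probs = forward_classify(img, None, cfg)
        assert probs.shape == (4,)
        assert probs.min() >= 0.0
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_zeroed_head_gives_exactly_uniform(self):
        cfg = tiny_config()
        params = init_params(cfg)
        params["head_w2"].data[:] = 0.0
        params["head_b2"].data[:] = 0.0
        probs = forward_classify(np.random.default_rng(1).random((64, 64)), params, cfg)
        np.testing.assert_array_equal(probs, np.full(4, 0.25))

    def test_repeated_forward_bitwise_identical(self):
        cfg = tiny_config()
        model = ViTClassifier(cfg)
        img = np.random.default_rng(3).random((2, 64, 64))
        a = model.predict_proba(img)
        b = model.predict_proba(img)
        np.testing.assert_array_equal(a, b)

    def test_forward_finite_for_extreme_inputs(self):
        cfg = tiny_config()
        model = ViTClassifier(cfg)
        for img in (np.zeros((64, 64)), np.ones((64, 64))):
            probs = model.predict_proba(img[None])
            assert np.all(np.isfinite(probs))


class TestTrainingAndPersistence:
    def test_short_fit_reduces_loss(self):
        rng = np.random.default_rng(0)
        cfg = ModelConfig(scales=(8,), d=16, heads=2, blocks=1,
                          dense_neurons=16, n_classes=2, seed=0)
        # two linearly separable blobs: bright top vs bright bottom
        imgs, labels = [], []
        for i in range(24):
            img = np.full((16, 16), 0.2)
            if i % 2:
                img[:8] = 0.8
            else:
                img[8:] = 0.8
            imgs.append(np.clip(img + 0.02 * rng.standard_normal(img.shape), 0, 1))
            labels.append(i % 2)
        imgs, labels = np.stack(imgs), np.array(labels)
        model = ViTClassifier(cfg)
        hist = model.fit(imgs, labels, epochs=15, batch_size=8, lr=1e-2, seed=0)
        assert hist[-1] < hist[0]
        assert (model.predict(imgs) == labels).mean() >= 0.9

    def test_save_load_roundtrip(self, tmp_path):
        cfg = tiny_config()
        model = ViTClassifier(cfg)
        img = np.random.default_rng(4).random((1, 64, 64))
        before = model.predict_proba(img)
        model.save(tmp_path / "ckpt")
        loaded = ViTClassifier.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(loaded.predict_proba(img), before)
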