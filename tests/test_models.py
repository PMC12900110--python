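"""Architecture blocks, parameter checksums, and forward-pass contracts."""

import numpy as np
import pytest

from oblfp import models, nn
from oblfp.models import (ArchitectureSpec, ClassifierOutput, SEParams,
                          build_attention_cnn, build_model, build_res_cnn,
                          count_parameters, load_checkpoint, residual_block,
                          save_checkpoint, spatial_attention,
                          squeeze_excitation)


def se_scalar_oracle(u, w1, w2, b1=None, b2=None):
    """Independent scalar re-statement of squeeze-and-excitation:
    pool each channel, two affine maps with ReLU between, sigmoid gates."""
    c, t = u.shape
    z = [sum(u[i]) / t for i in range(c)]
    h = [max(0.0, sum(w1[j][i] * z[i] for i in range(c))
             + (b1[j] if b1 is not None else 0.0))
         for j in range(len(w1))]
    s = [1.0 / (1.0 + np.exp(-(sum(w2[i][j] * h[j] for j in range(len(h)))
                               + (b2[i] if b2 is not None else 0.0))))
         for i in range(c)]
    return np.array([[s[i] * u[i, j] for j in range(t)] for i in range(c)])


class TestSqueezeExcitation:
    def test_zero_weights_halve_the_map(self):
        u = np.arange(8.0).reshape(4, 2)
        params = SEParams(w1=np.zeros((2, 4)), w2=np.zeros((4, 2)), r=2)
        out = squeeze_excitation(u, params)
        np.testing.assert_allclose(out, u / 2.0)   # sigmoid(0) = 0.5

    def test_matches_scalar_oracle_hand_values(self):
        u = np.array([[1.0, 1], [2, 2], [3, 3], [4, 4]])
        w1 = np.array([[0.1, -0.2, 0.3, 0.05], [0.0, 0.4, -0.1, 0.2]])
        w2 = np.array([[0.3, -0.1], [0.2, 0.2], [-0.4, 0.1], [0.05, 0.6]])
        params = SEParams(w1=w1, w2=w2, r=2)
        out = squeeze_excitation(u, params)
        np.testing.assert_allclose(out, se_scalar_oracle(u, w1, w2), atol=1e-12)

    def test_matches_scalar_oracle_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = int(rng.choice([2, 4, 8]))
            t = int(rng.integers(1, 6))
            r = 2
            u = rng.normal(size=(c, t))
            w1 = rng.normal(size=(c // r, c))
            w2 = rng.normal(size=(c, c // r))
            b1 = rng.normal(size=c // r)
            b2 = rng.normal(size=c)
            params = SEParams(w1=w1, w2=w2, r=r, b1=b1, b2=b2)
            np.testing.assert_allclose(
                squeeze_excitation(u, params),
                se_scalar_oracle(u, w1, w2, b1, b2), atol=1e-6)

    def test_gates_stay_in_unit_interval(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(8, 5)) * 10
        params = SEParams(w1=rng.normal(size=(1, 8)) * 5,
                          w2=rng.normal(size=(8, 1)) * 5, r=8)
        out = squeeze_excitation(u, params)
        ratio = out[np.abs(u) > 1e-9] / u[np.abs(u) > 1e-9]
        assert np.all(ratio > 0.0) and np.all(ratio < 1.0)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            SEParams(w1=np.zeros((2, 5)), w2=np.zeros((5, 2)), r=2)


class TestSpatialAttention:
    def test_identity_limit_with_large_bias(self):
        u = np.random.default_rng(2).normal(size=(6, 16))
        out = spatial_attention(u, weight=np.zeros((1, 2, 7)), bias=50.0)
        np.testing.assert_allclose(out, u, atol=1e-6)   # sigmoid(50) ~ 1

    def test_constant_map_uniformly_scaled(self):
        u = np.full((4, 12), 2.0)
        w = np.random.default_rng(3).normal(size=(1, 2, 7))
        out = spatial_attention(u, weight=w)
        interior = out[:, 3:-3]        # 'same' padding distorts the borders
        assert np.allclose(interior, interior[0, 0])
        assert np.allclose(out, np.broadcast_to(out[0], out.shape))

    def test_mask_bounds_on_nonnegative_map(self):
        rng = np.random.default_rng(4)
        u = np.abs(rng.normal(size=(5, 20)))
        out = spatial_attention(u, weight=rng.normal(size=(1, 2, 7)))
        assert np.all(out >= 0.0)
        assert np.all(out <= u + 1e-12)


class TestResidualBlock:
    def test_zero_residual_path_is_relu_identity(self):
        u = np.random.default_rng(5).normal(size=(8, 10))
        block = nn.ResidualBlock(8, 8, r=4, rng=np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
        out = residual_block(u, 8, block=block)
        np.testing.assert_allclose(out, np.maximum(u, 0.0), atol=1e-12)

    def test_matches_unrolled_two_stage_composition(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=(4, 7))
        block = nn.ResidualBlock(4, 4, r=2, rng=rng)
        block.eval()
        # literal step-by-step composition through the same sublayers
        f = block.conv1.forward(u[None])
        f = block.bn1.forward(f)
        f = np.maximum(f, 0.0)
        f = block.conv2.forward(f)
        f = block.bn2.forward(f)
        f = block.se.forward(f)
        expected = np.maximum(f + u[None], 0.0)[0]
        np.testing.assert_allclose(residual_block(u, 4, block=block),
                                   expected, atol=1e-12)

    def test_skip_path_carries_gradient(self):
        """With the residual path zeroed, the shortcut still propagates."""
        block = nn.ResidualBlock(4, 4, r=2, rng=np.random.default_rng(7))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
        block.eval()
        x = np.abs(np.random.default_rng(8).normal(size=(1, 4, 7)))  # relu-active
        block.forward(x)
        dx = block.backward(np.ones((1, 4, 7)))
        assert np.abs(dx).min() > 0.0

    def test_projection_on_width_change(self):
        u = np.random.default_rng(9).normal(size=(4, 8))
        out = residual_block(u, 6, seed=0)
        assert out.shape == (6, 8)
        block = nn.ResidualBlock(4, 6, r=2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            residual_block(np.zeros((5, 8)), 6, block=block)


class TestArchitectures:
    def test_forward_contract(self):
        x = np.random.default_rng(10).normal(size=(32, 129))
        for build in (build_attention_cnn, build_res_cnn):
            out = build(seed=0).predict(x)
            assert isinstance(out, ClassifierOutput)
            assert out.logits.shape == (1, 2)
            assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_batch_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 32, 129))
        perm = rng.permutation(6)
        for build in (build_attention_cnn, build_res_cnn):
            model = build(seed=1)
            direct = model.predict(x).logits[perm]
            permuted = model.predict(x[perm]).logits
            np.testing.assert_allclose(direct, permuted, atol=1e-8)

    def test_eval_mode_deterministic(self):
        x = np.random.default_rng(12).normal(size=(3, 32, 129))
        model = build_attention_cnn(seed=2)
        np.testing.assert_array_equal(model.predict(x).logits,
                                      model.predict(x).logits)

    def test_wrong_input_shape_rejected(self):
        model = build_res_cnn(seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 16, 129)))

    def test_attention_pooling_footprint(self):
        """The bin axis contracts 129 -> 64 -> 16 -> 4 before global pooling."""
        model = build_attention_cnn(seed=0)
        x = np.random.default_rng(13).normal(size=(1, 32, 129))
        model.eval()
        stem = model.stem._mods
        h = stem[0].forward(x)
        assert h.shape[-1] == 64
        for m in stem[1:5]:
            h = m.forward(h)
        assert h.shape[-1] == 16
        for m in stem[5:]:
            h = m.forward(h)
        assert h.shape[-1] == 4

    def test_embedding_dimensions(self):
        x = np.random.default_rng(14).normal(size=(4, 32, 129))
        att, res = build_attention_cnn(seed=0), build_res_cnn(seed=0)
        att.predict(x), res.predict(x)
        assert att.embedding.shape == (4, 192)
        assert res.embedding.shape == (4, 128)


class TestParameterCounts:
    def test_single_linear_map(self):
        lin = nn.Linear(192, 2, rng=np.random.default_rng(0))
        assert sum(p.data.size for p in lin.parameters()) == 386

    def test_single_conv(self):
        conv = nn.Conv1d(64, 64, 3, rng=np.random.default_rng(0))
        assert sum(p.data.size for p in conv.parameters()) == 12352

    def test_published_model_sizes(self):
        att = count_parameters(build_attention_cnn())
        res = count_parameters(build_res_cnn())
        assert round(att / 1000, 1) == 155.1
        assert round(res / 1000, 1) == 306.3
        assert round((att + res) / 1000, 1) == 461.4

    def test_ensemble_count_is_additive(self):
        att = count_parameters(build_attention_cnn())
        res = count_parameters(build_res_cnn())
        both = count_parameters(nn.Sequential(build_attention_cnn(),
                                              build_res_cnn()))
        assert both == att + res


class TestRegistryAndCheckpoints:
    def test_registry_builds_members(self):
        assert build_model("attention_cnn", seed=0).name == "attention_cnn"
        assert build_model("res_cnn", seed=0).name == "res_cnn"

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            build_model("transformer")

    @pytest.mark.parametrize("stub", ["vanilla_cnn", "deep_cnn", "dilated_cnn",
                                      "wide_cnn", "shallow_cnn"])
    def test_baseline_stubs_unimplemented(self, stub):
        with pytest.raises(NotImplementedError):
            build_model(stub)

    def test_checkpoint_roundtrip(self, tmp_path):
        x = np.random.default_rng(15).normal(size=(2, 32, 129))
        model = build_res_cnn(seed=3)
        ref = model.predict(x).logits
        save_checkpoint(model, tmp_path / "ckpt")
        other = build_res_cnn(seed=99)
        assert not np.allclose(other.predict(x).logits, ref)
        load_checkpoint(other, tmp_path / "ckpt")
        np.testing.assert_array_equal(other.predict(x).logits, ref)

    def test_checkpoint_architecture_mismatch(self, tmp_path):
        save_checkpoint(build_res_cnn(seed=0), tmp_path / "ckpt")
        with pytest.raises(ValueError):
            load_checkpoint(build_attention_cnn(seed=0), tmp_path / "ckpt")
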