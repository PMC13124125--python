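"""Architecture contracts: branch shapes, fusion, batch norm, CBAM, forward."""

import numpy as np
import pytest

from dlam._autograd import Tensor
from dlam._nn import BatchNorm1d
from dlam.model import (
    Branch,
    Cbam,
    DlamModel,
    ModelConfig,
    default_branch_configs,
    fuse_maps,
    softmax_cross_entropy,
)


def make_blocks(rng, n):
    return {
        "expression": rng.normal(size=(n, 36)),
        "domain": rng.random((n, 36)),
        "subcellular": rng.normal(size=(n, 11)),
        "orthology": rng.random((n, 12)),
    }


class TestBranches:
    def test_two_conv_branch_length_arithmetic(self, rng):
        cfg = default_branch_configs()["expression"]
        branch = Branch(cfg, rng=np.random.default_rng(0))
        out = branch(Tensor(rng.normal(size=(3, 1, 36))))
        # 36 -> 32 (k5,s1) -> 15 (k4,s2) -> 12 (pool k4,s1), 10 channels
        assert out.shape == (3, 10, 12)
        assert cfg.out_length() == 12

    def test_one_conv_branch_preserves_length(self, rng):
        cfg = default_branch_configs()["orthology"]
        branch = Branch(cfg, rng=np.random.default_rng(0))
        out = branch(Tensor(rng.normal(size=(3, 1, 12))))
        assert out.shape == (3, 20, 12)

    def test_subcellular_branch_pads_11_to_12(self, rng):
        cfg = default_branch_configs()["subcellular"]
        branch = Branch(cfg, rng=np.random.default_rng(0))
        out = branch(Tensor(rng.normal(size=(2, 1, 11))))
        assert out.shape == (2, 20, 12)

    def test_zero_input_zero_bias_gives_zero_output(self):
        cfg = default_branch_configs()["expression"]
        branch = Branch(cfg, rng=np.random.default_rng(0))
        out = branch(Tensor(np.zeros((2, 1, 36))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_wrong_length_names_branch(self, rng):
        cfg = default_branch_configs()["domain"]
        branch = Branch(cfg, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="domain"):
            branch(Tensor(rng.normal(size=(2, 1, 20))))


class TestFusion:
    def test_default_fused_shape_and_slicing(self, rng):
        maps = {
            "expression": Tensor(rng.normal(size=(4, 10, 12))),
            "domain": Tensor(rng.normal(size=(4, 10, 12))),
            "subcellular": Tensor(rng.normal(size=(4, 20, 12))),
            "orthology": Tensor(rng.normal(size=(4, 20, 12))),
        }
        order = ("expression", "domain", "subcellular", "orthology")
        fused = fuse_maps(maps, order)
        assert fused.shape == (4, 60, 12)
        # concatenation is invertible by channel slicing in the fixed order
        np.testing.assert_array_equal(fused.data[:, :10], maps["expression"].data)
        np.testing.assert_array_equal(fused.data[:, 10:20], maps["domain"].data)
        np.testing.assert_array_equal(fused.data[:, 20:40], maps["subcellular"].data)
        np.testing.assert_array_equal(fused.data[:, 40:], maps["orthology"].data)

    def test_length_mismatch_errors(self, rng):
        maps = {
            "a": Tensor(rng.normal(size=(2, 3, 12))),
            "b": Tensor(rng.normal(size=(2, 3, 11))),
        }
        with pytest.raises(ValueError):
            fuse_maps(maps, ("a", "b"))


class TestBatchNorm:
    def test_constant_channel_training_mode_outputs_beta(self, rng):
        bn = BatchNorm1d(3)
        bn.beta.data[:] = [1.0, 2.0, 3.0]
        x = Tensor(np.ones((4, 3, 5)) * 7.0)
        out = bn(x, training=True)
        for c, b in enumerate([1.0, 2.0, 3.0]):
            np.testing.assert_allclose(out.data[:, c], b, atol=1e-2)

    def test_unit_gamma_zero_beta_centers_channels(self, rng):
        bn = BatchNorm1d(3)
        out = bn(Tensor(rng.normal(5, 2, size=(8, 3, 4))), training=True)
        np.testing.assert_allclose(out.data.mean(axis=(0, 2)), 0.0, atol=1e-9)

    def test_matches_hand_rolled_statistics(self, rng):
        x = rng.normal(size=(4, 2, 3))
        bn = BatchNorm1d(2)
        out = bn(Tensor(x), training=True).data
        mu = x.mean(axis=(0, 2), keepdims=True)
        var = x.var(axis=(0, 2), keepdims=True)
        np.testing.assert_allclose(out, (x - mu) / np.sqrt(var + bn.eps), atol=1e-6)


class TestCbam:
    @pytest.fixture()
    def cbam(self):
        return Cbam(channels=6, reduction=2, spatial_kernel=3, rng=np.random.default_rng(0))

    def test_zero_weights_give_half_attention(self, cbam, rng):
        for p in cbam.parameters():
            p.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 6, 5)))
        np.testing.assert_allclose(cbam.channel_attention(x).data, 0.5)
        refined = cbam.channel_attention(x) * x
        np.testing.assert_allclose(cbam.spatial_attention(refined).data, 0.5)

    def test_gates_strictly_in_open_unit_interval(self, cbam, rng):
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 6, 5)))
            cm = cbam.channel_attention(x).data
            sm = cbam.spatial_attention(cbam.channel_attention(x) * x).data
            assert np.all((cm > 0) & (cm < 1))
            assert np.all((sm > 0) & (sm < 1))

    def test_output_never_exceeds_input_magnitude(self, cbam, rng):
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 6, 5)))
            out = cbam(x).data
            assert np.all(np.abs(out) <= np.abs(x.data) + 1e-12)

    def test_constant_map_pools_agree(self, cbam):
        x = Tensor(np.full((1, 6, 5), 0.7))
        avg = x.mean(axis=2, keepdims=True)
        mx = x.max_reduce(axis=2, keepdims=True)
        np.testing.assert_allclose(
            cbam._shared(avg).data, cbam._shared(mx).data, atol=1e-12
        )

    def test_spatial_attention_invariant_to_channel_permutation(self, cbam, rng):
        x = rng.normal(size=(1, 6, 5))
        perm = np.random.default_rng(1).permutation(6)
        a = cbam.spatial_attention(Tensor(x)).data
        b = cbam.spatial_attention(Tensor(x[:, perm])).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_composed_equals_two_stage(self, cbam, rng):
        x = Tensor(rng.normal(size=(1, 5, 6))[:, :5])  # 5x6 map
        cb = Cbam(channels=5, reduction=2, spatial_kernel=3, rng=np.random.default_rng(2))
        full = cb(x).data
        refined = cb.channel_attention(x) * x
        staged = (refined * cb.spatial_attention(refined)).data
        np.testing.assert_allclose(full, staged, atol=1e-12)

    def test_zero_input_gives_zero_output(self, cbam):
        out = cbam(Tensor(np.zeros((1, 6, 5))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestForward:
    def test_batch_of_20_gives_20x2(self, rng):
        model = DlamModel(seed=0)
        logits = model.forward(make_blocks(rng, 20), np.ones((20, 4)))
        assert logits.shape == (20, 2)

    def test_eval_mode_deterministic(self, rng):
        model = DlamModel(seed=0)
        blocks = make_blocks(rng, 5)
        flags = np.ones((5, 4))
        a = model.predict_proba(blocks, flags)
        b = model.predict_proba(blocks, flags)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0)

    def test_no_attention_changes_only_cbam(self, rng):
        on = DlamModel(ModelConfig(attention=True), seed=0)
        off = DlamModel(ModelConfig(attention=False), seed=0)
        assert off.cbam is None
        cbam_params = sum(p.data.size for p in on.cbam.parameters())
        assert on.n_parameters() - off.n_parameters() == cbam_params
        # shapes unchanged end to end
        logits = off.forward(make_blocks(rng, 7), np.ones((7, 4)))
        assert logits.shape == (7, 2)

    @pytest.mark.parametrize(
        "modalities",
        [("expression",), ("expression", "domain"), ("expression", "domain", "orthology")],
    )
    def test_feature_subsets_run_end_to_end(self, modalities, rng):
        cfg = ModelConfig(modalities=modalities)
        model = DlamModel(cfg, seed=0)
        blocks = {k: v for k, v in make_blocks(rng, 6).items() if k in modalities}
        logits = model.forward(blocks, np.ones((6, len(modalities))))
        assert logits.shape == (6, 2)
        assert model.fused_channels == sum(
            cfg.branch_configs[m].out_channels() for m in modalities
        )

    def test_gradients_finite_for_all_parameters(self, rng):
        model = DlamModel(seed=0)
        logits = model.forward(
            make_blocks(rng, 8), np.ones((8, 4)), training=True,
            rng=np.random.default_rng(0),
        )
        loss = softmax_cross_entropy(logits, rng.integers(0, 2, size=8))
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None and np.all(np.isfinite(p.grad))

    def test_flag_vector_feeds_classifier(self, rng):
        """Availability flags reach the FC head: changing them changes the output."""
        model = DlamModel(seed=0)
        blocks = make_blocks(rng, 3)
        a = model.predict_proba(blocks, np.ones((3, 4)))
        b = model.predict_proba(blocks, np.zeros((3, 4)))
        assert not np.allclose(a, b)
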