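"""Architecture contracts: attention bounds, residual identity, shapes, capacity."""

import numpy as np
import pytest

from msaunet.arch import (
    MSABlock,
    MSFEF,
    MSSAAttention,
    ModelConfig,
    SSEAttention,
    build_model,
    predict_mask,
    zero_parameters,
)
from msaunet.nn import Tensor

SMALL = dict(base_channels=4, depth=3)


def make_input(rng, n=1, c=4, h=16, w=16):
    return Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


class TestModelConfig:
    def test_defaults_per_version(self):
        assert ModelConfig(version="V1").resolved_n_msa_blocks == 3
        assert ModelConfig(version="V2").resolved_n_msa_blocks == 2

    def test_bad_version(self):
        with pytest.raises(ValueError):
            ModelConfig(version="V3")

    def test_n_msa_exceeding_depth(self):
        with pytest.raises(ValueError):
            ModelConfig(n_msa_blocks=4, depth=3)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_bank_a=(3, 4, 7))

    def test_roundtrip_dict(self):
        cfg = ModelConfig(version="V2", n_msa_blocks=1, attention="sSE")
        assert ModelConfig.from_dict(cfg.to_dict()) == ModelConfig.from_dict(cfg.to_dict())


class TestSSE:
    def test_zero_input_weights_half(self, rng):
        mod = SSEAttention(4, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        w, recal = mod(x)
        np.testing.assert_allclose(w.data, 0.5)
        np.testing.assert_allclose(recal.data, 0.0)

    def test_weights_open_interval_and_contraction(self, rng):
        mod = SSEAttention(4, np.random.default_rng(1))
        x = make_input(rng)
        w, recal = mod(x)
        assert w.shape == (1, 1, 16, 16)
        assert (w.data > 0).all() and (w.data < 1).all()
        assert np.all(np.abs(recal.data) <= np.abs(x.data) + 1e-7)

    def test_spatial_dims_preserved(self, rng):
        mod = SSEAttention(8, np.random.default_rng(2))
        x = make_input(rng, c=8, h=12, w=20)
        _, recal = mod(x)
        assert recal.shape == x.shape


class TestMSSA:
    def test_zero_input_zeroed_convs_all_half(self):
        mod = MSSAAttention(4, (2, 4), np.random.default_rng(0))
        zero_parameters(mod)
        x = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        for m in mod.scale_maps(x):
            np.testing.assert_allclose(m.data, 0.5)
        w, recal = mod(x)
        np.testing.assert_allclose(w.data, 0.5)
        np.testing.assert_allclose(recal.data, 0.0)

    def test_final_weights_bounds_and_contraction(self, rng):
        mod = MSSAAttention(4, (2, 4), np.random.default_rng(3))
        x = make_input(rng)
        w, recal = mod(x)
        assert (w.data > 0).all() and (w.data < 1).all()
        assert np.all(np.abs(recal.data) <= np.abs(x.data) + 1e-7)
        assert recal.shape == x.shape

    def test_scale_maps_differ_on_localized_patch(self):
        # a single high-magnitude 4x4 patch: per-scale maps must not all agree
        mod = MSSAAttention(2, (2, 4), np.random.default_rng(7))
        x = np.zeros((1, 2, 16, 16), dtype=np.float32)
        x[:, :, 4:8, 4:8] = 50.0
        maps = [m.data for m in mod.scale_maps(Tensor(x))]
        assert len(maps) == 3
        assert not np.allclose(maps[0], maps[1])
        assert not np.allclose(maps[1], maps[2])

    def test_pool_factor_too_large_raises(self):
        mod = MSSAAttention(2, (32,), np.random.default_rng(0))
        with pytest.raises(ValueError):
            mod(Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32)))

    def test_non_divisible_dims_padded(self, rng):
        mod = MSSAAttention(2, (2, 4), np.random.default_rng(0))
        x = make_input(rng, c=2, h=10, w=6)
        w, recal = mod(x)
        assert recal.shape == x.shape
        assert w.shape[2:] == (10, 6)


class TestMSFEF:
    def test_shape_contract(self, rng):
        for kernels in ((3, 5, 7), (5, 7, 9)):
            mod = MSFEF(4, 16, kernels, np.random.default_rng(0))
            out = mod(make_input(rng))
            assert out.shape == (1, 16, 16, 16)

    def test_zero_weights_zero_output(self, rng):
        mod = MSFEF(4, 8, (3, 5, 7), np.random.default_rng(0))
        zero_parameters(mod)
        out = mod(make_input(rng))
        np.testing.assert_allclose(out.data, 0.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            MSFEF(4, 8, (3, 4), np.random.default_rng(0))

    def test_parameter_count_formula(self):
        # fusion rule: per-kernel conv (no bias, BN) then 1x1 fusion conv + BNs.
        # count = sum_k [k^2*Cin*Cout + 2*Cout] + (3*Cout*Cout + 2*Cout)
        cin, cout = 8, 16
        mod = MSFEF(cin, cout, (3, 5, 7), np.random.default_rng(0))
        expected = sum(k * k * cin * cout + 2 * cout for k in (3, 5, 7))
        expected += (3 * cout) * cout + 2 * cout
        assert mod.n_parameters() == expected


class TestMSABlock:
    @pytest.mark.parametrize("version", ["V1", "V2"])
    @pytest.mark.parametrize("attention", ["sSE", "MSSA"])
    def test_shape_preserved(self, rng, version, attention):
        cfg = ModelConfig(version=version, attention=attention, n_msa_blocks=1, depth=4)
        blk = MSABlock(4, 8, cfg, np.random.default_rng(0))
        out = blk(make_input(rng))
        assert out.shape == (1, 8, 16, 16)

    def test_residual_identity_when_zeroed(self, rng):
        cfg = ModelConfig(version="V1", attention="MSSA", n_msa_blocks=1, depth=4)
        blk = MSABlock(4, 4, cfg, np.random.default_rng(0))
        zero_parameters(blk)
        x = make_input(rng)
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-7)

    def test_v2_has_more_parameters_than_v1(self):
        kw = dict(n_msa_blocks=1, attention="MSSA", depth=4)
        v1 = MSABlock(8, 16, ModelConfig(version="V1", **kw), np.random.default_rng(0))
        v2 = MSABlock(8, 16, ModelConfig(version="V2", **kw), np.random.default_rng(0))
        assert v2.n_parameters() > v1.n_parameters()


class TestBuildModel:
    @pytest.mark.parametrize("version", ["V1", "V2"])
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_ablation_grid_builds_and_forward(self, version, n):
        cfg = ModelConfig(version=version, n_msa_blocks=n, base_channels=4, depth=4)
        model = build_model(cfg, seed=0)
        model.eval()
        x = np.random.default_rng(0).normal(size=(1, 1, 64, 64)).astype(np.float32)
        out = model(Tensor(x))
        assert out.shape == (1, 1, 64, 64)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_baseline_n0(self):
        cfg = ModelConfig(n_msa_blocks=0, **SMALL)
        model = build_model(cfg, seed=0)
        model.eval()
        out = model(Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32)))
        assert out.shape == (1, 1, 16, 16)

    def test_parameter_count_monotone_in_n(self):
        for version in ("V1", "V2"):
            counts = [build_model(ModelConfig(version=version, n_msa_blocks=n,
                                              base_channels=4, depth=4), seed=0).n_parameters()
                      for n in range(5)]
            assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_v2_bigger_than_v1(self):
        for n in (1, 2, 3):
            p1 = build_model(ModelConfig(version="V1", n_msa_blocks=n, **SMALL), seed=0).n_parameters()
            p2 = build_model(ModelConfig(version="V2", n_msa_blocks=n, **SMALL), seed=0).n_parameters()
            assert p2 > p1

    def test_indivisible_input_rejected(self):
        model = build_model(ModelConfig(**SMALL), seed=0)
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 1, 17, 17), dtype=np.float32)))

    def test_seeded_build_deterministic(self):
        cfg = ModelConfig(**SMALL)
        a = build_model(cfg, seed=5)
        b = build_model(cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestGradientFlow:
    def test_every_parameter_gets_gradient(self):
        # residual/BN wiring check: across 5 trials no parameter may have an
        # identically-zero gradient after one training step
        from msaunet.loss import DiceLossSpec, dice_loss_tensor

        cfg = ModelConfig(version="V1", n_msa_blocks=2, attention="MSSA",
                          base_channels=4, depth=2)
        model = build_model(cfg, seed=0)
        params = list(model.parameters())
        got_grad = [np.zeros_like(p.data, dtype=bool) for p in params]
        rng = np.random.default_rng(0)
        for _ in range(5):
            model.zero_grad()
            x = Tensor(rng.normal(size=(2, 1, 16, 16)).astype(np.float32))
            gt = (rng.random((2, 1, 16, 16)) > 0.7).astype(np.float32)
            model.train()
            loss = dice_loss_tensor(gt, model(x), DiceLossSpec())
            loss.backward()
            for i, p in enumerate(params):
                assert p.grad is not None
                assert np.all(np.isfinite(p.grad))
                got_grad[i] |= p.grad != 0
        for i, g in enumerate(got_grad):
            assert g.any(), f"parameter {i} never received a nonzero gradient"


class TestPredictMask:
    def _const_model(self, p):
        cfg = ModelConfig(**SMALL)
        model = build_model(cfg, seed=0)
        zero_parameters(model)
        # zero weights give head logits == bias; set bias for probability p
        model.head.bias.data = np.array([np.log(p / (1 - p))], dtype=np.float32)
        model.eval()
        return model

    def test_threshold_below(self):
        model = self._const_model(0.7)
        mask = predict_mask(model, np.zeros((32, 32), dtype=np.float32), threshold=0.5)
        assert mask.shape == (32, 32)
        assert (mask == 1).all()

    def test_threshold_above(self):
        model = self._const_model(0.7)
        mask = predict_mask(model, np.zeros((32, 32), dtype=np.float32), threshold=0.9)
        assert (mask == 0).all()

    def test_exact_selection(self):
        # thresholding a raw probability map: 0.6 pixels selected, 0.4 not
        probs = np.array([[0.4, 0.6], [0.6, 0.4]])
        assert ((probs >= 0.5).astype(np.uint8) == [[0, 1], [1, 0]]).all()
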