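"""Architecture contracts of the segmentation network."""

import dataclasses

import numpy as np
import pytest

from cowseg import nn
from cowseg.nn import Tensor
from cowseg.seg_model import (
    ASPPAttn,
    Backbone,
    CBAMBlock,
    ECABlock,
    SegConfig,
    SegModel,
    SEBlock,
    desk_config,
    load_checkpoint,
    poly_lr,
    save_checkpoint,
)

DESK = desk_config()


def tiny_cfg(**kw):
    base = dict(backbone_depth=18, base_channels=8, aspp_dilations=(2, 4, 6),
                input_size=(32, 48), n_classes=2)
    base.update(kw)
    return SegConfig(**base)


class TestBackbone:
    @pytest.mark.parametrize("h,w", [(96, 160), (64, 64), (32, 48)])
    def test_feature_strides(self, h, w):
        cfg = tiny_cfg(input_size=(h, w))
        bb = Backbone(cfg, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 3, h, w), dtype=np.float32))
        low, pen, high = bb(x)
        assert low.shape[2:] == (h // 4, w // 4)
        assert high.shape[2:] == (h // 16, w // 16)

    def test_output_stride_eight(self):
        cfg = tiny_cfg(output_stride=8)
        bb = Backbone(cfg, np.random.default_rng(0))
        x = Tensor(np.zeros((1, 3, 32, 48), dtype=np.float32))
        _, _, high = bb(x)
        assert high.shape[2:] == (4, 6)

    def test_deep_stem_parameter_count(self):
        # classic stem: one 7x7 conv (3 -> c): 49*3*c weights
        # deep stem: 3x3 convs 3->c/2->c/2->c: 9*(3*m + m*m + m*c), m = c/2
        c = 16
        m = c // 2
        classic = Backbone(tiny_cfg(stem="classic", base_channels=c),
                           np.random.default_rng(0))
        deep = Backbone(tiny_cfg(stem="deep_stem_D", base_channels=c),
                        np.random.default_rng(0))
        n_classic = sum(p.data.size for p in classic.stem.parameters()
                        if p.data.ndim == 4)
        n_deep = sum(p.data.size for p in deep.stem.parameters()
                     if p.data.ndim == 4)
        assert n_classic == 49 * 3 * c
        assert n_deep == 9 * (3 * m + m * m + m * c)

    def test_avgpool_shortcut_toggle_preserves_shapes(self):
        x = Tensor(np.random.default_rng(0).normal(0, 1, (1, 3, 32, 48)).astype(np.float32))
        for flag in (True, False):
            bb = Backbone(tiny_cfg(downsample_avgpool=flag), np.random.default_rng(0))
            low, _, high = bb(x)
            assert low.shape[2:] == (8, 12) and high.shape[2:] == (2, 3)


class TestAttention:
    def _zero_params(self, module):
        for p in module.parameters():
            p.data = np.zeros_like(p.data)

    def test_se_zero_init_halves_input(self, rng):
        se = SEBlock(4, ratio=2, rng=rng)
        self._zero_params(se)
        x = Tensor(rng.normal(0, 1, (2, 4, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(se(x).data, x.data / 2, atol=1e-6)

    def test_eca_zero_init_halves_input(self, rng):
        eca = ECABlock(6, rng=rng)
        self._zero_params(eca)
        x = Tensor(rng.normal(0, 1, (1, 6, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(eca(x).data, x.data / 2, atol=1e-6)

    def test_cbam_zero_init_quarters_input(self, rng):
        cbam = CBAMBlock(4, ratio=2, rng=rng)
        self._zero_params(cbam)
        x = Tensor(rng.normal(0, 1, (1, 4, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(cbam(x).data, x.data / 4, atol=1e-6)

    def test_gates_lie_in_unit_interval(self, rng):
        x = Tensor(rng.normal(0, 5, (2, 8, 4, 4)).astype(np.float32))
        for block in (SEBlock(8, 2, rng), ECABlock(8, 3, rng)):
            g = block.gates(x).data
            assert np.all(g > 0) and np.all(g < 1)
            out = block(x).data
            assert np.all(np.abs(out) <= np.abs(x.data) + 1e-6)

    def test_se_hand_computed_gates(self):
        # 2-channel 1x1 input, hand-set weights: gate = sigmoid(W2 relu(W1 p))
        se = SEBlock(2, ratio=1, rng=np.random.default_rng(0))
        se.fc1.weight.data = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=np.float32)
        se.fc1.bias.data = np.zeros(2, dtype=np.float32)
        se.fc2.weight.data = np.array([[2.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        se.fc2.bias.data = np.zeros(2, dtype=np.float32)
        x = Tensor(np.array([0.5, -0.25], dtype=np.float32).reshape(1, 2, 1, 1))
        # pooled = (0.5, -0.25); h = relu((0.5, 0.25)) = (0.5, 0.25)
        # gates = sigmoid((1.0, 0.25))
        expected = 1 / (1 + np.exp(-np.array([1.0, 0.25])))
        np.testing.assert_allclose(se.gates(x).data[0], expected, atol=1e-6)

    def test_eca_constant_channels_equal_gates(self, rng):
        eca = ECABlock(6, rng=rng)
        x = Tensor(np.full((1, 6, 4, 4), 0.7, dtype=np.float32))
        g = eca.gates(x).data[0]
        # interior channels see identical neighborhoods
        assert np.allclose(g[1:-1], g[1], atol=1e-7)

    def test_attention_none_is_exact_identity(self, rng):
        cfg = tiny_cfg(attention="none")
        model = SegModel(cfg, np.random.default_rng(0))
        from cowseg.seg_model import Identity
        assert isinstance(model.aspp.attention, Identity)
        x = Tensor(rng.normal(0, 1, (1, 4, 3, 3)).astype(np.float32))
        assert model.aspp.attention(x) is x


class TestASPP:
    def test_output_spatial_dims_preserved(self, rng):
        cfg = tiny_cfg()
        aspp = ASPPAttn(16, 8, cfg, (6, 10), rng)
        x = Tensor(rng.normal(0, 1, (2, 16, 6, 10)).astype(np.float32))
        out = aspp(x)
        assert out.shape == (2, 8, 6, 10)

    def test_oversized_dilation_clamped_with_warning(self, rng):
        cfg = tiny_cfg(aspp_dilations=(2, 12, 24))
        with pytest.warns(UserWarning, match="clamped"):
            aspp = ASPPAttn(8, 8, cfg, (4, 6), rng)
        assert max(aspp.dilations) <= 3

    def test_empty_dilations_degenerates_to_projection_plus_pooling(self, rng):
        cfg = dataclasses.replace(tiny_cfg(), aspp_dilations=())
        aspp = ASPPAttn(8, 8, cfg, (4, 6), rng)
        assert len(aspp.branches) == 0
        x = Tensor(rng.normal(0, 1, (1, 8, 4, 6)).astype(np.float32))
        assert aspp(x).shape == (1, 8, 4, 6)


class TestSegModel:
    def test_probabilities_sum_to_one_and_shape(self, rng):
        model = SegModel(tiny_cfg(), np.random.default_rng(1))
        img = rng.integers(0, 255, (32, 48, 3)).astype(np.uint8)
        probs = model.predict_probs(img)
        assert probs.shape == (32, 48, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        mask = model.predict_mask(img)
        assert set(np.unique(mask)) <= {0, 1}

    def test_non_multiple_of_16_input_padded_and_cropped(self, rng):
        model = SegModel(tiny_cfg(), np.random.default_rng(1))
        img = rng.integers(0, 255, (41, 53, 3)).astype(np.uint8)
        assert model.predict_probs(img).shape == (41, 53, 2)

    def test_aux_head_emits_full_resolution_logits(self, rng):
        model = SegModel(tiny_cfg(aux_head=True), np.random.default_rng(1))
        x = Tensor(rng.normal(0, 1, (1, 3, 32, 48)).astype(np.float32))
        logits, aux = model.forward(x)
        assert logits.shape == (1, 2, 32, 48)
        assert aux.shape == (1, 2, 32, 48)

    def test_checkpoint_roundtrip_identical_predictions(self, tmp_path, rng):
        model = SegModel(tiny_cfg(), np.random.default_rng(2))
        img = rng.integers(0, 255, (32, 48, 3)).astype(np.uint8)
        ref = model.predict_probs(img)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(loaded.predict_probs(img), ref)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegConfig(backbone_depth=34)
        with pytest.raises(ValueError):
            SegConfig(aspp_dilations=(6, 4))
        with pytest.raises(ValueError):
            SegConfig(n_classes=1)
        with pytest.raises(ValueError):
            SegConfig(output_stride=4)


class TestPolyLR:
    def test_initial_rate(self):
        assert poly_lr(0, 50_000, 0.001) == pytest.approx(0.001)

    def test_final_rate_zero(self):
        assert poly_lr(50_000, 50_000, 0.001) == 0.0

    def test_midpoint_closed_form(self):
        assert poly_lr(25_000, 50_000, 0.001, 0.9) == \
            pytest.approx(0.001 * 0.5 ** 0.9)

    def test_overrun_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert poly_lr(60, 50, 0.1) == 0.0
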