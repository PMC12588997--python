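"""Attention, C2f_AA, OREPA reparameterization, GELAN, leaf extraction."""

import warnings

import numpy as np
import pytest

from leafchem.msio import BAND_ORDER
from leafchem.segblocks import (
    AAConfig,
    AAParams,
    C2fAAParams,
    C2fConfig,
    GELANConfig,
    OREPABlock,
    OREPAGELAN,
    aggregated_attention,
    c2f_aa_forward,
    c2f_forward,
    extract_leaf,
    mask_bbox,
    orepa_compress,
    orepa_forward_train,
)
from leafchem.segblocks.nn import conv2d
from leafchem.segblocks.orepa import (
    BRANCH_NAMES,
    PARAM_FIELDS,
    fit_orepa,
    orepa_forward,
    orepa_param_grad,
)
from leafchem.synthgen import SceneSpec, generate_leaf_capture


class TestAggregatedAttention:
    CFG = AAConfig(channel_dim=4, window_size=3, pool_size=2, n_heads=2)

    @pytest.mark.parametrize("shape", [(4, 5, 5), (4, 6, 9), (4, 12, 7)])
    def test_output_shape_matches_input(self, shape):
        rng = np.random.default_rng(0)
        x = rng.normal(size=shape)
        out = aggregated_attention(x, self.CFG, AAParams.init(self.CFG, rng))
        assert out.shape == shape

    def test_weights_nonnegative_and_normalized(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 7, 8))
        _, weights = aggregated_attention(x, self.CFG, AAParams.init(self.CFG, rng),
                                          return_weights=True)
        assert np.all(weights >= 0)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_constant_input_preserved_under_identity_projections(self):
        # all keys equal -> uniform weights -> averaging preserves the constant
        x = np.ones((4, 6, 5)) * np.arange(1.0, 5.0)[:, None, None]
        out = aggregated_attention(x, self.CFG, AAParams.identity(self.CFG))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_dimension_validation(self):
        rng = np.random.default_rng(2)
        params = AAParams.init(self.CFG, rng)
        with pytest.raises(ValueError, match="channels"):
            aggregated_attention(rng.normal(size=(3, 6, 6)), self.CFG, params)
        with pytest.raises(ValueError, match="window"):
            aggregated_attention(rng.normal(size=(4, 2, 6)), self.CFG, params)
        with pytest.raises(ValueError, match="divisible"):
            AAConfig(channel_dim=5, n_heads=2)


class TestC2fAA:
    def test_shape_contract(self):
        rng = np.random.default_rng(3)
        cfg = C2fConfig(c_in=3, c_out=4)
        params = C2fAAParams.init(cfg, rng)
        for shape in [(3, 6, 6), (3, 9, 5), (3, 5, 11)]:
            assert c2f_aa_forward(rng.normal(size=shape), cfg, params).shape == (4, *shape[1:])

    def test_attention_ablation_reduces_to_plain_c2f(self):
        rng = np.random.default_rng(4)
        cfg = C2fConfig(c_in=3, c_out=4)
        params = C2fAAParams.init(cfg, rng)
        x = rng.normal(size=(3, 8, 8))
        np.testing.assert_array_equal(
            c2f_aa_forward(x, cfg, params, use_attention=False),
            c2f_forward(x, cfg, params),
        )

    def test_channel_mismatch_raises(self):
        rng = np.random.default_rng(5)
        cfg = C2fConfig(c_in=3, c_out=4)
        with pytest.raises(ValueError, match="channels"):
            c2f_aa_forward(rng.normal(size=(2, 8, 8)), cfg, C2fAAParams.init(cfg, rng))


class TestOREPA:
    def test_reparameterization_equivalence_100_blocks(self):
        # headline property: train-time six-branch sum == compressed single conv
        worst = 0.0
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            c_in, c_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            block = OREPABlock.init(c_in, c_out, rng)
            x = rng.normal(size=(c_in, 9, 11))
            y_train = orepa_forward_train(x, block)
            y_inf = orepa_forward(x, orepa_compress(block))
            worst = max(worst, float(np.abs(y_train - y_inf).max()))
        assert worst <= 1e-4

    def test_six_branch_types(self):
        assert len(BRANCH_NAMES) == 6
        block = OREPABlock.init(2, 3, np.random.default_rng(0))
        assert set(block.scales) == set(BRANCH_NAMES)

    def test_zero_parameters_give_zero_output_and_kernel(self):
        block = OREPABlock.zeros(2, 3)
        x = np.random.default_rng(1).normal(size=(2, 6, 6))
        np.testing.assert_array_equal(orepa_forward_train(x, block), 0.0)
        compressed = orepa_compress(block)
        np.testing.assert_array_equal(compressed.compressed_kernel, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        block = OREPABlock.init(2, 2, rng)
        block.bias[:] = 0.0
        x1, x2 = rng.normal(size=(2, 2, 7, 7))
        lhs = orepa_forward_train(x1 + x2, block)
        rhs = orepa_forward_train(x1, block) + orepa_forward_train(x2, block)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_single_branch_reduces_to_plain_convolution(self):
        rng = np.random.default_rng(3)
        block = OREPABlock.zeros(2, 3)
        block.w3 = rng.normal(size=(3, 2, 3, 3))
        x = rng.normal(size=(2, 8, 8))
        np.testing.assert_allclose(orepa_forward_train(x, block),
                                   conv2d(x, block.w3), atol=1e-12)

    def test_compressing_twice_raises(self):
        block = orepa_compress(OREPABlock.init(2, 2, np.random.default_rng(0)))
        with pytest.raises(ValueError, match="already compressed"):
            orepa_compress(block)

    def test_gradient_flows_to_every_branch(self):
        # finite-difference check: no dead branch parameter
        rng = np.random.default_rng(7)
        block = OREPABlock.init(2, 2, rng)
        x = rng.normal(size=(2, 6, 6))
        delta = rng.normal(size=(2, 6, 6))
        grads = orepa_param_grad(block, x, delta)

        def objective():
            return float(np.sum(delta * orepa_forward_train(x, block)))

        eps = 1e-6
        for key in PARAM_FIELDS:
            arr = getattr(block, key)
            idx = tuple(0 for _ in arr.shape)
            arr[idx] += eps
            up = objective()
            arr[idx] -= 2 * eps
            dn = objective()
            arr[idx] += eps
            fd = (up - dn) / (2 * eps)
            assert grads[key][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6), key
            assert abs(grads[key][idx]) > 0 or abs(fd) < 1e-12

    def test_training_smoke_decreases_loss(self):
        # tiny synthetic scenes; few epochs of gradient descent
        spec = SceneSpec(width=64, height=48, seed=2)
        capture, _ = generate_leaf_capture(spec, (2.5, 2.0))
        img = capture.bands["green"].pixels / spec.gains["green"]
        x = np.stack([img[:24, :24], img[24:48, :24]])
        target_kernel = np.random.default_rng(5).normal(size=(2, 2, 3, 3))
        y = conv2d(x, target_kernel)
        block = OREPABlock.init(2, 2, np.random.default_rng(6))
        losses = fit_orepa(block, [x], [y], lr=0.05, epochs=10)
        assert losses[-1] < losses[0]
        assert all(b <= a * 1.5 for a, b in zip(losses, losses[1:]))


class TestOREPAGELAN:
    def test_compression_preserves_output_and_shrinks_parameters(self):
        rng = np.random.default_rng(8)
        gelan = OREPAGELAN(GELANConfig(c_in=4, c_out=6, n_units=2), rng)
        x = rng.normal(size=(4, 9, 9))
        before = gelan(x)
        n_before = gelan.n_parameters()
        gelan.compress()
        after = gelan(x)
        assert np.abs(before - after).max() <= 1e-4
        assert gelan.n_parameters() < n_before
        assert after.shape == (6, 9, 9)

    def test_double_compress_warns_and_is_noop(self):
        gelan = OREPAGELAN(GELANConfig(c_in=4, c_out=4), np.random.default_rng(9))
        gelan.compress()
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            gelan.compress()
        assert len(rec) == 1 and "no-op" in str(rec[0].message)


class TestExtractLeaf:
    @pytest.fixture()
    def capture(self):
        spec = SceneSpec(width=96, height=64, seed=3)
        cap, gt = generate_leaf_capture(spec, (2.5, 2.0))
        return cap, gt

    def test_full_image_mask_returns_original(self, capture):
        cap, _ = capture
        mask = np.ones(cap.base_shape, dtype=bool)
        crops, valid = extract_leaf(cap, mask)
        np.testing.assert_array_equal(crops["green"], cap.bands["green"].pixels)
        assert valid["pan"].shape == cap.bands["pan"].shape

    def test_square_mask_crop_size(self, capture):
        cap, _ = capture
        mask = np.zeros(cap.base_shape, dtype=bool)
        mask[10:20, 30:40] = True
        crops, _ = extract_leaf(cap, mask)
        assert crops["green"].shape == (10, 10)
        assert crops["pan"].shape == (20, 20)

    def test_background_zeroed_foreground_kept(self, capture):
        cap, gt = capture
        crops, valid = extract_leaf(cap, gt.mask)
        for band in BAND_ORDER:
            assert np.all(crops[band][~valid[band]] == 0.0)
            r0, r1, c0, c1 = mask_bbox(gt.mask if band != "pan"
                                       else np.repeat(np.repeat(gt.mask, 2, 0), 2, 1))
            orig = cap.bands[band].pixels[r0:r1, c0:c1]
            np.testing.assert_array_equal(crops[band][valid[band]], orig[valid[band]])

    def test_empty_mask_raises(self, capture):
        cap, _ = capture
        with pytest.raises(ValueError, match="empty mask"):
            extract_leaf(cap, np.zeros(cap.base_shape, dtype=bool))
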