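"""CSR-UNet building blocks and network contracts.

Layer backward passes are verified against central finite differences;
composite training behaviour is verified by overfitting a single sample
(the end-to-end check that gradients flow correctly through the whole
encoder-decoder)."""

import numpy as np
import pytest

from csrseg import model
from csrseg.losses import TverskyConfig
from csrseg.nn.layers import (BatchNorm, Conv, CSRBlock, MaxPool, SEBlock,
                              TransposedConv)
from csrseg.nn.optim import Adam, cosine_lr
from csrseg.pipeline import softmax_focal_tversky


def numeric_grad_check(layer, x, n_samples=4, eps=1e-2, train=True):
    """Compare analytic input/parameter gradients of a layer against central
    differences of sum(forward * R) for a fixed random projection R."""
    rng = np.random.default_rng(0)
    R = rng.normal(size=layer.forward(x, train).shape).astype(np.float32)

    def loss():
        return float(np.sum(layer.forward(x, train).astype(np.float64) * R))

    for p in layer.params():
        p.zero_grad()
    layer.forward(x, train)
    dx = layer.backward(R.copy())
    worst = 0.0
    for arr, grad in [(x, dx)] + [(p.value, p.grad) for p in layer.params()]:
        flat, gflat = arr.ravel(), grad.ravel()
        for idx in rng.integers(0, flat.size, n_samples):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            denom = max(1e-4, abs(num) + abs(gflat[idx]))
            worst = max(worst, abs(num - gflat[idx]) / denom)
    return worst


def _se_away_from_kink(rng):
    """SE block with the hidden bias shifted so finite-difference probes do
    not cross the ReLU kink (which is non-differentiable, not a bug)."""
    se = SEBlock(4, 2, rng)
    se.b1.value[...] = 0.5
    return se


class TestLayerGradients:
    @pytest.mark.parametrize("make,shape", [
        (lambda rng: Conv(3, 4, 3, 3, rng, bias=True), (2, 3, 6, 6, 4)),
        (lambda rng: Conv(3, 4, 1, 3, rng, bias=True), (2, 3, 6, 6, 4)),
        (lambda rng: Conv(5, 4, 3, 2, rng), (2, 5, 8, 8)),
        (lambda rng: BatchNorm(3), (2, 3, 6, 6, 4)),
        (lambda rng: _se_away_from_kink(rng), (2, 4, 6, 6, 4)),
        (lambda rng: MaxPool((2, 2, 2)), (2, 3, 6, 6, 4)),
        (lambda rng: MaxPool((2, 2, 1)), (2, 3, 6, 6, 5)),
        (lambda rng: TransposedConv(3, 4, (2, 2, 1), rng), (2, 3, 5, 5, 3)),
        (lambda rng: TransposedConv(3, 4, (2, 2), rng), (2, 3, 5, 5)),
    ])
    def test_backward_matches_finite_differences(self, make, shape):
        rng = np.random.default_rng(7)
        layer = make(rng)
        x = rng.normal(size=shape).astype(np.float32)
        assert numeric_grad_check(layer, x) < 2e-3

    def test_batchnorm_eval_mode_gradient(self):
        rng = np.random.default_rng(7)
        bn = BatchNorm(3)
        x = rng.normal(size=(2, 3, 5, 5)).astype(np.float32)
        assert numeric_grad_check(bn, x, train=False) < 2e-3


class TestSEBlock:
    def test_identity_when_gate_forced_open(self, rng):
        se = SEBlock(4, 2, rng)
        se.w1.value[...] = 0.0
        se.w2.value[...] = 0.0
        se.b2.value[...] = 30.0  # sigmoid(30) ~ 1
        x = rng.normal(size=(1, 4, 5, 5, 3)).astype(np.float32)
        assert np.allclose(se.forward(x), x, atol=1e-5)

    def test_gate_strictly_shrinks_magnitude(self, rng):
        se = SEBlock(4, 2, rng)
        x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
        y = se.forward(x)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-7)

    def test_pooling_equals_channel_means(self, rng):
        se = SEBlock(3, 2, rng)
        consts = np.array([0.5, -1.0, 2.0], np.float32)
        x = np.broadcast_to(consts[None, :, None, None], (1, 3, 4, 4)).copy()
        se.forward(x)
        pooled = se._cache[1]
        assert np.allclose(pooled[0], consts)


class TestCSRBlock:
    def test_shape_preserving_and_finite(self, rng):
        blk = CSRBlock(3, 8, 3, rng)
        x = rng.normal(size=(1, 3, 8, 8, 4)).astype(np.float32)
        y = blk.forward(x, train=True)
        assert y.shape == (1, 8, 8, 8, 4)
        assert np.all(np.isfinite(y))

    def test_identity_shortcut_when_channels_match(self, rng):
        assert CSRBlock(8, 8, 2, rng).shortcut is None
        assert CSRBlock(4, 8, 2, rng).shortcut is not None

    def test_overfits_single_sample(self, rng):
        """200 gradient steps on one sample drive the focal Tversky loss to
        below a tenth of its initial value."""
        cfg = model.ModelConfig(dims="2.5d", in_channels=5, base_channels=8,
                                depth=2)
        net = model.build_csr_unet(cfg, seed=0)
        x = rng.normal(size=(1, 5, 32, 32)).astype(np.float32)
        y = np.zeros((1, 32, 32), bool)
        y[0, 10:20, 8:18] = True
        opt = Adam(net.params(), lr=1e-3)
        tv = TverskyConfig()
        losses = []
        for _ in range(200):
            logits = net.forward(x, train=True)
            loss, dl = softmax_focal_tversky(logits, y, tv)
            losses.append(loss)
            net.zero_grad()
            net.backward(dl)
            opt.step()
        assert losses[-1] < 0.1 * losses[0]


class TestUNetContracts:
    def test_3d_shape_contract(self, rng):
        cfg = model.ModelConfig(dims="3d", base_channels=8, depth=2, min_z=16)
        net = model.build_csr_unet(cfg, seed=0)
        x = rng.normal(size=(1, 1, 64, 64, 16)).astype(np.float32)
        assert net.forward(x).shape == (1, 2, 64, 64, 16)

    def test_2p5d_single_slice_output(self, rng):
        cfg = model.ModelConfig(dims="2.5d", in_channels=5, base_channels=8,
                                depth=2)
        net = model.build_csr_unet(cfg, seed=0)
        x = rng.normal(size=(1, 5, 96, 96)).astype(np.float32)
        assert net.forward(x).shape == (1, 2, 96, 96)

    @pytest.mark.parametrize("shape", [(21, 19, 7), (16, 16, 5), (33, 40, 11)])
    def test_non_divisible_shapes_pad_and_crop(self, rng, shape):
        cfg = model.ModelConfig(dims="3d", base_channels=4, depth=2,
                                se_reduction=4, min_z=shape[2])
        net = model.build_csr_unet(cfg, seed=0)
        x = rng.normal(size=(1, 1) + shape).astype(np.float32)
        assert net.forward(x).shape == (1, 2) + shape

    def test_build_determinism(self):
        cfg = model.ModelConfig(dims="3d", base_channels=8, depth=2)
        a = model.build_csr_unet(cfg, seed=3)
        b = model.build_csr_unet(cfg, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_eval_forward_deterministic(self, rng):
        cfg = model.ModelConfig(dims="3d", base_channels=4, depth=1)
        net = model.build_csr_unet(cfg, seed=0)
        x = rng.normal(size=(1, 1, 12, 12, 4)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_gradient_reaches_every_parameter(self, rng):
        cfg = model.ModelConfig(dims="3d", base_channels=4, depth=2,
                                se_reduction=4, min_z=8)
        net = model.build_csr_unet(cfg, seed=1)
        x = rng.normal(size=(2, 1, 16, 16, 8)).astype(np.float32)
        y = rng.random((2, 16, 16, 8)) > 0.7
        logits = net.forward(x, train=True)
        _, dl = softmax_focal_tversky(logits, y, TverskyConfig())
        net.zero_grad()
        net.backward(dl)
        for p in net.params():
            assert np.any(p.grad != 0), f"no gradient reached {p.name}"

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        cfg = model.ModelConfig(dims="3d", base_channels=4, depth=1)
        net = model.build_csr_unet(cfg, seed=2)
        x = rng.normal(size=(1, 1, 12, 12, 4)).astype(np.float32)
        ref = net.predict_proba(x)
        path = model.save_checkpoint(net, tmp_path / "net.npz")
        back = model.load_checkpoint(path)
        assert np.array_equal(back.predict_proba(x), ref)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            model.ModelConfig(dims="4d")
        with pytest.raises(ValueError):
            model.ModelConfig(base_channels=2, se_reduction=4)
        with pytest.raises(ValueError):
            model.ModelConfig(depth=0)


class TestSchedulesAndPooling:
    def test_cosine_final_lr_below_one_percent(self):
        lrs = [cosine_lr(e, 20, 1e-3) for e in range(20)]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[-1] < 0.01 * 1e-3
        assert all(b < a for a, b in zip(lrs, lrs[1:]))

    def test_z_pooling_disabled_for_thin_volumes(self):
        assert model.plan_z_pooling(5, 3) == (True, False, False)
        assert model.plan_z_pooling(16, 2) == (True, True)
        assert model.plan_z_pooling(2, 2) == (False, False)
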