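"""Network-engine layers: finite-difference gradient checks and layer contracts.

Gradient checks run in float64 (the engine's working dtype is switchable)
against central differences; each check covers every code path the layer
dispatches to (direct, GEMM, phase-decomposed stride-2, 1x1).
"""

import numpy as np
import pytest

import spinesva.engine as eng
from spinesva.engine import (
    BilinearUpsample2x,
    Conv2d,
    GroupNorm,
    MaxPool2x,
    ReLU,
    SGDNesterov,
)


@pytest.fixture
def f64_engine():
    eng.set_dtype(np.float64)
    yield
    eng.set_dtype(np.float32)


def _check_layer_gradients(layer, x, atol=1e-7):
    """Central-difference check of input and parameter gradients."""
    rng = np.random.default_rng(0)
    y = layer.forward(x)
    dy = rng.normal(size=y.shape)

    def loss(out):
        return float(np.sum(out * dy))

    dx = layer.backward(dy)
    eps = 1e-6
    # input gradient at a handful of positions
    flat = x.ravel()
    for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
        orig = flat[i]
        flat[i] = orig + eps
        lp = loss(layer.forward(x))
        flat[i] = orig - eps
        lm = loss(layer.forward(x))
        flat[i] = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(dx.ravel()[i], abs=atol, rel=1e-4)
    # parameter gradients
    layer.forward(x)
    for p in layer.params():
        p.zero_grad()
    layer.backward(dy)
    for p in layer.params():
        pf = p.value.ravel()
        for i in rng.choice(pf.size, size=min(4, pf.size), replace=False):
            orig = pf[i]
            pf[i] = orig + eps
            lp = loss(layer.forward(x))
            pf[i] = orig - eps
            lm = loss(layer.forward(x))
            pf[i] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(p.grad.ravel()[i], abs=atol, rel=1e-4)


@pytest.mark.parametrize(
    "kernel,stride,shape",
    [
        (3, 1, (2, 3, 40, 24)),   # direct numba path (960 px > GEMM limit)
        (3, 1, (2, 3, 10, 8)),    # small-spatial GEMM path
        (3, 2, (2, 3, 64, 48)),   # phase-decomposed stride-2 path
        (3, 2, (2, 3, 12, 8)),    # stride-2 via GEMM
        (1, 1, (2, 4, 9, 7)),     # pointwise
        (1, 2, (2, 4, 10, 8)),    # pointwise downsampling
    ],
)
def test_conv_gradients_all_paths(f64_engine, kernel, stride, shape):
    rng = np.random.default_rng(3)
    layer = Conv2d(shape[1], 5, kernel, stride=stride, rng=rng)
    x = rng.normal(size=shape)
    _check_layer_gradients(layer, x)


def test_conv_matches_scipy_reference(f64_engine):
    """3x3 'same' convolution agrees with scipy.ndimage on a single channel."""
    from scipy import ndimage

    rng = np.random.default_rng(7)
    layer = Conv2d(1, 1, 3, rng=rng, bias=False)
    x = rng.normal(size=(1, 1, 20, 16))
    out = layer.forward(x)[0, 0]
    kernel = layer.weight.value[:, :, 0, 0]
    ref = ndimage.correlate(x[0, 0], kernel, mode="constant", cval=0.0)
    np.testing.assert_allclose(out, ref, atol=1e-12)


def test_group_norm_gradients_and_statistics(f64_engine):
    rng = np.random.default_rng(5)
    layer = GroupNorm(6, 3)
    x = rng.normal(loc=2.0, scale=3.0, size=(2, 6, 7, 5))
    y = layer.forward(x)
    # per-sample, per-group zero mean / unit variance before the affine
    yg = y.reshape(2, 3, -1)
    np.testing.assert_allclose(yg.mean(axis=-1), 0.0, atol=1e-10)
    np.testing.assert_allclose(yg.std(axis=-1), 1.0, atol=1e-3)
    _check_layer_gradients(layer, x)


def test_group_norm_requires_divisible_groups():
    with pytest.raises(ValueError):
        GroupNorm(6, 4)


def test_bilinear_upsample_gradients_and_exact_doubling(f64_engine):
    rng = np.random.default_rng(6)
    layer = BilinearUpsample2x()
    x = rng.normal(size=(2, 3, 6, 5))
    y = layer.forward(x)
    assert y.shape == (2, 3, 12, 10)
    # a constant map upsamples to the same constant
    const = layer.forward(np.full((1, 1, 4, 4), 3.5))
    np.testing.assert_allclose(const, 3.5, atol=1e-12)
    _check_layer_gradients(layer, x)


def test_maxpool_gradients_and_values(f64_engine):
    rng = np.random.default_rng(8)
    layer = MaxPool2x()
    x = rng.normal(size=(2, 3, 8, 6))
    y = layer.forward(x)
    ref = x.reshape(2, 3, 4, 2, 3, 2).max(axis=(3, 5))
    np.testing.assert_allclose(y, ref, atol=1e-14)
    _check_layer_gradients(layer, x)


def test_relu_masks_negatives(f64_engine):
    layer = ReLU()
    x = np.array([[[[-1.0, 0.0, 2.0]]]])
    np.testing.assert_array_equal(layer.forward(x), [[[[0.0, 0.0, 2.0]]]])
    np.testing.assert_array_equal(layer.backward(np.ones_like(x)), [[[[0.0, 0.0, 1.0]]]])


class TestSGDNesterov:
    def test_plain_descent_with_zero_momentum(self):
        p = eng.Parameter(np.array([1.0, -2.0]), weight_decay=False)
        opt = SGDNesterov([p], lr=0.5, momentum=0.0, weight_decay=0.0)
        p.grad[:] = [0.2, -0.4]
        opt.step()
        np.testing.assert_allclose(p.value, [0.9, -1.8], atol=1e-7)

    def test_weight_decay_only_on_flagged_parameters(self):
        w = eng.Parameter(np.array([1.0]), weight_decay=True)
        b = eng.Parameter(np.array([1.0]), weight_decay=False)
        opt = SGDNesterov([w, b], lr=1.0, momentum=0.0, weight_decay=0.1)
        w.grad[:] = 0.0
        b.grad[:] = 0.0
        opt.step()
        assert w.value[0] == pytest.approx(0.9)
        assert b.value[0] == pytest.approx(1.0)

    def test_nesterov_momentum_accelerates(self):
        # constant gradient: second step moves further than the first
        p = eng.Parameter(np.array([0.0]), weight_decay=False)
        opt = SGDNesterov([p], lr=0.1, momentum=0.9, weight_decay=0.0)
        p.grad[:] = 1.0
        opt.step()
        first = -float(p.value[0])
        before = float(p.value[0])
        p.grad[:] = 1.0
        opt.step()
        second = before - float(p.value[0])
        assert second > first

    def test_tiny_updates_survive_float32_parameters(self):
        # updates below float32 ulp of the weight accumulate in the master copy
        p = eng.Parameter(np.array([1.0], dtype=np.float32), weight_decay=False)
        opt = SGDNesterov([p], lr=1e-9, momentum=0.0, weight_decay=0.0)
        for _ in range(1000):
            p.grad[:] = 1.0
            opt.step()
        assert float(p.value[0]) < 1.0  # 1e-6 total, visible in float32
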