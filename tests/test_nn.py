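"""Autodiff engine: gradients vs central finite differences (independent oracle)."""

import numpy as np
import pytest

from stackmae import nn
from stackmae.nn.tensor import Tensor, bce_with_logits, conv3d


def fd_gradients(f, params, eps=1e-3):
    """Central finite differences of the scalar f() w.r.t. each param."""
    grads = []
    for p in params:
        fd = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            hi = float(f().data)
            p.data[i] = orig - eps
            lo = float(f().data)
            p.data[i] = orig
            fd[i] = (hi - lo) / (2 * eps)
        grads.append(fd)
    return grads


def assert_grads_match(f, params, atol=2e-3):
    for p in params:
        p.zero_grad()
    out = f()
    out.backward()
    auto = [p.grad.copy() for p in params]
    numeric = fd_gradients(f, params)
    for a, n in zip(auto, numeric):
        np.testing.assert_allclose(a, n, atol=atol)


@pytest.fixture
def rng():
    return np.random.default_rng(3)


@pytest.mark.parametrize(
    "op",
    [
        lambda x: (x * x + 2.0 * x).mean(),
        lambda x: (x.exp() * x.sigmoid()).sum() * 0.01,
        lambda x: x.softplus().mean(),
        lambda x: x.gelu().mean(),
        lambda x: x.tanh().sum() * 0.1,
        lambda x: x.softmax().__pow__(2).mean(),
        lambda x: (x.reshape(4, 6).transpose(1, 0) ** 3).mean(),
        lambda x: x.upsample_yx(2).mean(axis=None),
    ],
    ids=["poly", "exp-sigmoid", "softplus", "gelu", "tanh", "softmax", "reshape-T", "upsample"],
)
def test_elementwise_and_shape_op_gradients(rng, op):
    x = Tensor(rng.normal(size=(2, 3, 4)) * 0.7, requires_grad=True)
    assert_grads_match(lambda: op(x), [x])


def test_matmul_broadcast_gradients(rng):
    a = Tensor(rng.normal(size=(2, 3, 4)) * 0.5, requires_grad=True)
    b = Tensor(rng.normal(size=(4, 5)) * 0.5, requires_grad=True)
    assert_grads_match(lambda: ((a @ b) ** 2).mean(), [a, b])


def test_gather_scatter_gradients(rng):
    base = Tensor(rng.normal(size=(2, 5, 3)), requires_grad=True)
    rows = Tensor(rng.normal(size=(2, 2, 3)), requires_grad=True)
    idx = np.array([[0, 3], [1, 4]])
    gidx = np.array([[1, 2], [0, 3]])

    def f():
        return (base.scatter_rows(idx, rows).gather_rows(gidx) ** 2).mean()

    assert_grads_match(f, [base, rows])


def test_conv3d_gradients(rng):
    x = Tensor(rng.normal(size=(1, 3, 2, 4, 4)) * 0.5, requires_grad=True)
    w = Tensor(rng.normal(size=(2, 3, 1, 3, 3)) * 0.3, requires_grad=True)
    assert_grads_match(lambda: (conv3d(x, w) ** 2).mean(), [x, w])


def test_conv3d_z_kernel_gradients(rng):
    x = Tensor(rng.normal(size=(1, 2, 3, 3, 3)) * 0.5, requires_grad=True)
    w = Tensor(rng.normal(size=(1, 2, 3, 3, 3)) * 0.3, requires_grad=True)
    assert_grads_match(lambda: (conv3d(x, w) ** 2).mean(), [x, w])


def test_bce_with_logits_matches_definition(rng):
    logits = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    t = (rng.random((3, 4)) > 0.5).astype(np.float32)
    loss = bce_with_logits(logits, t)
    from scipy.special import expit

    p = expit(logits.data)
    ref = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
    assert float(loss.data) == pytest.approx(ref, rel=1e-5)
    assert_grads_match(lambda: bce_with_logits(logits, t), [logits])


def test_transformer_block_gradients(rng):
    blk = nn.Block(6, 2, rng)
    x = Tensor(rng.normal(size=(2, 4, 6)), requires_grad=True)
    params = [x, blk.norm1.gamma, blk.attn.qkv.weight, blk.mlp.fc1.bias]
    assert_grads_match(lambda: (blk(x) ** 2).mean(), params)


def test_layernorm_normalizes(rng):
    ln = nn.LayerNorm(8)
    x = Tensor(rng.normal(size=(3, 8)) * 5 + 2)
    y = ln(x).data
    np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-4)
    np.testing.assert_allclose(y.std(axis=-1), 1.0, atol=1e-2)


def test_pixelshuffle_doubles_inplane_only(rng):
    up = nn.PixelShuffleUp(3, 2, rng)
    x = Tensor(rng.normal(size=(1, 3, 2, 3, 5)))
    y = up(x)
    assert y.shape == (1, 2, 2, 6, 10)
    assert_grads_match(
        lambda: (up(Tensor(x.data)) ** 2).mean(), up.parameters(), atol=3e-3
    )


def test_adamw_and_sgd_reduce_quadratic(rng):
    for opt_cls, kwargs in [
        (nn.AdamW, dict(lr=0.05, weight_decay=0.0)),
        (nn.SGD, dict(lr=0.05, momentum=0.9, weight_decay=0.0)),
    ]:
        w = Tensor(rng.normal(size=(5,)), requires_grad=True)
        opt = opt_cls([w], **kwargs)
        first = float((w * w).sum().data)
        for _ in range(50):
            loss = (w * w).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float((w * w).sum().data) < 0.1 * first


def test_warmup_cosine_schedule_shape():
    lrs = [nn.warmup_cosine_lr(i, 1.0, 10, 100) for i in range(100)]
    assert lrs[9] == pytest.approx(1.0)
    assert all(a <= b + 1e-12 for a, b in zip(lrs[:9], lrs[1:10]))  # warmup rises
    assert all(a >= b - 1e-12 for a, b in zip(lrs[10:-1], lrs[11:]))  # decay falls
    assert lrs[-1] < 0.01


def test_dropout_scaling_and_inference_passthrough(rng):
    x = Tensor(np.ones((1000,)), requires_grad=True)
    y = x.dropout(0.4, np.random.default_rng(0), training=True)
    kept = y.data[y.data > 0]
    assert np.allclose(kept, 1 / 0.6, atol=1e-6)
    assert abs(y.data.mean() - 1.0) < 0.1
    z = x.dropout(0.4, np.random.default_rng(0), training=False)
    np.testing.assert_array_equal(z.data, x.data)
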