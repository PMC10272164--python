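"""Numeric gradient checks and layer contracts for the autodiff engine."""

import numpy as np
import pytest

from semgnn import nn


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(build, arrays, tol=2e-5):
    tensors = [nn.Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    (out * out).sum().backward()

    def scalar():
        return float((build(*[nn.Tensor(a) for a in arrays]).data ** 2).sum())

    for t, a in zip(tensors, arrays):
        ng = numeric_grad(scalar, a)
        scale = np.abs(ng).max() + 1e-12
        assert np.abs(t.grad - ng).max() / scale < tol


RNG = np.random.default_rng(42)

OP_CASES = {
    "matmul": (lambda a, b: a @ b,
               [RNG.standard_normal((3, 4)), RNG.standard_normal((4, 2))]),
    "batched_matmul": (lambda a, b: a @ b,
                       [RNG.standard_normal((2, 3, 4)), RNG.standard_normal((4, 5))]),
    "tanh_mean": (lambda a: a.tanh().mean(axis=0, keepdims=True),
                  [RNG.standard_normal((4, 3))]),
    "broadcast_mul_add": (lambda a, b: a * b + b,
                          [RNG.standard_normal((3, 4)), RNG.standard_normal((1, 4))]),
    "amax": (lambda a: a.amax(axis=1), [RNG.standard_normal((3, 5, 2))]),
    "softmax": (lambda a: nn.softmax(a, axis=-1), [RNG.standard_normal((3, 6))]),
    "reshape_transpose": (lambda a: a.reshape(6, 2).transpose(1, 0),
                          [RNG.standard_normal((3, 4))]),
    "getitem": (lambda a: a[np.array([0, 2, 2])], [RNG.standard_normal((4, 3))]),
    "scatter": (lambda a: nn.scatter_rows(a, np.array([1, 3]), 5),
                [RNG.standard_normal((2, 3))]),
    "concat": (lambda a, b: nn.concat([a, b], axis=1),
               [RNG.standard_normal((2, 3)), RNG.standard_normal((2, 2))]),
    "stack": (lambda a, b: nn.stack([a, b], axis=1),
              [RNG.standard_normal((2, 3)), RNG.standard_normal((2, 3))]),
    "conv2d": (lambda x, w, b: nn.conv2d(x, w, b, stride=2, padding=1),
               [RNG.standard_normal((2, 3, 6, 8)),
                RNG.standard_normal((4, 3, 3, 3)),
                RNG.standard_normal(4)]),
    "conv3d": (lambda x, w, b: nn.conv3d(x, w, b, stride=1, padding=1),
               [RNG.standard_normal((2, 2, 4, 4, 4)),
                RNG.standard_normal((3, 2, 3, 3, 3)),
                RNG.standard_normal(3)]),
    "maxpool2d": (lambda x: nn.maxpool2d(x, 2), [RNG.standard_normal((2, 2, 5, 6))]),
    "maxpool3d": (lambda x: nn.maxpool3d(x, 2), [RNG.standard_normal((1, 2, 7, 7, 7))]),
}


@pytest.mark.parametrize("name", sorted(OP_CASES))
def test_backward_matches_numeric_gradient(name):
    build, arrays = OP_CASES[name]
    assert_grads_match(build, [a.copy() for a in arrays])


def test_grid_conv_equals_reference_convolution():
    rng = np.random.default_rng(3)
    spatial, c = (5, 4, 3), 2
    plan = nn.GridConvPlan(spatial, c)
    rows = nn.Tensor(rng.standard_normal((7, int(np.prod(spatial)))))
    k = nn.Tensor(rng.standard_normal((c, 3, 3, 3)))
    b = nn.Tensor(rng.standard_normal(c))
    out = nn.grid_conv(rows, k, b, plan)
    ref = nn.conv3d(
        nn.Tensor(rows.data.reshape(7, 1, *spatial)),
        nn.Tensor(k.data.reshape(c, 1, 3, 3, 3)), b, padding=1,
    )
    assert np.allclose(out.data.reshape(7, c, *spatial), ref.data, atol=1e-12)


def test_grid_conv_gradients():
    rng = np.random.default_rng(4)
    plan = nn.GridConvPlan((4, 4), 2)
    arrays = [rng.standard_normal((5, 16)), rng.standard_normal((2, 3, 3)),
              rng.standard_normal(2)]
    assert_grads_match(lambda r, k, b: nn.grid_conv(r, k, b, plan), arrays)


class TestAttention:
    def test_rows_are_distributions_and_padding_excluded(self):
        rng = np.random.default_rng(0)
        att = nn.SelfAttention(6, 4, rng, dtype=np.float64)
        mask = np.array([[True, True, True, False]])
        x = nn.Tensor(rng.standard_normal((1, 4, 6)))
        att(x, mask)
        p = att.last_attention[0]
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(p[:, 3] == 0.0)

    def test_uniform_inputs_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        att = nn.SelfAttention(6, 4, rng, dtype=np.float64)
        x = nn.Tensor(np.ones((1, 5, 6)))
        mask = np.array([[True] * 4 + [False]])
        att(x, mask)
        assert np.allclose(att.last_attention[0, 0, :4], 0.25, atol=1e-12)

    def test_attention_gradients(self):
        rng = np.random.default_rng(5)
        att = nn.SelfAttention(4, 3, rng, dtype=np.float64)
        x = rng.standard_normal((2, 3, 4))

        def build(t):
            return att(t)

        assert_grads_match(build, [x])


class TestBatchNorm:
    def test_train_mode_normalizes_valid_rows(self):
        bn = nn.BatchNorm(3, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 3)) * 4 + 2
        out = bn(nn.Tensor(x), train=True)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-7)
        assert np.allclose(out.data.std(axis=0), 1.0, atol=1e-3)

    def test_row_weight_excludes_masked_rows(self):
        bn = nn.BatchNorm(2, dtype=np.float64)
        x = np.array([[1.0, 2.0], [3.0, 4.0], [100.0, 100.0]])
        w = np.array([1.0, 1.0, 0.0])
        out = bn(nn.Tensor(x), train=True, row_weight=w)
        # statistics ignore the masked outlier row
        assert np.allclose(out.data[:2].mean(axis=0), 0.0, atol=1e-7)

    def test_eval_mode_uses_running_stats(self):
        bn = nn.BatchNorm(2, dtype=np.float64)
        rng = np.random.default_rng(1)
        for _ in range(50):
            bn(nn.Tensor(rng.standard_normal((16, 2)) + 5.0), train=True)
        out = bn(nn.Tensor(np.full((4, 2), 5.0)), train=False)
        assert np.abs(out.data).max() < 0.5


def test_adam_minimizes_quadratic():
    rng = np.random.default_rng(0)
    w = nn.Tensor(rng.standard_normal(5), requires_grad=True)
    target = np.arange(5.0)
    opt = nn.Adam([w], lr=0.1)
    for _ in range(200):
        loss = ((w - nn.Tensor(target)) ** 2.0).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(w.data - target).max() < 1e-3
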