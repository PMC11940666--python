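import numpy as np
import pytest

from hicenhance.nn import Adam, Conv2d, LayerNorm, Linear, Module, Tensor, no_grad


def numgrad(f, x, eps=1e-3):
    """Central-difference gradient of scalar f wrt float32 array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f1 = f()
        x[i] = orig - eps
        f2 = f()
        x[i] = orig
        g[i] = (f1 - f2) / (2 * eps)
    return g


def check(make_loss, *tensors, rtol=2e-2, atol=2e-2):
    loss = make_loss()
    lossT = loss if isinstance(loss, Tensor) else Tensor(loss)
    lossT.backward()
    for t in tensors:
        gn = numgrad(lambda: float(make_loss().data), t.data)
        scale = max(1.0, np.abs(gn).max())
        np.testing.assert_allclose(t.grad / scale, gn / scale, rtol=rtol, atol=atol)


rng = np.random.default_rng(0)


def T(*shape, grad=True):
    return Tensor(rng.normal(size=shape).astype(np.float32), requires_grad=grad)


class TestElementwiseOps:
    def test_add_mul_sub_div(self):
        a, b = T(3, 4), T(3, 4)
        check(lambda: ((a + b) * (a - b) / (b * b + Tensor(3.0))).sum(), a, b)

    def test_scalar_mul(self):
        a = T(4, 5)
        check(lambda: (a * 2.5).sum(), a)

    def test_pow(self):
        a = Tensor(np.abs(rng.normal(size=(3, 3))).astype(np.float32) + 0.5,
                   requires_grad=True)
        check(lambda: (a**3).sum(), a)

    def test_relu_sigmoid_silu_abs(self):
        a = T(4, 4)
        check(lambda: (a.relu() + a.sigmoid() + a.silu()).sum(), a)
        b = Tensor(rng.normal(size=(4,)).astype(np.float32) + 2.0, requires_grad=True)
        check(lambda: b.abs().sum(), b)

    def test_broadcasting_accumulates(self):
        a, b = T(3, 4), T(4)
        check(lambda: (a * b).sum(), a, b)

    def test_softmax_rows_sum_one(self):
        a = T(5, 7)
        s = a.softmax()
        np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, rtol=1e-5)
        check(lambda: (a.softmax() * a.softmax()).sum(), a)


class TestShapes:
    def test_reshape_transpose_getitem(self):
        a = T(2, 3, 4)
        check(lambda: (a.reshape(6, 4).transpose(1, 0)[1:3] ** 2).sum(), a)

    def test_concat(self):
        a, b = T(2, 3), T(2, 5)
        check(lambda: (Tensor.concat([a, b], axis=1) ** 2).sum(), a, b)

    def test_matmul_batched(self):
        a, b = T(2, 3, 4), T(2, 4, 5)
        check(lambda: (a @ b).sum(), a, b)

    def test_mean_sum_axis(self):
        a = T(3, 4, 5)
        check(lambda: a.mean(axis=2).sum() + a.sum(), a)


class TestSpatialOps:
    def test_conv2d_matches_scipy(self):
        from scipy.signal import correlate2d

        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        w = rng.normal(size=(4, 3, 3, 3)).astype(np.float32)
        y = Tensor(x).conv2d(Tensor(w), padding=1).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for b in range(2):
            for o in range(4):
                want = sum(
                    correlate2d(xp[b, c], w[o, c], mode="valid") for c in range(3)
                )
                np.testing.assert_allclose(y[b, o], want, atol=1e-4)

    def test_conv2d_grads(self):
        x, w, b = T(2, 2, 6, 6), T(3, 2, 3, 3), T(3)
        check(lambda: (x.conv2d(w, b, padding=1) ** 2).sum(), x, w, b)

    def test_conv1x1_grads(self):
        x, w = T(2, 4, 5, 5), T(6, 4, 1, 1)
        check(lambda: (x.conv2d(w) ** 2).sum(), x, w)

    def test_avg_pool(self):
        x = T(1, 1, 4, 4)
        y = x.avg_pool2()
        assert y.shape == (1, 1, 2, 2)
        np.testing.assert_allclose(y.data[0, 0, 0, 0], x.data[0, 0, :2, :2].mean(),
                                   rtol=1e-6)
        check(lambda: (x.avg_pool2() ** 2).sum(), x)

    def test_bilinear_identity_and_grads(self):
        x = T(1, 2, 4, 4)
        np.testing.assert_allclose(x.resize_bilinear(4, 4).data, x.data, atol=1e-6)
        check(lambda: (x.resize_bilinear(8, 8) ** 2).sum(), x)

    def test_pixel_shuffle_inverse_of_layout(self):
        x = T(1, 8, 3, 3)
        y = x.pixel_shuffle(2)
        assert y.shape == (1, 2, 6, 6)
        check(lambda: (x.pixel_shuffle(2) ** 2).sum(), x)

    def test_sdpa_matches_dense_chain(self):
        q, k, v = T(2, 2, 5, 3), T(2, 2, 5, 3), T(2, 2, 5, 3)
        scale = 1 / np.sqrt(3)
        fused = Tensor.sdpa(q, k, v, scale)
        att = (q.data * scale) @ np.swapaxes(k.data, -1, -2)
        e = np.exp(att - att.max(-1, keepdims=True))
        p = e / e.sum(-1, keepdims=True)
        np.testing.assert_allclose(fused.data, p @ v.data, atol=1e-5)
        check(lambda: (Tensor.sdpa(q, k, v, scale) ** 2).sum(), q, k, v)

    def test_layer_norm(self):
        x, g, b = T(2, 4, 6), T(6), T(6)
        y = x.layer_norm(g, b)
        # normalized pre-affine stats
        xhat = (y.data - b.data) / g.data
        np.testing.assert_allclose(xhat.mean(-1), 0.0, atol=1e-5)
        check(lambda: (x.layer_norm(g, b) ** 2).sum(), x, g, b)


class TestAutogradMechanics:
    def test_no_grad_blocks_graph(self):
        a = T(3, 3)
        with no_grad():
            y = (a * a).sum()
        assert not y.requires_grad

    def test_grad_accumulates_over_uses(self):
        a = T(3)
        (a + a).sum().backward()
        np.testing.assert_allclose(a.grad, 2.0)

    def test_backward_frees_graph(self):
        a = T(2, 2)
        y = (a * a).sum()
        y.backward()
        assert y._backward is None

    def test_aliased_add_gradient_not_shared(self):
        # y = a + b must give each parent an independently owned gradient
        a, b = T(3), T(3)
        y = a + b
        (y * Tensor(np.array([1.0, 2.0, 3.0], dtype=np.float32))).sum().backward()
        a.grad[0] = 99.0
        assert b.grad[0] != 99.0


class TestLayers:
    def test_parameter_registration_and_sharing(self):
        class M(Module):
            def __init__(self):
                r = np.random.default_rng(0)
                self.a = Linear(3, 3, r)
                self.b = self.a  # shared
                self.stack = [Linear(3, 2, r)]

        m = M()
        names = dict(m.named_parameters())
        assert "a.weight" in names and "stack.0.weight" in names
        # dedup: shared module counted once
        assert len(m.parameters()) == 4

    def test_state_dict_roundtrip(self, tmp_path):
        r = np.random.default_rng(1)
        m1, m2 = Linear(4, 3, r), Linear(4, 3, np.random.default_rng(2))
        p = tmp_path / "w.npz"
        m1.save(p)
        m2.load(p)
        np.testing.assert_array_equal(m1.weight.data, m2.weight.data)

    def test_load_rejects_mismatch(self):
        r = np.random.default_rng(1)
        m = Linear(4, 3, r)
        with pytest.raises(KeyError):
            m.load_state_dict({"weight": m.weight.data})  # missing bias
        with pytest.raises(ValueError):
            m.load_state_dict({"weight": np.zeros((2, 2)), "bias": m.bias.data})

    def test_adam_decreases_quadratic(self):
        r = np.random.default_rng(3)
        lin = Linear(4, 1, r)
        x = Tensor(r.normal(size=(16, 4)).astype(np.float32))
        w_true = r.normal(size=(4, 1)).astype(np.float32)
        target = Tensor(x.data @ w_true + 0.3)
        opt = Adam(lin.parameters(), lr=0.05)
        first = None
        for _ in range(50):
            loss = ((lin(x) - target) ** 2).mean()
            if first is None:
                first = loss.item()
            lin.zero_grad()
            loss.backward()
            opt.step()
        assert loss.item() < 0.2 * first

    def test_conv_layer_padding_default(self):
        r = np.random.default_rng(0)
        conv = Conv2d(2, 3, 3, r)
        y = conv(Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32)))
        assert y.shape == (1, 3, 8, 8)

    def test_layer_norm_module(self):
        r = np.random.default_rng(0)
        ln = LayerNorm(5)
        y = ln(Tensor(np.arange(10, dtype=np.float32).reshape(2, 5)))
        np.testing.assert_allclose(y.data.mean(-1), 0.0, atol=1e-5)
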