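import numpy as np
import pytest

from mitransfer.nn import (
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    Network,
    ReLU,
    sgd_train,
    softmax,
)


def _conv_scalar_oracle(x, w, b, pad):
    """Direct quadruple-loop convolution, one output element at a time."""
    bsz, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    out = np.zeros((bsz, cout, ho, wo))
    for n in range(bsz):
        for o in range(cout):
            for i in range(ho):
                for j in range(wo):
                    acc = b[o]
                    for c in range(cin):
                        for u in range(k):
                            for v in range(k):
                                acc += w[o, c, u, v] * xp[n, c, i + u, j + v]
                    out[n, o, i, j] = acc
    return out


def _pool_scalar_oracle(x, k):
    bsz, c, h, w = x.shape
    ho, wo = h // k, w // k
    out = np.zeros((bsz, c, ho, wo))
    for n in range(bsz):
        for ch in range(c):
            for i in range(ho):
                for j in range(wo):
                    out[n, ch, i, j] = x[n, ch, i * k:(i + 1) * k,
                                         j * k:(j + 1) * k].max()
    return out


def _numeric_grad(f, p, eps=1e-6):
    g = np.zeros_like(p)
    it = np.nditer(p, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = p[idx]
        p[idx] = old + eps
        fp = f()
        p[idx] = old - eps
        fm = f()
        p[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestConv2D:
    def test_forward_matches_scalar_loop_oracle(self, rng):
        for pad in (0, 1):
            conv = Conv2D(2, 3, kernel_size=3, padding=pad, rng=rng)
            x = rng.standard_normal((2, 2, 6, 5))
            ref = _conv_scalar_oracle(x, conv.params["W"], conv.params["b"], pad)
            np.testing.assert_allclose(conv.forward(x), ref, atol=1e-10)

    def test_same_padding_preserves_spatial_size(self, rng):
        conv = Conv2D(1, 4, kernel_size=3, padding="same", rng=rng)
        assert conv.forward(rng.standard_normal((1, 1, 7, 9))).shape == (1, 4, 7, 9)

    def test_identity_kernel_reproduces_input(self):
        conv = Conv2D(1, 1, kernel_size=3, padding="same")
        conv.params["W"][:] = 0.0
        conv.params["W"][0, 0, 1, 1] = 1.0  # centered delta kernel
        x = np.arange(20.0).reshape(1, 1, 4, 5)
        np.testing.assert_allclose(conv.forward(x), x)

    def test_weight_gradient_matches_finite_differences(self, rng):
        conv = Conv2D(1, 2, kernel_size=3, padding=1, rng=rng)
        x = rng.standard_normal((2, 1, 5, 5))
        t = rng.standard_normal(conv.forward(x).shape)

        def loss():
            return 0.5 * ((conv.forward(x) - t) ** 2).sum()

        out = conv.forward(x)
        conv.backward(out - t)
        for name in ("W", "b"):
            num = _numeric_grad(loss, conv.params[name])
            np.testing.assert_allclose(conv.grads[name], num, atol=1e-6)

    def test_input_gradient_matches_finite_differences(self, rng):
        conv = Conv2D(2, 1, kernel_size=3, padding=1, rng=rng)
        x = rng.standard_normal((1, 2, 4, 4))
        t = rng.standard_normal(conv.forward(x).shape)
        out = conv.forward(x)
        dx = conv.backward(out - t)

        def loss():
            return 0.5 * ((conv.forward(x) - t) ** 2).sum()

        num = _numeric_grad(loss, x)
        np.testing.assert_allclose(dx, num, atol=1e-6)


class TestActivationsAndPooling:
    def test_relu_pointwise(self):
        x = np.array([[-2.0, -0.0, 0.5, 3.0]])
        np.testing.assert_array_equal(ReLU().forward(x),
                                      [[0.0, 0.0, 0.5, 3.0]])

    def test_relu_gradient_gates_on_positive_input(self):
        r = ReLU()
        r.forward(np.array([[-1.0, 2.0]]))
        np.testing.assert_array_equal(r.backward(np.array([[5.0, 5.0]])),
                                      [[0.0, 5.0]])

    def test_maxpool_matches_scalar_oracle(self, rng):
        x = rng.standard_normal((2, 3, 6, 8))
        pool = MaxPool2D(k=2)
        np.testing.assert_array_equal(pool.forward(x), _pool_scalar_oracle(x, 2))

    def test_maxpool_crops_remainder(self, rng):
        x = rng.standard_normal((1, 1, 5, 7))
        assert MaxPool2D(k=2).forward(x).shape == (1, 1, 2, 3)

    def test_maxpool_gradient_routes_to_argmax(self):
        x = np.array([[[[1.0, 2.0], [4.0, 3.0]]]])  # max at (1, 0)
        pool = MaxPool2D(k=2)
        pool.forward(x)
        dx = pool.backward(np.array([[[[7.0]]]]))
        np.testing.assert_array_equal(dx, [[[[0.0, 0.0], [7.0, 0.0]]]])

    def test_softmax_rows_are_distributions(self, rng):
        p = softmax(rng.standard_normal((5, 3)) * 50)  # large logits: stable
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_softmax_hand_computed(self):
        p = softmax(np.array([[np.log(1.0), np.log(3.0)]]))
        np.testing.assert_allclose(p, [[0.25, 0.75]], atol=1e-12)


class TestDense:
    def test_forward_is_affine_map(self, rng):
        d = Dense(3, 2, rng=rng)
        x = rng.standard_normal((4, 3))
        np.testing.assert_allclose(d.forward(x),
                                   x @ d.params["W"].T + d.params["b"])

    def test_gradients_match_finite_differences(self, rng):
        d = Dense(3, 2, rng=rng)
        x = rng.standard_normal((4, 3))
        t = rng.standard_normal((4, 2))

        def loss():
            return 0.5 * ((d.forward(x) - t) ** 2).sum()

        d.backward(d.forward(x) - t)
        for name in ("W", "b"):
            num = _numeric_grad(loss, d.params[name])
            np.testing.assert_allclose(d.grads[name], num, atol=1e-6)


class TestNetwork:
    def _tiny_net(self, seed=0):
        rng = np.random.default_rng(seed)
        return Network([
            Conv2D(1, 2, kernel_size=3, padding="same", rng=rng),
            ReLU(),
            MaxPool2D(2),
            Flatten(),
            Dense(2 * 2 * 2, 2, rng=rng),
        ])

    def test_loss_gradient_matches_finite_differences_end_to_end(self, rng):
        net = self._tiny_net()
        x = rng.standard_normal((3, 1, 4, 4))
        y = np.eye(2)[np.array([0, 1, 0])]
        net.loss_and_grad(x, y)
        analytic = [l.grads[k].copy() for l in net.trainable_layers()
                    for k in ("W", "b")]
        numeric = []
        for l in net.trainable_layers():
            for k in ("W", "b"):
                numeric.append(_numeric_grad(
                    lambda: net.loss_and_grad(x, y), l.params[k]))
        for a, n in zip(analytic, numeric):
            np.testing.assert_allclose(a, n, atol=1e-6)

    def test_training_reduces_loss_on_separable_data(self, rng):
        net = self._tiny_net()
        x = np.zeros((20, 1, 4, 4))
        y = np.repeat([0, 1], 10)
        x[:10, 0, :2] = 1.0 + 0.1 * rng.standard_normal((10, 2, 4))
        x[10:, 0, 2:] = 1.0 + 0.1 * rng.standard_normal((10, 2, 4))
        log = sgd_train(net, x, y, lr=0.1, epochs=30, batch_size=4,
                        rng=np.random.default_rng(1))
        assert log[-1] < 0.5 * log[0]
        assert (net.predict_proba(x).argmax(axis=1) == y).mean() >= 0.9

    def test_training_is_bit_reproducible(self, rng):
        x = rng.standard_normal((12, 1, 4, 4))
        y = np.tile([0, 1], 6)
        vecs = []
        for _ in range(2):
            net = self._tiny_net(seed=3)
            sgd_train(net, x, y, lr=0.05, epochs=5, batch_size=3,
                      rng=np.random.default_rng(7))
            vecs.append(net.parameter_vector())
        np.testing.assert_array_equal(vecs[0], vecs[1])

    def test_frozen_layers_do_not_update(self, rng):
        net = self._tiny_net()
        before = [l.params["W"].copy() for l in net.trainable_layers()]
        net.freeze_first(1)
        x = rng.standard_normal((8, 1, 4, 4))
        y = np.tile([0, 1], 4)
        sgd_train(net, x, y, lr=0.1, epochs=3, batch_size=4,
                  rng=np.random.default_rng(0))
        after = [l.params["W"] for l in net.trainable_layers()]
        np.testing.assert_array_equal(before[0], after[0])  # frozen conv
        assert np.abs(before[1] - after[1]).max() > 0  # dense trained

    def test_freeze_more_than_available_rejected(self):
        with pytest.raises(ValueError, match="cannot freeze"):
            self._tiny_net().freeze_first(5)

    def test_diverging_loss_raises(self, rng):
        net = self._tiny_net()
        x = 1e3 * rng.standard_normal((8, 1, 4, 4))
        y = np.tile([0, 1], 4)
        with pytest.raises(FloatingPointError, match="non-finite"), \
                np.errstate(over="ignore", invalid="ignore"):
            sgd_train(net, x, y, lr=1e6, epochs=50, batch_size=2,
                      rng=np.random.default_rng(2))
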