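"""Minimal NumPy neural-network engine for the CNN classifiers.

Implements exactly the layer algebra the classifiers need, with explicit
forward and backward passes:

* 2D convolution: y[i,j] = f( sum_{c,u,v} W[k,c,u,v] * I[c, i+u, j+v] + b[k] )
* ReLU activation h(x) = max(0, x)
* max pooling over k x k windows (stride k)
* fully connected layers y_l = h(w y_{l-1} + b)
* 2-way softmax output trained with cross-entropy by plain SGD.

Everything is float64 and single-threaded; given a seed, initialization,
shuffling and hence training are bit-reproducible.  Arrays are
(batch, channels, height, width) for image layers and (batch, features)
after flattening.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "softmax",
    "Network",
    "sgd_train",
]


def _im2col(xp: np.ndarray, k: int):
    """Sliding k x k patches of a padded batch -> (B, C*k*k, Ho*Wo)."""
    b, c, h, w = xp.shape
    ho, wo = h - k + 1, w - k + 1
    cols = np.empty((b, c, k, k, ho, wo), dtype=xp.dtype)
    for u in range(k):
        for v in range(k):
            cols[:, :, u, v] = xp[:, :, u : u + ho, v : v + wo]
    return cols.reshape(b, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, shape, k: int, ho: int, wo: int):
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    b, c, h, w = shape
    dx = np.zeros(shape, dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, k, k, ho, wo)
    for u in range(k):
        for v in range(k):
            dx[:, :, u : u + ho, v : v + wo] += dcols[:, :, u, v]
    return dx


class Layer:
    trainable = False
    params: dict = {}
    grads: dict = {}
    frozen = False

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution (cross-correlation), stride 1, square kernel.

    ``padding`` is an integer number of zero rows/columns on each border;
    "same" picks k//2 so output size equals input size for odd k.
    """

    trainable = True

    def __init__(self, in_channels, out_channels, kernel_size=3,
                 padding="same", rng=None):
        k = int(kernel_size)
        self.k = k
        self.pad = k // 2 if padding == "same" else int(padding)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * k * k
        w = rng.standard_normal((out_channels, in_channels, k, k))
        self.params = {
            "W": w * np.sqrt(2.0 / fan_in),
            "b": np.zeros(out_channels),
        }
        self.grads = {}

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.k)
        self._cache = (x.shape, xp.shape, cols, ho, wo)
        w = self.params["W"]
        wmat = w.reshape(w.shape[0], -1)  # (out, C*k*k)
        out = np.einsum("of,bfl->bol", wmat, cols) + self.params["b"][None, :, None]
        return out.reshape(x.shape[0], w.shape[0], ho, wo)

    def backward(self, dout):
        x_shape, xp_shape, cols, ho, wo = self._cache
        b = dout.shape[0]
        w = self.params["W"]
        dmat = dout.reshape(b, w.shape[0], ho * wo)
        self.grads["W"] = np.einsum("bol,bfl->of", dmat, cols).reshape(w.shape)
        self.grads["b"] = dmat.sum(axis=(0, 2))
        wmat = w.reshape(w.shape[0], -1)
        dcols = np.einsum("of,bol->bfl", wmat, dmat)
        dxp = _col2im(dcols, xp_shape, self.k, ho, wo)
        p = self.pad
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """Max pooling over k x k windows with stride k (remainder cropped)."""

    def __init__(self, k=2):
        self.k = int(k)

    def forward(self, x):
        k = self.k
        b, c, h, w = x.shape
        ho, wo = h // k, w // k
        xc = x[:, :, : ho * k, : wo * k]
        windows = (
            xc.reshape(b, c, ho, k, wo, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho, wo, k * k)
        )
        self._argmax = windows.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(
            windows, self._argmax[..., None], axis=-1
        )[..., 0]

    def backward(self, dout):
        k = self.k
        b, c, h, w = self._shape
        ho, wo = h // k, w // k
        dwin = np.zeros((b, c, ho, wo, k * k))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._shape)
        dx[:, :, : ho * k, : wo * k] = (
            dwin.reshape(b, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho * k, wo * k)
        )
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((out_features, in_features))
        self.params = {
            "W": w * np.sqrt(2.0 / in_features),
            "b": np.zeros(out_features),
        }
        self.grads = {}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """A plain layer stack with SGD and optional per-layer freezing."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x):
        return softmax(self.forward(x))

    def loss_and_grad(self, x, y_onehot):
        """Mean cross-entropy and backprop through all layers."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1))
        dlogits = (probs - y_onehot) / n
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def step(self, lr: float):
        for layer in self.layers:
            if layer.trainable and not layer.frozen:
                for name, p in layer.params.items():
                    p -= lr * layer.grads[name]

    def trainable_layers(self):
        return [l for l in self.layers if l.trainable]

    def parameter_vector(self) -> np.ndarray:
        """All parameters flattened (for checksums and equality tests)."""
        parts = [p.ravel() for l in self.trainable_layers()
                 for p in l.params.values()]
        return np.concatenate(parts) if parts else np.empty(0)

    def freeze_first(self, n_trainable: int):
        """Freeze the first ``n_trainable`` parameterized layers."""
        tl = self.trainable_layers()
        if n_trainable > len(tl):
            raise ValueError(
                f"cannot freeze {n_trainable} layers; network has {len(tl)} "
                "parameterized layers"
            )
        for l in tl[:n_trainable]:
            l.frozen = True
        for l in tl[n_trainable:]:
            l.frozen = False


def sgd_train(net: Network, x: np.ndarray, y: np.ndarray, *, lr: float,
              epochs: int, batch_size: int, rng: np.random.Generator):
    """Plain SGD with per-epoch shuffling; returns per-epoch mean losses.

    ``y`` holds class indices {0, 1, ...}; raises on non-finite loss.
    """
    n = x.shape[0]
    n_classes = int(y.max()) + 1
    onehot = np.eye(n_classes)[y]
    log = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = net.loss_and_grad(x[idx], onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            net.step(lr)
            total += loss * len(idx)
        log.append(total / n)
    return log
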