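"""Minimal feed-forward / convolutional network engine on numpy.

Implements exactly the layer vocabulary the image classifier needs —
2D convolution (valid padding, stride 1), ReLU, 2x2 max pooling,
inverted dropout, dense layers and a sigmoid/binary-cross-entropy head
with per-class weights — together with the Adam optimizer and
backpropagation through every layer down to the *input*, which is what
the attribution module differentiates.

Arrays are NHWC (samples, height, width, channels) for image layers and
(samples, features) for dense layers. All parameters are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2x2",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "sigmoid",
    "weighted_bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_with_logits(logits, y, w_pos=1.0, w_neg=1.0):
    """Class-weighted binary cross entropy and its gradient w.r.t. logits.

    Returns (mean loss, d loss / d logits). Numerically stable: works on
    logits, never on clipped probabilities.
    """
    logits = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    w = np.where(y == 1, w_pos, w_neg)
    # log(1 + exp(-|z|)) formulation
    zy = logits * (2.0 * y - 1.0)  # margin: positive when correct side
    loss_i = np.logaddexp(0.0, -zy)
    loss = float(np.mean(w * loss_i))
    p = sigmoid(logits)
    grad = w * (p - y) / y.size
    return loss, grad


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, valid padding.

    Computed as k*k shifted GEMMs (one per kernel tap) rather than a single
    im2col, which keeps memory traffic proportional to the activations
    instead of k*k times larger.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        k = kernel_size
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = k * k * in_ch
        self.W = _he_init(rng, (k, k, in_ch, out_ch), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        self._x = x if train else None
        self._x_shape = x.shape
        n, h, w, _ = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        out = np.empty((n * oh * ow, self.out_ch), dtype=np.float32)
        out[:] = self.b
        for di in range(k):
            for dj in range(k):
                patch = np.ascontiguousarray(x[:, di : di + oh, dj : dj + ow, :]).reshape(
                    -1, self.in_ch
                )
                out += patch @ self.W[di, dj]
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, dout):
        n, oh, ow, _ = dout.shape
        k = self.k
        dflat = np.ascontiguousarray(dout, dtype=np.float32).reshape(-1, self.out_ch)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                if self._x is not None:
                    patch = np.ascontiguousarray(
                        self._x[:, di : di + oh, dj : dj + ow, :]
                    ).reshape(-1, self.in_ch)
                    self.grads[0][di, dj] = patch.T @ dflat
                dx[:, di : di + oh, dj : dj + ow, :] += (dflat @ self.W[di, dj].T).reshape(
                    n, oh, ow, self.in_ch
                )
        if self._x is not None:
            self.grads[1][...] = dflat.sum(axis=0)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped.

    The gradient is routed to exactly one element per window, with ties
    broken deterministically in scan order (top-left first).
    """

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def _quadrants(self, x):
        return [x[:, di::2, dj::2, :] for di, dj in self._OFFSETS]

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        quads = [q[:, :oh, :ow, :] for q in self._quadrants(x)]
        m = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        taken = np.zeros(m.shape, dtype=bool)
        self._masks = []
        for q in quads:
            mask = (q == m) & ~taken
            taken |= mask
            self._masks.append(mask)
        return m

    def backward(self, dout):
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for (di, dj), mask in zip(self._OFFSETS, self._masks):
            dx[:, di : di + 2 * oh : 2, dj : dj + 2 * ow : 2, :] = np.where(mask, dout, 0.0)
        return dx


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = _he_init(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dout):
        dout = dout.astype(np.float32)
        if self._x is not None:
            self.grads[0][...] = self._x.T @ dout
            self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class Network:
    """Sequence of layers ending in a single logit; sigmoid applied on demand."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward_logits(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return np.asarray(x).reshape(x.shape[0], -1)[:, 0]

    def backward(self, dlogits):
        d = np.asarray(dlogits, dtype=np.float32).reshape(-1, 1)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = np.empty(x.shape[0], dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = sigmoid(self.forward_logits(x[i : i + batch_size]))
        return out

    def input_gradient(self, x, batch_size: int = 256) -> np.ndarray:
        """d sigmoid(logit) / d input, evaluated sample-wise (inference mode)."""
        x = np.asarray(x, dtype=np.float32)
        out = np.empty_like(x)
        for i in range(0, x.shape[0], batch_size):
            xb = x[i : i + batch_size]
            z = self.forward_logits(xb, train=False)
            p = sigmoid(z)
            out[i : i + batch_size] = self.backward(p * (1.0 - p))
        return out

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w
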