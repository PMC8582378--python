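"""A small, deterministic neural-network engine in numpy.

Implements exactly the pieces the two spectrum classifiers need: dense layers,
1-D convolutions (im2col + BLAS matmul, "same" padding, no biases), batch
normalization over channels, ReLU, global average pooling, and plain SGD with
momentum and optional per-layer L2 weight decay, trained with a weighted
binary cross-entropy on a sigmoid output. Everything is float32 and driven by
a caller-supplied :class:`numpy.random.Generator`, so runs are reproducible
bit-for-bit on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_F = np.float32


@dataclass
class Param:
    value: np.ndarray
    decay: bool = False                       # participates in weight decay
    grad: np.ndarray = field(init=False)
    velocity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer with bias: (N, d_in) -> (N, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "he"):
        scale = np.sqrt(2.0 / d_in) if init == "he" else np.sqrt(1.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)).astype(_F))
        self.b = Param(np.zeros(d_out, dtype=_F))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad[...] = self._x.T @ g
        self.b.grad[...] = g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class AddChannel(Layer):
    """(N, L) -> (N, 1, L) so conv stacks accept flat feature rows."""

    def forward(self, x, training):
        return x[:, None, :]

    def backward(self, g):
        return g[:, 0, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, C, L) activations.

    Trainable scale and shift (2 parameters per channel); running mean and
    variance are tracked with exponential smoothing for inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, smoothing: float = 0.1):
        self.gamma = Param(np.ones(channels, dtype=_F))
        self.beta = Param(np.zeros(channels, dtype=_F))
        self.eps = eps
        self.smoothing = smoothing
        self.running_mean = np.zeros(channels, dtype=_F)
        self.running_var = np.ones(channels, dtype=_F)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.smoothing * (mu - self.running_mean)
            self.running_var += self.smoothing * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(_F)
        self._xhat = (x - mu[None, :, None]) / self._std[None, :, None]
        return self.gamma.value[None, :, None] * self._xhat + self.beta.value[None, :, None]

    def backward(self, g):
        xhat = self._xhat
        self.gamma.grad[...] = (g * xhat).sum(axis=(0, 2))
        self.beta.grad[...] = g.sum(axis=(0, 2))
        m = g.shape[0] * g.shape[2]
        gmean = g.mean(axis=(0, 2))
        gxmean = (g * xhat).mean(axis=(0, 2))
        coef = (self.gamma.value / self._std)[None, :, None]
        return coef * (g - gmean[None, :, None] - xhat * gxmean[None, :, None])


class Conv1d(Layer):
    """1-D convolution without bias, "same" padding: output length ceil(L/stride)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Param(
            rng.normal(0.0, scale, size=(c_in * kernel, c_out)).astype(_F),
            decay=True,
        )
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride

    def params(self) -> list[Param]:
        return [self.W]

    def _pad(self, length: int) -> tuple[int, int, int]:
        l_out = -(-length // self.stride)
        total = max((l_out - 1) * self.stride + self.kernel - length, 0)
        return l_out, total // 2, total - total // 2

    def forward(self, x, training):
        n, c, length = x.shape
        l_out, pl, pr = self._pad(length)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]            # (N, C, L_out, K)
        cols = win.transpose(0, 2, 1, 3).reshape(n * l_out, c * self.kernel)
        self._cols = np.ascontiguousarray(cols)
        self._shape = (n, c, length, l_out, pl, pr)
        out = self._cols @ self.W.value
        return out.reshape(n, l_out, self.c_out).transpose(0, 2, 1)

    def backward(self, g):
        n, c, length, l_out, pl, pr = self._shape
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1).reshape(n * l_out, self.c_out))
        self.W.grad[...] = self._cols.T @ g2
        gcols = (g2 @ self.W.value.T).reshape(n, l_out, c, self.kernel)
        gcols = gcols.transpose(0, 2, 1, 3)           # (N, C, L_out, K)
        gxp = np.zeros((n, c, length + pl + pr), dtype=_F)
        for j in range(self.kernel):
            stop = j + self.stride * (l_out - 1) + 1
            gxp[:, :, j:stop:self.stride] += gcols[:, :, :, j]
        return gxp[:, :, pl:pl + length]


class GlobalAvgPool1d(Layer):
    """(N, C, L) -> (N, C), averaging over the length axis."""

    def forward(self, x, training):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._length, axis=2) / self._length


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Network:
    """A feed-forward stack ending in a single logit per sample."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x.reshape(len(x))                      # (N,) logits

    def backward(self, g: np.ndarray) -> None:
        g = g.reshape(-1, 1)                          # final layers emit (N, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        X = np.asarray(X, dtype=_F)
        out = np.empty(len(X), dtype=np.float64)
        for lo in range(0, len(X), batch_size):
            out[lo:lo + batch_size] = sigmoid(
                self.forward(X[lo:lo + batch_size], training=False)
            )
        return out


def train_sgd(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    *,
    schedule: tuple[tuple[int, float], ...],
    batch_size: int,
    momentum: float,
    rng: np.random.Generator,
    pos_class_weight: float = 1.0,
    weight_decay: float = 0.0,
) -> None:
    """Train in place with SGD + momentum on weighted binary cross-entropy.

    ``schedule`` is a sequence of (epochs, learning rate) stages run back to
    back; weight decay applies only to parameters flagged for it (conv
    weights). The positive-class weight multiplies the loss gradient of
    positive samples.
    """
    X = np.asarray(X, dtype=_F)
    y = np.asarray(y, dtype=_F)
    n = len(X)
    sample_w = np.where(y > 0.5, _F(pos_class_weight), _F(1.0))
    params = net.params()
    for epochs, lr in schedule:
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                xb, yb, wb = X[idx], y[idx], sample_w[idx]
                logits = net.forward(xb, training=True)
                p = sigmoid(logits)
                # d(weighted BCE)/d logit, averaged over the batch
                g = (wb * (p - yb) / len(idx)).astype(_F)
                net.backward(g)
                for prm in params:
                    grad = prm.grad
                    if weight_decay and prm.decay:
                        grad = grad + weight_decay * prm.value
                    prm.velocity[...] = momentum * prm.velocity - lr * grad
                    prm.value += prm.velocity
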