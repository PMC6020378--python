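"""Minimal deterministic neural-network core on NumPy.

Implements exactly the pieces the guide-design models need: 1-D convolution
(im2col), batch normalization, dense layers, ReLU, pooling/upsampling,
softmax cross-entropy and MSE losses, and an Adam optimizer with per-layer
learning-rate scaling (used to fine-tune a pretrained encoder at a lower
rate than a freshly initialized head). All layers implement full backprop
including the gradient with respect to the *input*, which the
interpretation module uses for activation maximization.

Array convention: a batch is ``(N, L, C)`` — N samples, L positions,
C channels. Everything runs in float64; given a seed, training is
bit-reproducible on a single device.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "Dense",
    "Flatten",
    "GlobalAvgPool",
    "Upsample",
    "Crop",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
    "softmax_probs",
    "mse_loss",
]


class Param:
    """A trainable tensor with its gradient and a learning-rate multiplier."""

    __slots__ = ("value", "grad", "lr_scale")

    def __init__(self, value: np.ndarray, lr_scale: float = 1.0):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.lr_scale = float(lr_scale)


class Layer:
    train_mode_sensitive = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_lr_scale(self, scale: float) -> None:
        for p in self.params():
            p.lr_scale = scale

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv1D(Layer):
    """Same-padded 1-D convolution ``(N, L, C_in) -> (N, L_out, C_out)``.

    ``L_out = floor((L + 2*(k//2) - k) / stride) + 1``. He-normal init.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_len(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x, train):
        N, L, C = x.shape
        Lout = self.out_len(L)
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = np.empty((N, Lout, self.kernel, C))
        for j in range(self.kernel):
            cols[:, :, j, :] = xp[:, j: j + self.stride * Lout: self.stride, :]
        y = np.einsum("nlkc,kco->nlo", cols, self.W.value, optimize=True) + self.b.value
        self._cache = (cols, x.shape, xp.shape)
        return y

    def backward(self, dy):
        cols, x_shape, xp_shape = self._cache
        N, L, C = x_shape
        Lout = dy.shape[1]
        self.W.grad += np.einsum("nlkc,nlo->kco", cols, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = np.einsum("nlo,kco->nlkc", dy, self.W.value, optimize=True)
        dxp = np.zeros(xp_shape)
        for j in range(self.kernel):
            dxp[:, j: j + self.stride * Lout: self.stride, :] += dcols[:, :, j, :]
        if self.pad:
            return dxp[:, self.pad:-self.pad, :]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over the (N, L) axes."""

    train_mode_sensitive = True

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, shape, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat * inv
        m = shape[0] * shape[1]
        return (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1)))


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    train_mode_sensitive = True

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dy):
        N, L, C = self._shape
        return np.repeat(dy[:, None, :], L, axis=1) / L


class Upsample(Layer):
    """Nearest-neighbour upsampling along the position axis."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, train):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy):
        N, L, C = dy.shape
        return dy.reshape(N, L // self.factor, self.factor, C).sum(axis=2)


class Crop(Layer):
    """Crop the position axis down to a target length (from the end)."""

    def __init__(self, length: int):
        self.length = length

    def forward(self, x, train):
        self._orig = x.shape[1]
        return x[:, : self.length, :]

    def backward(self, dy):
        extra = self._orig - dy.shape[1]
        if extra:
            return np.pad(dy, ((0, 0), (0, extra), (0, 0)))
        return dy


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    # -- serialization -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        it = iter(arrays[len(ps):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.lr_scale == 0.0:
                continue
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            step = self.lr * p.lr_scale
            if self.weight_decay and p.value.ndim > 1:  # decay weights, not biases/BN
                p.value -= step * self.weight_decay * p.value
            p.value -= step * mhat / (np.sqrt(vhat) + self.eps)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          label_smoothing: float = 0.0):
    """Return (mean loss, probabilities, gradient wrt logits)."""
    n, k = logits.shape
    probs = softmax_probs(logits)
    target = np.full((n, k), label_smoothing / k)
    target[np.arange(n), labels] += 1.0 - label_smoothing
    loss = float(-np.mean((target * np.log(probs + 1e-12)).sum(axis=1)))
    return loss, probs, (probs - target) / n


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Return (mean squared error, gradient wrt pred)."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
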