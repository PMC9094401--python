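"""A compact numpy engine for small 1D convolutional networks.

Implements exactly the layer set the per-band decoder needs — Conv1D (same
padding), BatchNorm, LeakyReLU, MaxPool, Flatten, Dense, Dropout — with a
sigmoid/binary-cross-entropy head, L1 weight penalties, and an Adam
optimizer.  Everything is dense numpy in float32 (convolutions are cast to
BLAS matrix products over im2col windows) and seeded: given the same
weights, data order and dropout stream, training is reproducible on one CPU.

Conventions follow the common deep-learning-framework defaults the decoder's
reference configuration names: he_uniform initialization for conv kernels,
LeCun-normal for dense kernels, zero biases, batch-norm eps 1e-3 with
momentum 0.99 running statistics, Adam eps 1e-7.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "LeakyReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "binary_cross_entropy",
]

DTYPE = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params/grads in lists."""

    trainable_params: list
    grads: list
    l1_weight: float = 0.0

    def __init__(self):
        self.trainable_params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l1_loss(self) -> float:
        return 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.trainable_params))


class Conv1D(Layer):
    """1D convolution, stride 1, 'same' zero padding.

    Weight shape (C_in, kernel, C_out); he_uniform init: U(-lim, lim) with
    lim = sqrt(6 / fan_in), fan_in = kernel * C_in.  Bias initialized to zero.
    Forward/backward run as matrix products over im2col windows.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, l1_weight: float,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("same padding requires an odd kernel size")
        self.kernel_size = kernel_size
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel_size * c_in
        lim = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-lim, lim, size=(c_in, kernel_size, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.l1_weight = l1_weight
        self.trainable_params = [self.w, self.b]

    def forward(self, x, training):
        # x: (N, L, C_in) -> (N, L, C_out)
        n, length, _ = x.shape
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        win = sliding_window_view(xp, self.kernel_size, axis=1)  # (N,L,Cin,k)
        self._cols = win.reshape(n * length, self.c_in * self.kernel_size)
        self._n, self._length = n, length
        out = self._cols @ self.w.reshape(-1, self.c_out)
        return out.reshape(n, length, self.c_out) + self.b

    def backward(self, grad_out):
        n, length, k = self._n, self._length, self.kernel_size
        g2 = grad_out.reshape(n * length, self.c_out)
        gw = (self._cols.T @ g2).reshape(self.w.shape)
        if self.l1_weight:
            gw += self.l1_weight * np.sign(self.w)
        self.grads = [gw, g2.sum(axis=0)]
        # input grad: correlate grad_out with the flipped kernel
        pad = k // 2
        gp = np.pad(grad_out, ((0, 0), (pad, pad), (0, 0)))
        gwin = sliding_window_view(gp, k, axis=1)  # (N,L,Cout,k)
        wflip = self.w[:, ::-1, :].transpose(2, 1, 0).reshape(self.c_out * k, self.c_in)
        gx = gwin.reshape(n * length, self.c_out * k) @ wflip
        return gx.reshape(n, length, self.c_in)

    def l1_loss(self):
        return float(self.l1_weight * np.abs(self.w).sum())


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = DTYPE(eps)
        self.momentum = DTYPE(momentum)
        self.trainable_params = [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1]
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad_out):
        g_gamma = (grad_out * self._xhat).sum(axis=(0, 1))
        g_beta = grad_out.sum(axis=(0, 1))
        self.grads = [g_gamma, g_beta]
        gxhat = grad_out * self.gamma
        if not self._training:
            return gxhat / self._std
        m = self._m
        return (
            gxhat - gxhat.mean(axis=(0, 1)) - self._xhat * (gxhat * self._xhat).sum(axis=(0, 1)) / m
        ) / self._std


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        super().__init__()
        self.alpha = DTYPE(alpha)

    def forward(self, x, training):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, self.alpha * grad_out)


class MaxPool1D(Layer):
    """Max pooling with stride == pool size; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool = pool_size

    def forward(self, x, training):
        n, length, c = x.shape
        l_out = length // self.pool
        if l_out < 1:
            raise ValueError(f"input length {length} too short for pool size {self.pool}")
        self._in_shape = x.shape
        xt = x[:, : l_out * self.pool].reshape(n, l_out, self.pool, c)
        self._argmax = xt.argmax(axis=2)
        return xt.max(axis=2)

    def backward(self, grad_out):
        n, l_out, c = grad_out.shape
        gx = np.zeros(self._in_shape, dtype=grad_out.dtype)
        gt = gx[:, : l_out * self.pool].reshape(n, l_out, self.pool, c)
        ni, li, ci = np.ogrid[:n, :l_out, :c]
        gt[ni, li, self._argmax, ci] = grad_out
        return gx


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer, LeCun-normal kernel init: N(0, 1/fan_in)."""

    def __init__(self, n_in: int, n_out: int, l1_weight: float, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.l1_weight = l1_weight
        self.trainable_params = [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad_out):
        gw = self._x.T @ grad_out
        if self.l1_weight:
            gw += self.l1_weight * np.sign(self.w)
        self.grads = [gw, grad_out.sum(axis=0)]
        return grad_out @ self.w.T

    def l1_loss(self):
        return float(self.l1_weight * np.abs(self.w).sum())


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time.  Needs the model's rng."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Sequential:
    """A feed-forward stack with a sigmoid binary-classification head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h[:, 0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward_logits(x, training=False))

    def l1_loss(self) -> float:
        """Current L1 penalty term (reporting only; gradients always include it)."""
        return sum(layer.l1_loss() for layer in self.layers)

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: "Adam") -> float:
        """One forward/backward/update pass; returns the batch BCE loss.

        The returned loss excludes the L1 penalty (whose gradient is applied
        regardless); call :meth:`l1_loss` to report the penalty term.
        """
        y = np.asarray(y, dtype=DTYPE)
        logits = self.forward_logits(x, training=True)
        p = _sigmoid(logits)
        loss = binary_cross_entropy(p, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        # d(BCE)/d(logit) for the mean loss
        grad = ((p - y) / DTYPE(y.size))[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        params, grads = [], []
        for layer in self.layers:
            params.extend(layer.trainable_params)
            grads.extend(layer.grads)
        optimizer.update(params, grads)
        return float(loss)


class Adam:
    """Adam with bias correction (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, learning_rate: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = DTYPE(beta1), DTYPE(beta2), DTYPE(eps)
        self.t = 0
        self._m: list = []
        self._v: list = []

    def update(self, params: list, grads: list) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        step = DTYPE(self.lr / (1 - float(b1) ** self.t))
        b2t = DTYPE(1 - float(b2) ** self.t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            g = g.astype(DTYPE, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= step * m / (np.sqrt(v / b2t) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
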