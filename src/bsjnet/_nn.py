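"""Minimal numpy neural-network layers with hand-derived gradients.

Everything here operates on float64 arrays and is fully deterministic given
the rng used for initialization, which makes bit-identical CPU re-runs
possible.  Sequence tensors have shape (batch, positions, channels); the
convolution slides along the position axis with symmetric ("same") padding
so the position count is preserved through the conv and attention stages.

Parameter initialization is a seeded uniform fan-in scheme:
U(-1/sqrt(fan_in), 1/sqrt(fan_in)).
"""

from __future__ import annotations

import numpy as np

LOG_EPS = 1e-12  # clamp for log() inside the cross-entropy


def stable_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax with max-subtraction for numerical stability."""
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, shape)


class Layer:
    """Base class: forward caches what backward needs; params/grads by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1dSame(Layer):
    """1-D convolution along positions, stride 1, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for symmetric same-padding")
        self.k = kernel_size
        self.in_channels = in_channels
        fan_in = in_channels * kernel_size
        self.params["W"] = _fan_in_uniform(rng, (kernel_size * in_channels, out_channels), fan_in)
        self.params["b"] = _fan_in_uniform(rng, (out_channels,), fan_in)

    def _im2col(self, xp: np.ndarray, L: int) -> np.ndarray:
        N, _, C = xp.shape
        cols = np.empty((N, L, self.k, C))
        for j in range(self.k):
            cols[:, :, j, :] = xp[:, j : j + L, :]
        return cols.reshape(N, L, self.k * C)

    def forward(self, x, train=True):
        N, L, C = x.shape
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = self._im2col(xp, L)
        self._cache = (cols, x.shape)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        cols, (N, L, C) = self._cache
        self.grads["W"] = cols.reshape(-1, self.k * C).T @ dout.reshape(-1, dout.shape[-1])
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = (dout @ self.params["W"].T).reshape(N, L, self.k, C)
        p = (self.k - 1) // 2
        dxp = np.zeros((N, L + 2 * p, C))
        for j in range(self.k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        return dxp[:, p : p + L, :]


class BatchNorm1d(Layer):
    """Normalization over the batch and position axes, per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        xf = x.reshape(-1, x.shape[-1])
        if train:
            mu = xf.mean(axis=0)
            var = xf.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mu) * inv_std
        self._cache = (xhat, inv_std, x.shape, train)
        return (self.params["gamma"] * xhat + self.params["beta"]).reshape(x.shape)

    def backward(self, dout):
        xhat, inv_std, shape, train = self._cache
        dy = dout.reshape(-1, dout.shape[-1])
        self.grads["gamma"] = (dy * xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not train:
            return (dxhat * inv_std).reshape(shape)
        m = dy.shape[0]
        dx = (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx.reshape(shape)


class LayerNorm(Layer):
    """Per-position normalization over the channel axis."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)

    def forward(self, x, train=True):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv_std = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
        self.grads["beta"] = dout.sum(axis=tuple(range(dout.ndim - 1)))
        dxhat = dout * self.params["gamma"]
        d = dout.shape[-1]
        return (inv_std / d) * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Dropout(Layer):
    def __init__(self, p: float, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention over positions.

    Q = X W_Q, K = X W_K, V = X W_V; per head,
    attention = softmax(Q K^T / sqrt(D_k)) and the output is attention @ V,
    with the head outputs concatenated.  D_k is the per-head key width.
    (Row-wise softmax over keys is the only normalization that makes the
    weight matrix row-stochastic, so Q K^T rather than K^T Q is used.)
    """

    def __init__(self, width: int, heads: int, rng):
        super().__init__()
        if width % heads != 0:
            raise ValueError(f"attention heads ({heads}) must divide the width ({width})")
        self.heads = heads
        self.width = width
        self.d_k = width // heads
        for name in ("W_Q", "W_K", "W_V"):
            self.params[name] = _fan_in_uniform(rng, (width, width), width)

    def _split(self, x: np.ndarray) -> np.ndarray:
        N, L, F = x.shape
        return x.reshape(N, L, self.heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        N, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(N, L, H * dh)

    def forward(self, x, train=True):
        Q = x @ self.params["W_Q"]
        K = x @ self.params["W_K"]
        V = x @ self.params["W_V"]
        Qh, Kh, Vh = self._split(Q), self._split(K), self._split(V)
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        A = stable_softmax(scores, axis=-1)
        out = self._merge(A @ Vh)
        self._cache = (x, Qh, Kh, Vh, A)
        self.last_attention = A  # (N, heads, L, L), row-stochastic
        return out

    def backward(self, dout):
        x, Qh, Kh, Vh, A = self._cache
        dOh = self._split(dout)
        dV = self._merge(A.transpose(0, 1, 3, 2) @ dOh)
        dA = dOh @ Vh.transpose(0, 1, 3, 2)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = self._merge(dS @ Kh / np.sqrt(self.d_k))
        dK = self._merge(dS.transpose(0, 1, 3, 2) @ Qh / np.sqrt(self.d_k))
        x2 = x.reshape(-1, self.width)
        self.grads["W_Q"] = x2.T @ dQ.reshape(-1, self.width)
        self.grads["W_K"] = x2.T @ dK.reshape(-1, self.width)
        self.grads["W_V"] = x2.T @ dV.reshape(-1, self.width)
        return (
            dQ @ self.params["W_Q"].T
            + dK @ self.params["W_K"].T
            + dV @ self.params["W_V"].T
        )


class AdaptiveMaxPool(Layer):
    """Global max over the position axis (adaptive output size 1)."""

    def forward(self, x, train=True):
        if x.shape[1] == 0:
            raise ValueError("cannot max-pool an empty position axis")
        self._argmax = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout):
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._argmax[:, None, :], dout[:, None, :], axis=1)
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        super().__init__()
        self.params["W"] = _fan_in_uniform(rng, (in_features, out_features), in_features)
        self.params["b"] = _fan_in_uniform(rng, (out_features,), in_features)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self):
        for i, layer in enumerate(self.layers):
            sub = layer.named_params() if isinstance(layer, Sequential) else (
                (name, layer) for name in layer.params
            )
            for name, owner in sub:
                yield f"{i}.{name}", owner


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient wrt the logits.

    ``y`` holds integer class indices; the one-hot form of the loss
    -sum_i y_i log(p_i) reduces to -log p_true per example.
    """
    probs = stable_softmax(logits, axis=-1)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], LOG_EPS, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class SGD:
    def __init__(self, named_params, lr: float):
        self.slots = list(named_params)
        self.lr = lr

    def step(self):
        for name, owner in self.slots:
            key = name.rsplit(".", 1)[-1]
            owner.params[key] -= self.lr * owner.grads[key]


class Adam:
    def __init__(self, named_params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.slots = list(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(owner.params[name.rsplit(".", 1)[-1]])
                  for name, owner in self.slots}
        self.v = {name: np.zeros_like(owner.params[name.rsplit(".", 1)[-1]])
                  for name, owner in self.slots}

    def step(self):
        self.t += 1
        for name, owner in self.slots:
            key = name.rsplit(".", 1)[-1]
            g = owner.grads[key]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            owner.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
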