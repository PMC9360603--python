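"""NumPy building blocks for the compact SSVEP classifiers.

Each layer owns its parameters and gradients and implements a
``forward(x, training)`` / ``backward(grad)`` pair. Convolutions use an
im2col + matmul realization, which is efficient here because every
kernel in the architecture family is a narrow 1-D strip ((k,1) across
channels or (1,k) along the spectrum). All tensors are float32 and all
randomness flows through explicitly passed generators, so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameterless identity."""

    #: spec-level layer index this runtime op belongs to (set by the builder)
    spec_index: int = -1
    frozen: bool = False

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable tensors (e.g. batch-norm running stats)."""
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad_same(kernel: int) -> tuple[int, int]:
    """Zero-padding (before, after) that preserves length under a valid conv.

    For even kernels the extra cell goes after, matching the common
    deep-learning "same" convention.
    """
    total = kernel - 1
    before = total // 2
    return before, total - before


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with 'preserve' or 'valid' padding."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int],
        padding: str = "valid",
        rng: np.random.Generator | None = None,
    ) -> None:
        if padding not in ("preserve", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.padding = padding
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        rng = rng or np.random.default_rng()
        # He initialization, appropriate for the ReLU that follows each conv
        self.W = (rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        if self.padding == "preserve":
            return h, w
        oh, ow = h - kh + 1, w - kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"kernel {self.kernel} does not fit input ({h}, {w}) without padding"
            )
        return oh, ow

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        kh, kw = self.kernel
        ph, pw = _pad_same(kh), _pad_same(kw)
        return np.pad(x, ((0, 0), (0, 0), ph, pw))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        xp = self._pad(x.astype(DTYPE, copy=False))
        kh, kw = self.kernel
        oh, ow = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        sn, sc, sh, sw = xp.strides
        patches = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, oh, ow, c, kh, kw),
            strides=(sn, sh, sw, sc, sh, sw),
            writeable=False,
        )
        cols = np.ascontiguousarray(patches).reshape(n * oh * ow, c * kh * kw)
        out = cols @ self.W + self.b
        out = out.reshape(n, oh, ow, self.filters).transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, xp.shape, (n, oh, ow))
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, padded_shape, (n, oh, ow) = self._cache
        kh, kw = self.kernel
        g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.filters)
        self.dW = (cols.T @ g).astype(DTYPE)
        self.db = g.sum(axis=0).astype(DTYPE)
        dcols = (g @ self.W.T).reshape(n, oh, ow, self.in_channels, kh, kw)
        dxp = np.zeros(padded_shape, dtype=DTYPE)
        # scatter-add per kernel offset; kernels are tiny so the loop is cheap
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if self.padding == "valid":
            return dxp
        ph, pw = _pad_same(kh), _pad_same(kw)
        h = padded_shape[2] - ph[0] - ph[1]
        w = padded_shape[3] - pw[0] - pw[1]
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class BatchNorm2D(Layer):
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # a frozen layer behaves as a fixed feature extractor: inference
        # statistics, no running-stat updates
        if training and not self.frozen:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std, x.shape)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(
            DTYPE
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma = (grad * xhat).sum(axis=(0, 2, 3)).astype(DTYPE)
        self.dbeta = grad.sum(axis=(0, 2, 3)).astype(DTYPE)
        if self.frozen:
            return (grad * (self.gamma * inv_std)[None, :, None, None]).astype(DTYPE)
        gxhat = grad * self.gamma[None, :, None, None]
        dx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_features + units))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(in_features, units)).astype(DTYPE)
        self.b = np.zeros(units, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = (self._x.T @ grad).astype(DTYPE)
        self.db = grad.sum(axis=0).astype(DTYPE)
        return (grad @ self.W.T).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None  # installed by the network

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without a generator")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (grad * self._mask).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
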