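"""Minimal CNN building blocks in numpy.

Implements exactly the layers the two-stream fracture classifier needs —
same-padded 3x3 convolution, ReLU, batch normalization, cross-channel local
response normalization (LRN), 2x2 average pooling, global average pooling,
dense layers and inverted dropout — each with an analytic backward pass, plus
Adam and RMSprop. Convolutions use an im2col formulation
(``sliding_window_view`` + ``tensordot``) so everything runs through BLAS.

All computation is float32; determinism comes from a single
``numpy.random.Generator`` threaded through initialization and dropout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded stride-1 convolution with odd square kernels.

    He-normal weight init. Input/output layout is (B, C, H, W).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel side must be odd")
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k
        self._win = win if train else None
        out = np.tensordot(win, self.w.value, axes=([1, 4, 5], [1, 2, 3]))  # B,H,W,F
        out += self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        self.b.grad += dout.sum(axis=(0, 2, 3))
        # dW[f,c,i,j] = sum_{b,h,w} dout[b,f,h,w] * x_pad[b,c,h+i,w+j]
        self.w.grad += np.tensordot(dout, self._win, axes=([0, 2, 3], [0, 2, 3]))
        self._win = None
        # dx = full correlation of dout with spatially flipped kernels
        dpad = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        dwin = sliding_window_view(dpad, (k, k), axis=(2, 3))  # B,F,H,W,k,k
        wflip = self.w.value[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, wflip, axes=([1, 4, 5], [0, 2, 3]))  # B,H,W,C
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (B, H, W) with affine terms."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if train:
            self._xhat, self._inv_std = xhat, inv_std
        out = self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self._xhat = None
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        dxhat = dout * g
        # standard batch-norm backward, vectorized per channel
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        ) * inv_std[:, None, None]
        return dx.astype(np.float32)


def lrn_response(
    a: np.ndarray,
    t: float = 2.0,
    alpha: float = 1e-4,
    beta: float = 0.75,
    n: int = 5,
    channel_axis: int = 0,
) -> np.ndarray:
    """Cross-channel local response normalization (closed form).

    ``b_j = a_j / (t + alpha * sum_{i in window(j)} a_i**2) ** beta`` where the
    window spans channels j - n//2 .. j + n//2 clipped to [0, N).
    """
    if n < 1:
        raise ValueError(f"LRN window n must be >= 1, got {n}")
    a = np.asarray(a, dtype=np.float64)
    x = np.moveaxis(a, channel_axis, -1)
    half = n // 2
    nch = x.shape[-1]
    c = np.cumsum(x**2, axis=-1)
    c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
    hi = np.minimum(np.arange(nch) + half + 1, nch)
    lo = np.maximum(np.arange(nch) - half, 0)
    s = c[..., hi] - c[..., lo]
    out = x / (t + alpha * s) ** beta
    return np.moveaxis(out, -1, channel_axis)


class LRN(Layer):
    """Local response normalization across channels (axis 1)."""

    def __init__(self, t: float = 2.0, alpha: float = 1e-4, beta: float = 0.75, n: int = 5):
        if n < 1:
            raise ValueError(f"LRN window n must be >= 1, got {n}")
        self.t, self.alpha, self.beta, self.n = t, alpha, beta, n

    def _window_sum(self, x: np.ndarray) -> np.ndarray:
        half = self.n // 2
        c = np.cumsum(x, axis=1)
        c = np.concatenate([np.zeros_like(c[:, :1]), c], axis=1)
        nch = x.shape[1]
        hi = np.minimum(np.arange(nch) + half + 1, nch)
        lo = np.maximum(np.arange(nch) - half, 0)
        return c[:, hi] - c[:, lo]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.t + self.alpha * self._window_sum(x.astype(np.float64) ** 2)
        self._x, self._s = (x, s) if train else (None, None)
        return (x / s**self.beta).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        self._x = self._s = None
        # da_i = dout_i * s_i^-beta - 2*alpha*beta * a_i * window_sum(dout_j a_j s_j^(-beta-1))
        core = dout * x * s ** (-self.beta - 1)
        dx = dout * s ** (-self.beta) - 2 * self.alpha * self.beta * x * self._window_sum(core)
        return dx.astype(np.float32)


class AvgPool2(Layer):
    """2x2 average pooling with stride 2 (even spatial dims required)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2 needs even spatial dims, got {(h, w)}")
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * np.float32(0.25)


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) by spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def parameters(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        self._x = None
        return dout @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction stabilization."""
    z = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def binary_pair_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Two-class cross-entropy averaged over both class slots.

    ``loss = (1/N) * sum_j -(y_j log P_j + (1 - y_j) log(1 - P_j))`` with
    N = 2 classes; the batch loss is the mean over rows. With a softmax output
    (rows of ``p`` summing to 1) this equals the usual ``-log P_true``.
    Targets must be one-hot rows.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if p.shape != y.shape or p.shape[1] != 2:
        raise ValueError(f"need matching (n, 2) shapes, got {p.shape} vs {y.shape}")
    if not np.all((y == 0) | (y == 1)) or not np.all(y.sum(axis=1) == 1):
        raise ValueError("targets must be one-hot over 2 classes")
    pc = np.clip(p, eps, 1 - eps)
    per_class = -(y * np.log(pc) + (1 - y) * np.log(1 - pc))
    return float(per_class.mean(axis=1).mean())


class Adam:
    def __init__(self, params: list[Param], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


class RMSprop:
    def __init__(self, params: list[Param], lr: float = 1e-5,
                 rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad * p.grad
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
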