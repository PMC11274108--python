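"""Layer implementations with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
releases it on the next call; layers are therefore stateful and must be
driven forward-then-backward in matching order, which the network classes
guarantee. Parameters are ``Param`` objects holding the value, an
accumulated gradient and a ``frozen`` flag that the optimizer respects.
"""

from __future__ import annotations

import numpy as np

#: computation dtype of the engine; single precision is standard deep-learning
#: practice and halves the memory traffic that dominates CPU convolutions
DTYPE = np.float32

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv1D",
    "Conv2D",
    "MaxPool1D",
    "MaxPool2D",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "LSTM",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    """A trainable tensor: value, gradient accumulator and freeze flag."""

    __slots__ = ("name", "value", "grad", "frozen")

    def __init__(self, value: np.ndarray, name: str):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.frozen = False

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape}, frozen={self.frozen})"


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base class; subclasses define forward/backward and list their params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, name: str, rng: np.random.Generator):
        self.W = Param(glorot(rng, in_dim, out_dim, (in_dim, out_dim)), f"{name}/W")
        self.b = Param(np.zeros(out_dim), f"{name}/b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=DTYPE)
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    def seed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Conv1D(Layer):
    """1D convolution over (batch, time, channels) with 'same' padding.

    Computed as a sum of tap-shifted matmuls (never materializing an im2col
    buffer); the weight tensor is stored flat as (kernel*in_ch, out_ch).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, name: str,
                 rng: np.random.Generator):
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = kernel * in_ch
        self.W = Param(glorot(rng, fan_in, out_ch, (fan_in, out_ch)), f"{name}/W")
        self.b = Param(np.zeros(out_ch), f"{name}/b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        B, L, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        k = self.k
        pl = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pl, k // 2), (0, 0)))
        Wk = self.W.value.reshape(k, C, self.out_ch)
        out = np.broadcast_to(self.b.value, (B, L, self.out_ch)).copy()
        for j in range(k):
            out += xp[:, j:j + L, :] @ Wk[j]
        self._cache = (xp, (B, L, C, pl))
        return out

    def backward(self, dout):
        xp, (B, L, C, pl) = self._cache
        k = self.k
        dout2 = dout.reshape(-1, self.out_ch)
        Wk = self.W.value.reshape(k, C, self.out_ch)
        dW = self.W.grad.reshape(k, C, self.out_ch)
        dxp = np.zeros_like(xp)
        for j in range(k):
            sl = xp[:, j:j + L, :].reshape(-1, C)
            dW[j] += sl.T @ dout2
            dxp[:, j:j + L, :] += dout @ Wk[j].T
        self.b.grad += dout2.sum(axis=0)
        return dxp[:, pl:pl + L, :]


class Conv2D(Layer):
    """2D convolution over (batch, H, W, channels) with 'same' padding.

    Same shift-accumulation strategy as ``Conv1D``; weights stored flat as
    (kh*kw*in_ch, out_ch).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], name: str,
                 rng: np.random.Generator):
        self.kh, self.kw = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = self.kh * self.kw * in_ch
        self.W = Param(glorot(rng, fan_in, out_ch, (fan_in, out_ch)), f"{name}/W")
        self.b = Param(np.zeros(out_ch), f"{name}/b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        B, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        kh, kw = self.kh, self.kw
        pt, plft = (kh - 1) // 2, (kw - 1) // 2
        xp = np.pad(x, ((0, 0), (pt, kh // 2), (plft, kw // 2), (0, 0)))
        Wk = self.W.value.reshape(kh, kw, C, self.out_ch)
        out = np.broadcast_to(self.b.value, (B, H, W, self.out_ch)).copy()
        for i in range(kh):
            for j in range(kw):
                out += xp[:, i:i + H, j:j + W, :] @ Wk[i, j]
        self._cache = (xp, (B, H, W, C, pt, plft))
        return out

    def backward(self, dout):
        xp, (B, H, W, C, pt, plft) = self._cache
        kh, kw = self.kh, self.kw
        dout2 = dout.reshape(-1, self.out_ch)
        Wk = self.W.value.reshape(kh, kw, C, self.out_ch)
        dW = self.W.grad.reshape(kh, kw, C, self.out_ch)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = np.ascontiguousarray(xp[:, i:i + H, j:j + W, :]).reshape(-1, C)
                dW[i, j] += sl.T @ dout2
                dxp[:, i:i + H, j:j + W, :] += dout @ Wk[i, j].T
        self.b.grad += dout2.sum(axis=0)
        return dxp[:, pt:pt + H, plft:plft + W, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int, stride: int):
        self.pool = pool
        self.stride = stride

    def forward(self, x, train=False):
        B, L, C = x.shape
        if L < self.pool:
            raise ValueError(f"signal length {L} shorter than pool {self.pool}")
        Lo = (L - self.pool) // self.stride + 1
        idx = (np.arange(Lo) * self.stride)[:, None] + np.arange(self.pool)[None, :]
        win = x[:, idx, :]                       # (B, Lo, pool, C)
        am = win.argmax(axis=2)                  # (B, Lo, C)
        self._cache = (am, idx, x.shape)
        return np.take_along_axis(win, am[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        am, idx, shape = self._cache
        B, L, C = shape
        Lo = am.shape[1]
        dx = np.zeros(shape, dtype=DTYPE)
        bi, li, ci = np.indices(am.shape)
        pos = idx[li, am]                         # source time index of each max
        np.add.at(dx, (bi, pos, ci), dout)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2x2-style pooling with floor division of odd extents."""

    def __init__(self, pool: int, stride: int):
        if pool != stride:
            raise ValueError("only non-overlapping pooling supported")
        self.p = pool

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        p = self.p
        Ho, Wo = H // p, W // p
        xc = x[:, :Ho * p, :Wo * p, :]
        win = (xc.reshape(B, Ho, p, Wo, p, C)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(B, Ho, Wo, p * p, C))
        am = win.argmax(axis=3)
        self._cache = (am, x.shape)
        return np.take_along_axis(win, am[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        am, shape = self._cache
        B, H, W, C = shape
        p = self.p
        dx = np.zeros(shape, dtype=DTYPE)
        bi, hi, wi, ci = np.indices(am.shape)
        np.add.at(dx, (bi, hi * p + am // p, wi * p + am % p, ci), dout)
        return dx


class GlobalAvgPool(Layer):
    """Mean over all axes between batch and channels."""

    def forward(self, x, train=False):
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        return x.mean(axis=axes)

    def backward(self, dout):
        shape = self._shape
        n = int(np.prod(shape[1:-1]))
        expand = (shape[0],) + (1,) * (len(shape) - 2) + (shape[-1],)
        return np.broadcast_to(dout.reshape(expand), shape) / n


class GlobalMaxPool(Layer):
    def forward(self, x, train=False):
        B, C = x.shape[0], x.shape[-1]
        flat = x.reshape(B, -1, C)
        am = flat.argmax(axis=1)
        self._cache = (am, x.shape)
        return np.take_along_axis(flat, am[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout):
        am, shape = self._cache
        B, C = shape[0], shape[-1]
        dflat = np.zeros((B, int(np.prod(shape[1:-1])), C), dtype=DTYPE)
        bi, ci = np.indices(am.shape)
        dflat[bi, am, ci] = dout
        return dflat.reshape(shape)


class LSTM(Layer):
    """Single LSTM layer over (batch, T, D); returns the last hidden state.

    Gate order i, f, g, o; forget-gate bias initialized to 1 so early
    training does not wash out the cell state.
    """

    def __init__(self, in_dim: int, hidden: int, name: str, rng: np.random.Generator):
        self.H = hidden
        self.in_dim = in_dim
        self.W = Param(glorot(rng, in_dim, 4 * hidden, (in_dim, 4 * hidden)), f"{name}/W")
        self.U = Param(glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)), f"{name}/U")
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Param(b, f"{name}/b")

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=DTYPE)
        B, T, D = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        cache = []
        xW = x @ self.W.value  # (B, T, 4H) — one big matmul up front
        for t in range(T):
            z = xW[:, t, :] + h @ self.U.value + self.b.value
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        self._cache = (x, cache)
        return h

    def backward(self, dout):
        x, cache = self._cache
        B, T, D = x.shape
        H = self.H
        dh = np.asarray(dout, dtype=DTYPE)
        dc = np.zeros((B, H), dtype=DTYPE)
        dx = np.empty((B, T, D), dtype=DTYPE)
        dW = np.zeros_like(self.W.value)
        dU = np.zeros_like(self.U.value)
        db = np.zeros_like(self.b.value)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.value.T
            dh = dz @ self.U.value.T
            dc = dc * f
        self.W.grad += dW
        self.U.grad += dU
        self.b.grad += db
        return dx
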