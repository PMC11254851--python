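"""Minimal NumPy neural-network layer stack with explicit backward passes.

Implements exactly the layer kinds the two ECG-age architectures need
(1-D convolution, batch normalization, ReLU, max pooling, dropout, flatten,
linear) plus an Adam optimizer.  All arrays are float32.

Internally activations are stored channels-last, ``(N, L, C)``: convolution
then reduces to one im2col copy plus one GEMM with a contiguous output, and
normalization reduces over the two leading axes -- on a single CPU this
memory layout roughly halves the wall-clock cost of a training step relative
to the channels-first layout.  Every layer exposes

* ``forward(x, train)`` / ``backward(dy)``,
* ``params()``   -- list of :class:`Param` (weights with gradients),
* ``buffers()``  -- non-trainable state (batch-norm running statistics),
* ``descriptor(in_len)`` -- structural metadata the analytic complexity
  accountant consumes (never the other way round: the accountant re-derives
  counts from kernel/channel/stride arithmetic).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable (or frozen) tensor with its gradient."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    """Base class; layers are stateful (cache activations for backward)."""

    name = "layer"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def descriptor(self, in_len: int) -> dict:
        raise NotImplementedError

    def out_len(self, in_len: int) -> int:
        return in_len


def _same_pad(L: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-L // stride)  # ceil
    total = max((out - 1) * stride + k - L, 0)
    return total // 2, total - total // 2


class Conv1d(Layer):
    """Same-padded 1-D convolution; weight shape (out_ch, in_ch, k).

    Activations are (N, L, C); the im2col matrix is (N, L_out, k*in_ch) so the
    GEMM writes the (N, L_out, out_ch) output contiguously.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv",
                 kind: str = "conv1d", lead_mult: int = 1):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.name = name
        self.kind = kind
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.lead_mult = lead_mult
        self.w = Param(f"{name}.weight",
                       rng.normal(0.0, std, size=(out_ch, in_ch, kernel)).astype(np.float32))
        self.b = Param(f"{name}.bias", np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def out_len(self, in_len: int) -> int:
        return -(-in_len // self.stride)

    def _w2(self) -> np.ndarray:
        # (out_ch, in_ch, k) -> (k*in_ch, out_ch) matching the im2col layout
        return np.ascontiguousarray(self.w.value.transpose(2, 1, 0)
                                    ).reshape(self.kernel * self.in_ch, self.out_ch)

    def forward(self, x, train=False):
        N, L, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} input channels, got {C}")
        pl, pr = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, ::self.stride]                       # (N, Lout, C, k)
        Lout = win.shape[1]
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)
                                    ).reshape(N, Lout, self.kernel * C)
        y = cols @ self._w2()
        y += self.b.value
        self._cache = (cols, (N, L, C), (pl, pr), Lout)
        return y

    def backward(self, dy):
        cols, (N, L, C), (pl, pr), Lout = self._cache
        kC = self.kernel * C
        dW2 = cols.reshape(-1, kC).T @ dy.reshape(-1, self.out_ch)
        self.w.grad += dW2.reshape(self.kernel, C, self.out_ch).transpose(2, 1, 0)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = (dy @ self._w2().T).reshape(N, Lout, self.kernel, C)
        dxp = np.zeros((N, L + pl + pr, C), dtype=np.float32)
        s = self.stride
        for j in range(self.kernel):
            dxp[:, j:j + Lout * s:s, :] += dcols[:, :, j, :]
        return dxp[:, pl:pl + L, :]

    def params(self):
        return [self.w, self.b]

    def descriptor(self, in_len):
        return dict(name=self.name, kind=self.kind, in_ch=self.in_ch,
                    out_ch=self.out_ch, kernel=self.kernel, stride=self.stride,
                    in_len=in_len, out_len=self.out_len(in_len),
                    lead_mult=self.lead_mult)


class BatchNorm1d(Layer):
    """Per-channel normalization over the batch and time axes of (N, L, C)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.name = name
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.frozen = False  # inference statistics even in train mode
        self._cache = None

    def forward(self, x, train=False):
        # single-pass sufficient statistics; output as one fused affine map
        use_batch = train and not self.frozen
        if use_batch:
            m = x.shape[0] * x.shape[1]
            s1 = np.einsum("nlc->c", x, dtype=np.float64)
            s2 = np.einsum("nlc,nlc->c", x, x, dtype=np.float64)
            mean = (s1 / m).astype(np.float32)
            var = np.maximum(s2 / m - (s1 / m) ** 2, 0.0).astype(np.float32)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        scale = self.gamma.value * inv
        y = x * scale
        y += self.beta.value - mean * scale
        self._cache = (x, mean, inv, use_batch)
        return y

    def backward(self, dy):
        # xhat is never materialized: all reductions rewritten in terms of x
        x, mean, inv, use_batch = self._cache
        s1 = np.einsum("nlc->c", dy)
        sxy = np.einsum("nlc,nlc->c", dy, x)
        s2 = inv * (sxy - mean * s1)          # = sum(dy * xhat)
        self.gamma.grad += s2
        self.beta.grad += s1
        scale = self.gamma.value * inv
        if not use_batch:
            return dy * scale
        m = dy.shape[0] * dy.shape[1]
        c2 = inv * s2 / m
        c3 = s1 / m - mean * c2
        out = dy - x * c2
        out -= c3
        out *= scale
        return out

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def descriptor(self, in_len):
        return dict(name=self.name, kind="batchnorm", ch=self.ch,
                    in_len=in_len, out_len=in_len)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._y = None

    def forward(self, x, train=False):
        # in place: the producing layer's output is not referenced elsewhere
        y = np.maximum(x, 0.0, out=x)
        self._y = y
        return y

    def backward(self, dy):
        dy = dy * (self._y > 0)
        return dy

    def descriptor(self, in_len):
        return dict(name=self.name, kind="relu", in_len=in_len, out_len=in_len)


class MaxPool1d(Layer):
    """Non-overlapping max pooling on the time axis; window 1 is the identity."""

    def __init__(self, window: int, name: str = "pool"):
        self.name = name
        self.window = int(window)
        self._cache = None

    def out_len(self, in_len):
        return in_len // self.window

    def forward(self, x, train=False):
        P = self.window
        if P == 1:
            self._cache = None
            return x
        N, L, C = x.shape
        Lo = L // P
        xr = x[:, :Lo * P].reshape(N, Lo, P, C)
        y = xr.max(axis=2)
        self._cache = (xr, y, x.shape, Lo)
        return y

    def backward(self, dy):
        # equality mask against the stored maximum (exact float compare; a tie
        # splits the subgradient across the tied positions)
        if self._cache is None:
            return dy
        xr, y, (N, L, C), Lo = self._cache
        dx = (xr == y[:, :, None, :]) * dy[:, :, None, :]
        out = np.zeros((N, L, C), dtype=np.float32)
        out[:, :Lo * self.window] = dx.reshape(N, Lo * self.window, C)
        return out

    def descriptor(self, in_len):
        return dict(name=self.name, kind="maxpool", window=self.window,
                    in_len=in_len, out_len=self.out_len(in_len))


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None,
                 name: str = "dropout"):
        self.name = name
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep
                      ).astype(np.float32)
        self._mask /= keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def descriptor(self, in_len):
        return dict(name=self.name, kind="dropout", p=self.p,
                    in_len=in_len, out_len=in_len)


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def descriptor(self, in_len):
        return dict(name=self.name, kind="flatten", in_len=in_len, out_len=in_len)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / d_in)
        self.name = name
        self.d_in, self.d_out = d_in, d_out
        self.w = Param(f"{name}.weight", rng.normal(0, std, (d_out, d_in)).astype(np.float32))
        self.b = Param(f"{name}.bias", np.zeros(d_out, dtype=np.float32))
        self._x = None

    def forward(self, x, train=False):
        if x.shape[1] != self.d_in:
            raise ValueError(f"{self.name}: expected {self.d_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value

    def params(self):
        return [self.w, self.b]

    def descriptor(self, in_len):
        return dict(name=self.name, kind="linear", d_in=self.d_in, d_out=self.d_out,
                    in_len=in_len, out_len=in_len)


class Adam:
    """Adam with the conventional (0.9, 0.999, 1e-8) moments; skips frozen params."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
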