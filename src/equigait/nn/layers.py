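"""Minimal numpy layers with explicit forward/backward passes.

Conventions: batch-first arrays, time-series inputs shaped (n, T, channels),
flat inputs (n, features).  Each layer caches what its backward pass needs
during ``forward(x, train=True)``; ``backward(grad)`` returns the gradient
with respect to the layer input and accumulates parameter gradients in
``self.grads`` (aligned with ``self.params``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Flatten",
    "Conv1D",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "Dropout",
    "SpatialDropout1D",
    "LSTM",
    "ConvLSTM1x1",
]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class; stateless layers leave params/grads empty."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.reshape(-1, self.W.shape[0]).T @ grad.reshape(
            -1, self.W.shape[1]
        )
        self.grads[1][...] = grad.reshape(-1, self.W.shape[1]).sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """1-D convolution over (n, T, c_in) with optional dilation.

    ``padding`` is "same" (output length T), "causal" (left-pad only, output
    length T) or "valid" (output length T - span + 1, where span is the
    dilated kernel extent).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        padding: str = "same",
    ):
        super().__init__()
        if padding not in ("same", "causal", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.kernel, self.dilation, self.padding = kernel, dilation, padding
        limit = np.sqrt(6.0 / (kernel * c_in + c_out))
        self.W = rng.uniform(-limit, limit, size=(kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    @property
    def span(self) -> int:
        return (self.kernel - 1) * self.dilation + 1

    def _pads(self):
        if self.padding == "same":
            total = self.span - 1
            return total // 2, total - total // 2
        if self.padding == "causal":
            return self.span - 1, 0
        return 0, 0

    def forward(self, x, train=False):
        left, right = self._pads()
        if x.shape[1] + left + right < self.span:
            raise ValueError(
                f"input length {x.shape[1]} shorter than dilated kernel span "
                f"{self.span} with 'valid' padding"
            )
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        self._xp_shape = xp.shape
        t_out = xp.shape[1] - self.span + 1
        # taps[n, t, k, c] = xp[n, t + k*dilation, c]
        idx = np.arange(t_out)[:, None] + np.arange(self.kernel)[None, :] * self.dilation
        taps = xp[:, idx, :]
        self._taps = taps
        return np.einsum("ntkc,kco->nto", taps, self.W, optimize=True) + self.b

    def backward(self, grad):
        self.grads[0][...] = np.einsum(
            "ntkc,nto->kco", self._taps, grad, optimize=True
        )
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dxp = np.zeros(self._xp_shape)
        t_out = grad.shape[1]
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, off : off + t_out, :] += np.einsum(
                "nto,co->ntc", grad, self.W[k], optimize=True
            )
        left, right = self._pads()
        t_in = self._xp_shape[1] - left - right
        return dxp[:, left : left + t_in, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool width is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        n, t, c = x.shape
        t_out = t // self.pool
        if t_out == 0:
            raise ValueError(f"input length {t} shorter than pool width {self.pool}")
        self._shape = x.shape
        xr = x[:, : t_out * self.pool].reshape(n, t_out, self.pool, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, t_out, c = grad.shape
        dxr = np.zeros((n, t_out, self.pool, c))
        ni, ti, ci = np.ogrid[:n, :t_out, :c]
        dxr[ni, ti, self._arg, ci] = grad
        dx = np.zeros(self._shape)
        dx[:, : t_out * self.pool] = dxr.reshape(n, t_out * self.pool, c)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train=False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class SpatialDropout1D(Dropout):
    """Drops whole channels of a (n, T, c) sequence instead of single values."""

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        mask = (self.rng.random((x.shape[0], 1, x.shape[2])) >= self.p) / (1 - self.p)
        self._mask = mask
        return x * mask


class LSTM(Layer):
    """Single LSTM layer over (n, T, c_in) with full BPTT.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1.  ``return_sequences`` controls whether
    the full hidden sequence (n, T, units) or only the final state (n, units)
    is emitted.
    """

    def __init__(
        self,
        c_in: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        limit = np.sqrt(6.0 / (c_in + units))
        self.Wx = rng.uniform(-limit, limit, size=(c_in, 4 * units))
        limit_h = np.sqrt(6.0 / (2 * units))
        self.Wh = rng.uniform(-limit_h, limit_h, size=(units, 4 * units))
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        n, T, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        hs = np.empty((n, T, u))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, grad):
        x = self._x
        n, T, _ = x.shape
        u = self.units
        for gbuf in self.grads:
            gbuf[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        dWx, dWh, db = self.grads
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = dh_next + (grad[:, t] if self.return_sequences else 0)
            if not self.return_sequences and t == T - 1:
                dh = dh + grad
            dc = dc_next + dh * o * (1 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


class ConvLSTM1x1(Layer):
    """Convolutional LSTM with (1, 1) kernels and (1, 1) stride.

    A window of L samples × c channels is viewed as ``n_steps`` time steps of
    a (1 × L/n_steps) spatial grid, the usual layout for convolutional LSTMs
    on inertial windows.  With (1, 1) kernels the gate convolutions are
    pointwise, i.e. an ordinary LSTM applied at every spatial position with
    shared weights, recurrent over the ``n_steps`` sub-sequences.  The final
    hidden state (positions × filters) is flattened for the dense head.

    When L is not divisible by ``n_steps`` the step count falls back to the
    largest of (n_steps, 2, 1) that divides L.
    """

    def __init__(
        self, c_in: int, filters: int, rng: np.random.Generator, n_steps: int = 4
    ):
        super().__init__()
        self.filters = filters
        self.n_steps = n_steps
        self.lstm = LSTM(c_in, filters, rng)
        self.params = self.lstm.params
        self.grads = self.lstm.grads

    def _steps(self, length: int) -> int:
        for T in (self.n_steps, 2, 1):
            if length % T == 0:
                return T
        return 1

    def forward(self, x, train=False):
        n, length, c = x.shape
        T = self._steps(length)
        w = length // T
        self._shape, self._T = x.shape, T
        xr = x.reshape(n, T, w, c).transpose(0, 2, 1, 3).reshape(n * w, T, c)
        h = self.lstm.forward(xr, train)
        return h.reshape(n, w * self.filters)

    def backward(self, grad):
        n, length, c = self._shape
        T = self._T
        w = length // T
        dxr = self.lstm.backward(grad.reshape(n * w, self.filters))
        return dxr.reshape(n, w, T, c).transpose(0, 2, 1, 3).reshape(n, length, c)
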