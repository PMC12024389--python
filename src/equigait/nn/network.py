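"""Sequential and WaveNet-style network containers, Adam, and the loss.

This is a compact numpy training engine: enough machinery (explicit
backpropagation, Adam updates, softmax cross-entropy) to train the small
gait-classification architectures on a CPU, with seeded determinism.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv1D, Dense, GlobalAvgPool1D, Layer, ReLU, _sigmoid

__all__ = ["Network", "Sequential", "WaveNet", "Adam", "softmax", "softmax_xent"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y_idx: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y_idx)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y_idx] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


class Network:
    """Interface: forward / backward / iteration over trainable layers."""

    def layers(self) -> list[Layer]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_pairs(self):
        for layer in self.layers():
            yield from zip(layer.params, layer.grads)

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers())


class Sequential(Network):
    def __init__(self, layers: list[Layer]):
        self._layers = layers

    def layers(self):
        return self._layers

    def forward(self, x, train=False):
        for layer in self._layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self._layers):
            grad = layer.backward(grad)
        return grad


class WaveNet(Network):
    """Stack of gated dilated causal convolutions with residual and skip paths.

    Each block convolves its input with a filter branch (tanh) and a gate
    branch (sigmoid), multiplies them, and feeds the result both into a 1x1
    residual projection (added back to the block input) and a 1x1 skip
    projection (summed across blocks).  The summed skips pass through
    ReLU → 1x1 conv → ReLU → global average pooling → dense output.
    Dilations double per block, so the receptive field grows exponentially
    with depth.
    """

    def __init__(
        self,
        c_in: int,
        n_classes: int,
        rng: np.random.Generator,
        residual_channels: int = 16,
        skip_channels: int = 32,
        kernel: int = 2,
        n_blocks: int = 4,
    ):
        self.input_conv = Conv1D(c_in, residual_channels, kernel, rng, padding="causal")
        self.blocks = []
        for b in range(n_blocks):
            d = 2**b
            self.blocks.append(
                {
                    "filter": Conv1D(
                        residual_channels, residual_channels, kernel, rng, d, "causal"
                    ),
                    "gate": Conv1D(
                        residual_channels, residual_channels, kernel, rng, d, "causal"
                    ),
                    "skip": Conv1D(residual_channels, skip_channels, 1, rng),
                    "residual": Conv1D(residual_channels, residual_channels, 1, rng),
                }
            )
        self.head_relu1 = ReLU()
        self.head_conv = Conv1D(skip_channels, skip_channels, 1, rng)
        self.head_relu2 = ReLU()
        self.pool = GlobalAvgPool1D()
        self.out = Dense(skip_channels, n_classes, rng)

    def layers(self):
        out = [self.input_conv]
        for blk in self.blocks:
            out.extend([blk["filter"], blk["gate"], blk["skip"], blk["residual"]])
        out.extend([self.head_conv, self.out])
        return out

    def forward(self, x, train=False):
        x = self.input_conv.forward(x, train)
        skips = None
        self._gates = []
        for blk in self.blocks:
            f = np.tanh(blk["filter"].forward(x, train))
            g = _sigmoid(blk["gate"].forward(x, train))
            z = f * g
            self._gates.append((f, g))
            s = blk["skip"].forward(z, train)
            skips = s if skips is None else skips + s
            x = x + blk["residual"].forward(z, train)
        h = self.head_relu1.forward(skips, train)
        h = self.head_conv.forward(h, train)
        h = self.head_relu2.forward(h, train)
        return self.out.forward(self.pool.forward(h, train), train)

    def backward(self, grad):
        grad = self.pool.backward(self.out.backward(grad))
        grad = self.head_relu2.backward(grad)
        grad = self.head_conv.backward(grad)
        dskips = self.head_relu1.backward(grad)
        dx = np.zeros(
            (dskips.shape[0], dskips.shape[1], self.blocks[0]["residual"].W.shape[2])
        )
        for blk, (f, g) in zip(reversed(self.blocks), reversed(self._gates)):
            dz = blk["residual"].backward(dx) + blk["skip"].backward(dskips)
            df = dz * g * (1 - f * f)
            dg = dz * f * g * (1 - g)
            dx = dx + blk["filter"].backward(df) + blk["gate"].backward(dg)
        return self.input_conv.backward(dx)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(param_pairs)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
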