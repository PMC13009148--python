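"""Small convolutional-network engine in vectorized NumPy.

Implements exactly the pieces the channels-by-time EEG classifier needs:
2-D convolution with Keras-style 'same' padding and ReLU, max-pooling along
the time axis, inverted dropout, dense layers, the Adamax optimizer, and a
class-weighted sigmoid cross-entropy loss.  Forward passes cache what the
backward pass needs; the backward pass also exposes the gradient of the
output logit with respect to every convolutional activation map, which is
what Grad-CAM consumes.

All arrays are float32; all randomness comes from generators passed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Conv2D", "MaxPoolTime", "Dropout", "Flatten", "Dense",
    "Sequential", "Adamax", "weighted_bce_from_logits",
]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Convolution + ReLU with 'same' padding (stride 1, pad bottom/right)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], rng) -> None:
        super().__init__()
        self.kh, self.kw = kernel
        fan_in = in_ch * self.kh * self.kw
        self.W = (rng.standard_normal((out_ch, fan_in)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        B, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, self.kh - 1), (0, self.kw - 1)))
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * Wd, C * self.kh * self.kw)
        z = cols @ self.W.T + self.b
        self._cols, self._shape = cols, (B, C, H, Wd)
        self._mask = z > 0
        a = np.where(self._mask, z, 0.0)
        return np.ascontiguousarray(
            a.reshape(B, H, Wd, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, Wd = self._shape
        d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            B * H * Wd, self.out_ch)
        d = d * self._mask
        self.grads[0][...] = d.T @ self._cols
        self.grads[1][...] = d.sum(axis=0)
        dcols = (d @ self.W).reshape(B, H, Wd, C, self.kh, self.kw)
        dxp = np.zeros((B, C, H + self.kh - 1, Wd + self.kw - 1), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + H, j:j + Wd] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, :H, :Wd]


class MaxPoolTime(Layer):
    """Max-pool (1, size) along the time axis; a trailing odd column is dropped."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        B, F, H, Wd = x.shape
        Wo = Wd // self.size
        xt = x[..., : Wo * self.size].reshape(B, F, H, Wo, self.size)
        self._argmax = xt.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, F, H, Wd = self._in_shape
        Wo = Wd // self.size
        dxt = np.zeros((B, F, H, Wo, self.size), dtype=np.float32)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[..., : Wo * self.size] = dxt.reshape(B, F, H, Wo * self.size)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng, relu: bool = True) -> None:
        super().__init__()
        scale = np.sqrt((2.0 if relu else 1.0) / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.relu = relu

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Sequential:
    """Layer stack ending in a single logit per example."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        out = x.astype(np.float32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out[:, 0]

    def backward(self, dlogit: np.ndarray,
                 record_conv_grads: bool = False) -> dict[int, np.ndarray] | None:
        """Backpropagate d(loss)/d(logit); optionally collect conv-output grads."""
        conv_grads: dict[int, np.ndarray] = {}
        dout = dlogit[:, None].astype(np.float32)
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            if record_conv_grads and isinstance(layer, Conv2D):
                conv_grads[idx] = dout.copy()
            dout = layer.backward(dout)
        return conv_grads if record_conv_grads else None

    def forward_with_activations(self, x: np.ndarray) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        """Inference pass that also returns each Conv2D's post-ReLU output."""
        acts: dict[int, np.ndarray] = {}
        out = x.astype(np.float32, copy=False)
        for idx, layer in enumerate(self.layers):
            out = layer.forward(out, False, None)
            if isinstance(layer, Conv2D):
                acts[idx] = out
        return out[:, 0], acts


class Adamax:
    """Adamax: Adam with an infinity-norm second moment."""

    def __init__(self, params: list[np.ndarray], lr: float = 5e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bias = 1.0 - self.beta1 ** self.t
        for p, g, m, u in zip(self.params, grads, self.m, self.u):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= (self.lr / bias) * m / (u + self.eps)


def weighted_bce_from_logits(logits: np.ndarray, y: np.ndarray,
                             sample_weights: np.ndarray
                             ) -> tuple[float, np.ndarray]:
    """Mean class-weighted binary cross-entropy and its gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    # log(1 + e^z) computed stably
    softplus = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
    losses = sample_weights * (softplus - y * z)
    p = expit(z)
    dlogits = sample_weights * (p - y) / len(z)
    return float(losses.mean()), dlogits.astype(np.float32)
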