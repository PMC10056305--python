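"""Minimal NumPy neural-network backend.

Instantiates a :class:`~ecgpsr.network.NetworkSpec` as a runnable model
with exact forward/backward passes for conv2d (im2col), max pooling,
fully connected layers, ReLU, inverted dropout and a softmax/cross-entropy
head, trained with Adam.  Everything is seeded and deterministic; sized
for the small portrait networks used here, not for general deep learning.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkSpec, propagate_shapes


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, C*k*k, OH*OW) plus output extents."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    sn, sc, sh, sw = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, k, k, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride), writeable=False)
    return windows.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Scatter-add column gradients back to input shape (adjoint of _im2col)."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dpad[:, :, i:i + stride * oh:stride,
                 j:j + stride * ow:stride] += d6[:, :, i, j]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class _Conv2D:
    def __init__(self, layer, rng):
        k, ci, co = layer.kernel, layer.in_channels, layer.out_channels
        fan_in = k * k * ci
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(co, ci, k, k)).astype(np.float32)
        self.b = np.zeros(co, dtype=np.float32)
        self.k, self.stride, self.pad = k, layer.stride, layer.padding
        self.relu = layer.activation == "relu"
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self.cols = cols
        co = self.W.shape[0]
        out = (self.W.reshape(co, -1) @ cols) + self.b[None, :, None]
        out = out.reshape(x.shape[0], co, oh, ow)
        if self.relu:
            self.mask = out > 0
            out = out * self.mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self.mask
        n, co, oh, ow = dout.shape
        d2 = dout.reshape(n, co, oh * ow)
        self.grads[0][...] = np.einsum("nop,ncp->oc", d2, self.cols,
                                       optimize=True).reshape(self.W.shape)
        self.grads[1][...] = d2.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W.reshape(co, -1), d2,
                          optimize=True)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad)


class _MaxPool:
    def __init__(self, layer):
        self.k, self.stride, self.pad = layer.kernel, layer.stride, layer.padding
        self.params, self.grads = [], []

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        n, c, h, w = x.shape
        cols, oh, ow = _im2col(x[:, :, None].reshape(n * c, 1, h, w),
                               self.k, self.stride, self.pad)
        # cols: (n*c, k*k, oh*ow)
        self.argmax = np.argmax(cols, axis=1)
        self.oh, self.ow = oh, ow
        out = np.take_along_axis(cols, self.argmax[:, None, :], axis=1)
        return out.reshape(n, c, oh, ow)

    def backward(self, dout):
        n, c, h, w = self.x_shape
        oh, ow = self.oh, self.ow
        dcols = np.zeros((n * c, self.k * self.k, oh * ow), dtype=dout.dtype)
        np.put_along_axis(dcols, self.argmax[:, None, :],
                          dout.reshape(n * c, 1, oh * ow), axis=1)
        dx = _col2im(dcols, (n * c, 1, h, w), self.k, self.stride, self.pad)
        return dx.reshape(n, c, h, w)


class _Flatten:
    params, grads = [], []

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.x_shape)


class _Dense:
    def __init__(self, layer, rng):
        ci, co = layer.in_channels, layer.out_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / ci),
                            size=(ci, co)).astype(np.float32)
        self.b = np.zeros(co, dtype=np.float32)
        self.relu = layer.activation == "relu"
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self.x = x
        out = x @ self.W + self.b
        if self.relu:
            self.mask = out > 0
            out = out * self.mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self.mask
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class _Dropout:
    def __init__(self, layer):
        self.keep = layer.keep_prob
        self.params, self.grads = [], []

    def forward(self, x, train, rng):
        if not train:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) < self.keep) / self.keep
        return x * self.mask

    def backward(self, dout):
        if self.mask is None:
            return dout
        return dout * self.mask


class Model:
    """A NetworkSpec instantiated with weights; forward maps portraits to
    class probabilities (softmax rows summing to 1)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        propagate_shapes(spec)  # validate before allocating
        self.spec = spec
        rng = np.random.default_rng(np.random.PCG64(seed))
        self.layers = []
        for layer in spec.layers:
            if layer.kind == "conv2d":
                self.layers.append(_Conv2D(layer, rng))
            elif layer.kind == "maxpool2d":
                self.layers.append(_MaxPool(layer))
            elif layer.kind == "flatten":
                self.layers.append(_Flatten())
            elif layer.kind == "fully_connected":
                self.layers.append(_Dense(layer, rng))
            elif layer.kind == "dropout":
                self.layers.append(_Dropout(layer))

    def parameters(self):
        return [p for l in self.layers for p in l.params]

    def gradients(self):
        return [g for l in self.layers for g in l.grads]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward_logits(self, images: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """images: (N, H, W) binary/float -> (N, num_classes) logits."""
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities at inference (softmax applied)."""
        return softmax(self.forward_logits(images, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
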