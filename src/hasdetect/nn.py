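"""A small numpy CNN engine for the seizure detectors.

Implements exactly the layer set the architecture specs use: 2-D convolution
(im2col + BLAS matmul), batch normalization, ReLU, overlapping max-pooling,
flatten, dense, and a softmax cross-entropy head, with reverse-mode
gradients and an RMSProp update.  Everything is float32, seeded, and
deterministic for a fixed seed.

Data layout is NCHW; the 1-D detector runs through the same engine with a
width-1 spatial axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import CnnSpec


class Conv2d:
    """3x3-style convolution with stride/padding, He-initialized."""

    def __init__(self, c_in, c_out, kernel, stride, padding, rng):
        kh, kw = kernel
        fan_in = c_in * kh * kw
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, train):
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._x_padded_shape = x.shape
        n, c, h, w = x.shape
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        # (n, c, ho, wo, kh, kw) -> (n, ho, wo, c*kh*kw)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, -1)
        self._cols = cols.reshape(-1, cols.shape[-1])
        out = self._cols @ self.w + self.b
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, ho, wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(n, ho, wo, self.c_in, *self.kernel)
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.padding
        dx_pad = np.zeros(self._x_padded_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dx_pad[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if ph or pw:
            h, w = dx_pad.shape[2] - 2 * ph, dx_pad.shape[3] - 2 * pw
            dx_pad = dx_pad[:, :, ph : ph + h, pw : pw + w]
        return dx_pad

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[
            None, :, None, None
        ]

    def backward(self, dout):
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=axes)[None, :, None, None]
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)[None, :, None, None]
        ) / self._std[None, :, None, None]
        return dx.astype(np.float32)

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]


class ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def grads(self):
        return []


class MaxPool2d:
    """Max-pool with arbitrary (possibly overlapping) kernel and stride."""

    def __init__(self, kernel, stride):
        self.kernel, self.stride = kernel, stride

    def params(self):
        return []

    def forward(self, x, train):
        kh, kw = self.kernel
        sh, sw = self.stride
        self._x_shape = x.shape
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, kh * kw)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        kh, kw = self.kernel
        sh, sw = self.stride
        n, c, ho, wo = dout.shape
        dx = np.zeros(self._x_shape, dtype=np.float32)
        # scatter each kernel position's gradient where it was the argmax
        for p in range(kh * kw):
            mask = self._argmax == p
            if not mask.any():
                continue
            i, j = divmod(p, kw)
            contrib = np.where(mask, dout, 0.0).astype(np.float32)
            # overlapping windows may write the same input cell from
            # different output positions: accumulate per output row/col
            dx_view = dx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw]
            dx_view += contrib
        return dx

    def grads(self):
        return []


class Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def grads(self):
        return []


class Dense:
    def __init__(self, n_in, n_out, rng, relu=False):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, train):
        self._x = x
        out = x @ self.w + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class Network:
    """A CnnSpec instantiated with parameters; forward/backward over NCHW."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w, c = spec.input_shape
        self.layers: list = []
        shapes = spec.propagate()
        cur_c = c
        for layer, shape in zip(spec.layers, shapes):
            if layer.kind == "conv":
                self.layers.append(
                    Conv2d(cur_c, layer.filters, layer.kernel, layer.stride, layer.padding, rng)
                )
                cur_c = layer.filters
                if layer.batch_norm:
                    self.layers.append(BatchNorm2d(cur_c))
                if layer.relu:
                    self.layers.append(ReLU())
            elif layer.kind == "max_pool":
                self.layers.append(MaxPool2d(layer.kernel, layer.stride))
            elif layer.kind == "flatten":
                self.layers.append(Flatten())
                self._flat = shape[0]
            elif layer.kind == "fully_connected":
                self.layers.append(Dense(self._flat, layer.units, rng, relu=layer.relu))
                self._flat = layer.units
            elif layer.kind == "softmax":
                pass  # folded into the loss / predict

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch; x is NCHW float32."""
        out = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params():
                yield (li, name), p

    def gradients(self):
        for li, layer in enumerate(self.layers):
            for name, g in layer.grads():
                yield (li, name), g


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient wrt the logits."""
    p = softmax(logits)
    n = y.size
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class RMSProp:
    """RMSProp: cache = rho*cache + (1-rho)*g^2; p -= lr*g/(sqrt(cache)+eps)."""

    def __init__(self, network: Network, lr=1e-3, rho=0.9, eps=1e-8):
        self.network = network
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = {k: np.zeros_like(p) for k, p in network.parameters()}

    def step(self) -> None:
        params = dict(self.network.parameters())
        for k, g in self.network.gradients():
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(c) + self.eps)
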