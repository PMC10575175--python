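"""Minimal CPU neural-network layers for 3D heatmap volumes.

Plain-numpy building blocks (3D convolution via sliding windows, batch
normalization, ReLU, global average pooling, a linear head) with manual
backpropagation and SGD-with-momentum updates.  Everything is
deterministic given the initialization seed and data order; gradients are
verified against finite differences in the test suite.

Sized for desk-scale inputs (tens of channels, ~32x32 spatial grids);
no attempt is made at large-scale efficiency.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # training precision; float32 keeps BLAS fast on CPU


class Layer:
    """Base: forward caches what backward needs; params yields
    (parameter, gradient) pairs updated in place by the optimizer."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


class Conv3d(Layer):
    """3D convolution (cross-correlation) with per-axis stride.

    ``pad='same'`` pads k//2 on both sides of each axis; ``pad='valid'``
    pads nothing (used by the time-strided lateral connections).
    """

    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), pad="same",
                 bias=True, rng=None):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.pad = (
            tuple(k // 2 for k in self.kernel) if pad == "same" else (0, 0, 0)
        )
        rng = rng or np.random.default_rng(0)
        fan_in = cin * int(np.prod(self.kernel))
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, cin) + self.kernel).astype(DTYPE)
        self.b = np.zeros(cout, DTYPE) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None

    def forward(self, x, train=True):
        x = np.asarray(x, DTYPE)
        pt, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        st, sh, sw = self.stride
        win = win[:, :, ::st, ::sh, ::sw]
        n, _, to, ho, wo = win.shape[:5]
        # im2col: (N, To, Ho, Wo, C*kt*kh*kw) contiguous, then one matmul
        cols = np.ascontiguousarray(
            win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
        ).reshape(n * to * ho * wo, -1)
        y = cols @ self.w.reshape(self.w.shape[0], -1).T
        y = np.ascontiguousarray(
            y.reshape(n, to, ho, wo, -1).transpose(0, 4, 1, 2, 3)
        )
        if self.b is not None:
            y += self.b[None, :, None, None, None]
        if train:
            self._cols = cols
            self._xshape = x.shape
            self._xpshape = xp.shape
        return y

    def backward(self, dy):
        n, o, to, ho, wo = dy.shape
        dy_flat = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 4, 1)
        ).reshape(-1, o)
        self.dw += (dy_flat.T @ self._cols).reshape(self.w.shape)
        if self.b is not None:
            self.db += dy_flat.sum(axis=0)
        dxp = np.zeros(self._xpshape, DTYPE)
        st, sh, sw = self.stride
        kt, kh, kw = self.kernel
        w2 = self.w.reshape(o, -1, kt * kh * kw)  # (O, C, K)
        for off in range(kt * kh * kw):
            i, r = divmod(off, kh * kw)
            j, k = divmod(r, kw)
            contrib = (dy_flat @ w2[:, :, off]).reshape(n, to, ho, wo, -1)
            dxp[:, :,
                i:i + to * st:st,
                j:j + ho * sh:sh,
                k:k + wo * sw:sw] += contrib.transpose(0, 4, 1, 2, 3)
        pt, ph, pw = self.pad
        _, _, t, h, w = self._xshape
        self._cols = None
        return dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + w]

    def params(self):
        out = [(self.w, self.dw)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, T, H, W)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels, DTYPE)
        self.beta = np.zeros(channels, DTYPE)
        self.dgamma = np.zeros(channels, DTYPE)
        self.dbeta = np.zeros(channels, DTYPE)
        self.running_mean = np.zeros(channels, DTYPE)
        self.running_var = np.ones(channels, DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[1]
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.dgamma += (dy * self._xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        g = self.gamma.reshape(shape)
        n = self._n
        dxhat = dy * g
        dx = (self._inv.reshape(shape) / n) * (
            n * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes).reshape(shape)
        )
        self._xhat = None
        return dx

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class ResBlock3d(Layer):
    """conv-bn-relu-conv-bn plus a (projected if needed) shortcut."""

    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), rng=None):
        self.conv1 = Conv3d(cin, cout, kernel, stride, bias=False, rng=rng)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, kernel, bias=False, rng=rng)
        self.bn2 = BatchNorm3d(cout)
        self.project = cin != cout or stride != (1, 1, 1)
        if self.project:
            self.short_conv = Conv3d(cin, cout, (1, 1, 1), stride, bias=False,
                                     rng=rng)
            self.short_bn = BatchNorm3d(cout)

    def forward(self, x, train=True):
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, train), train), train
                ),
                train,
            ),
            train,
        )
        short = (
            self.short_bn.forward(self.short_conv.forward(x, train), train)
            if self.project
            else x
        )
        out = main + short
        if train:
            self._out_mask = out > 0
        return out * (out > 0)

    def backward(self, dy):
        dy = dy * self._out_mask
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))
            )
        )
        if self.project:
            dshort = self.short_conv.backward(self.short_bn.backward(dy))
        else:
            dshort = dy
        return dmain + dshort

    def params(self):
        out = (self.conv1.params() + self.bn1.params() + self.conv2.params()
               + self.bn2.params())
        if self.project:
            out += self.short_conv.params() + self.short_bn.params()
        return out


class GlobalAvgPool(Layer):
    """(N, C, T, H, W) -> (N, C) mean over all spatiotemporal positions."""

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        n, c, t, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None], self._shape
        ) / (t * h * w)


class Linear(Layer):
    def __init__(self, fin, fout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(1.0 / fin), (fout, fin)).astype(DTYPE)
        self.b = np.zeros(fout, DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw += dy.T @ self._x
        self.db += dy.sum(axis=0)
        dx = dy @ self.w
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGD:
    """SGD with classical momentum and optional weight decay."""

    def __init__(self, params, lr=0.05, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), v in zip(self.params, self.velocity):
            if self.weight_decay:
                g = g + self.weight_decay * p
            v *= self.momentum
            v -= self.lr * g
            p += v

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
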