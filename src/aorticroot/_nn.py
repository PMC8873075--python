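"""Minimal NumPy neural-network core for 3D volumetric segmentation.

Implements exactly the layer set needed by the U-Net used in this package:
3x3x3 / 1x1x1 convolutions, batch normalization, ReLU, 2x2x2 max pooling,
dropout, 2x2x2 transposed convolution, sigmoid head, and the Adam optimizer.
All layers provide hand-written backward passes; activations are kept
channels-last ``(N, D, H, W, C)`` in float32 so the inner products map onto
BLAS matmuls.

Convolutions use a shift-and-matmul scheme: for each of the 27 (or 1) kernel
offsets the shifted activation view is multiplied with the corresponding
``(C_in, C_out)`` weight slice.  This avoids materializing an im2col matrix
and is memory-bandwidth bound rather than copy bound, which is what matters
on a single CPU core.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: forward/backward plus (param, grad) pairs for the optimizer."""

    def parameters(self):
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padding 3D convolution with cubic kernel of size 1 or 3.

    The 3x3x3 case lowers to a single GEMM over an im2col matrix which is
    cached between forward and backward, so the weight gradient reuses it and
    only the input gradient needs the 27-offset scatter-add.
    """

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel**3
        scale = np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        self.w = (rng.standard_normal((kernel, kernel, kernel, c_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False, rng=None):
        k = self.kernel
        if k == 1:
            if train:
                self._x = x
            return x @ self.w[0, 0, 0] + self.b
        n, D, H, W, c = x.shape
        m = n * D * H * W
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        y = np.empty((m, self.c_out), dtype=F32)
        y[:] = self.b
        cache = [] if train else None
        for i in range(3):
            for j in range(3):
                for l in range(3):
                    xs = np.ascontiguousarray(
                        xp[:, i : i + D, j : j + H, l : l + W, :]
                    ).reshape(m, c)
                    y += xs @ self.w[i, j, l]
                    if train:
                        cache.append(xs)
        if train:
            self._cache, self._shape = cache, (n, D, H, W, c)
        return y.reshape(n, D, H, W, self.c_out)

    def backward(self, gy):
        if self.kernel == 1:
            x = self._x
            self._x = None
            m = int(np.prod(x.shape[:4]))
            gyf = gy.reshape(m, self.c_out)
            self.gw[0, 0, 0] += x.reshape(m, self.c_in).T @ gyf
            self.gb += gyf.sum(axis=0)
            return (gyf @ self.w[0, 0, 0].T).reshape(x.shape)
        n, D, H, W, c = self._shape
        m = n * D * H * W
        gyf = np.ascontiguousarray(gy).reshape(m, self.c_out)
        self.gb += gyf.sum(axis=0)
        gxp = np.zeros((n, D + 2, H + 2, W + 2, c), dtype=F32)
        idx = 0
        for i in range(3):
            for j in range(3):
                for l in range(3):
                    xs = self._cache[idx]
                    idx += 1
                    self.gw[i, j, l] += xs.T @ gyf
                    dcol = gyf @ self.w[i, j, l].T
                    gxp[:, i : i + D, j : j + H, l : l + W, :] += dcol.reshape(
                        n, D, H, W, c
                    )
        self._cache = None
        return gxp[:, 1 : 1 + D, 1 : 1 + H, 1 : 1 + W, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over the (N, D, H, W) axes.

    Training normalizes by the batch statistics and updates exponential
    running averages; inference uses the frozen running statistics, which
    makes eval-mode prediction a fixed function of the input - deterministic
    and translation-equivariant regardless of the inference window size.
    """

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train=False, rng=None):
        ax = (0, 1, 2, 3)
        if train:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv.astype(F32))
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, gy):
        xhat, inv = self._cache
        self._cache = None
        ax = (0, 1, 2, 3)
        m = float(np.prod(gy.shape[:4]))
        self.ggamma += (gy * xhat).sum(axis=ax)
        self.gbeta += gy.sum(axis=ax)
        gxhat = gy * self.gamma
        gx = (gxhat - gxhat.mean(axis=ax) - xhat * (gxhat * xhat).sum(axis=ax) / m) * inv
        return gx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        g = gy * self._mask
        self._mask = None
        return g


class MaxPool2(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, D, H, W, c = x.shape
        xr = x.reshape(n, D // 2, 2, H // 2, 2, W // 2, 2, c)
        y = xr.max(axis=(2, 4, 6))
        if train:
            self._xr_shape = xr.shape
            self._mask = xr == y[:, :, None, :, None, :, None, :]
            cnt = self._mask.sum(axis=(2, 4, 6), keepdims=True)
            self._cnt = cnt
        return y

    def backward(self, gy):
        g = (self._mask * (gy[:, :, None, :, None, :, None, :] / self._cnt)).astype(F32)
        self._mask = None
        n, d2, _, h2, _, w2, _, c = self._xr_shape
        return g.reshape(n, d2 * 2, h2 * 2, w2 * 2, c)


class Dropout(Layer):
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, gy):
        if getattr(self, "_mask", None) is None:
            return gy
        g = gy * self._mask
        self._mask = None
        return g


class ConvTranspose2(Layer):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((2, 2, 2, c_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def parameters(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        n, D, H, W, c = x.shape
        wmat = self.w.reshape(8 * self.c_out, self.c_in).T if False else self.w
        # (N,D,H,W,C) @ (C, 8*O)
        z = x @ self.w.transpose(3, 0, 1, 2, 4).reshape(self.c_in, 8 * self.c_out)
        z = z.reshape(n, D, H, W, 2, 2, 2, self.c_out)
        y = z.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(n, 2 * D, 2 * H, 2 * W, self.c_out)
        return y + self.b

    def backward(self, gy):
        x = self._x
        self._x = None
        n, D2, H2, W2, co = gy.shape
        D, H, W = D2 // 2, H2 // 2, W2 // 2
        self.gb += gy.sum(axis=(0, 1, 2, 3))
        gz = gy.reshape(n, D, 2, H, 2, W, 2, co).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        gz = np.ascontiguousarray(gz).reshape(n, D, H, W, 8 * co)
        wflat = self.w.transpose(3, 0, 1, 2, 4).reshape(self.c_in, 8 * co)
        gw = np.tensordot(x, gz, axes=([0, 1, 2, 3], [0, 1, 2, 3]))  # (C_in, 8*O)
        self.gw += gw.reshape(self.c_in, 2, 2, 2, co).transpose(1, 2, 3, 0, 4)
        return gz @ wflat.T


class Adam:
    """Adam optimizer over the (param, grad) pairs of a list of layers."""

    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = [p for layer in layers for p in layer.parameters()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0
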