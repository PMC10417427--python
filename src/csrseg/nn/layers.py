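"""Neural-network layers with explicit forward/backward passes.

All layers operate on float32 arrays in channels-first layout
``(batch, channels, *spatial)`` with 2 or 3 spatial dimensions. Convolutions
use "same" padding and stride 1; the 3x3(x3) convolution is computed by
shift-and-accumulate matmuls (one GEMM per kernel offset), which on CPU is
substantially faster than im2col for the small channel counts used here.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameter gradients accumulate
into ``Param.grad``.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Param", "Layer", "Conv", "BatchNorm", "ReLU", "MaxPool",
           "TransposedConv", "SEBlock", "CSRBlock", "Concat"]


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv(Layer):
    """Stride-1 convolution with same padding (kernel 1 or 3 per axis)."""

    def __init__(self, in_c: int, out_c: int, kernel: int, ndim: int,
                 rng: np.random.Generator, bias: bool = False, name: str = "conv"):
        self.in_c, self.out_c, self.kernel, self.ndim = in_c, out_c, kernel, ndim
        fan_in = in_c * kernel ** ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_c, in_c) + (kernel,) * ndim).astype(np.float32)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_c, np.float32)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _offsets(self):
        return list(itertools.product(*[range(self.kernel)] * self.ndim))

    def forward(self, x, train=False):
        B = x.shape[0]
        S = x.shape[2:]
        n = int(np.prod(S))
        if self.kernel == 1:
            xf = x.reshape(B, self.in_c, n)
            w2 = self.w.value.reshape(self.out_c, self.in_c)
            y = np.empty((B, self.out_c, n), np.float32)
            for b in range(B):
                y[b] = w2 @ xf[b]
            self._cache = (x, None)
        else:
            p = self.kernel // 2
            xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * self.ndim)
            y = np.zeros((B, self.out_c, n), np.float32)
            for off in self._offsets():
                sl = (slice(None), slice(None)) + tuple(
                    slice(o, o + s) for o, s in zip(off, S))
                xs = np.ascontiguousarray(xp[sl]).reshape(B, self.in_c, n)
                w2 = self.w.value[(slice(None), slice(None)) + off]
                for b in range(B):
                    y[b] += w2 @ xs[b]
            self._cache = (xp, S)
        if self.b is not None:
            y += self.b.value[None, :, None]
        return y.reshape(B, self.out_c, *S)

    def backward(self, dy):
        B = dy.shape[0]
        S = dy.shape[2:]
        n = int(np.prod(S))
        dyf = np.ascontiguousarray(dy).reshape(B, self.out_c, n)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=(0, 2))
        if self.kernel == 1:
            x, _ = self._cache
            xf = x.reshape(B, self.in_c, n)
            w2 = self.w.value.reshape(self.out_c, self.in_c)
            dwf = self.w.grad.reshape(self.out_c, self.in_c)
            dx = np.empty_like(xf)
            for b in range(B):
                dwf += dyf[b] @ xf[b].T
                dx[b] = w2.T @ dyf[b]
            return dx.reshape(x.shape)
        xp, S_in = self._cache
        dxp = np.zeros_like(xp)
        for off in self._offsets():
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, S))
            xs = np.ascontiguousarray(xp[sl]).reshape(B, self.in_c, n)
            w2 = self.w.value[(slice(None), slice(None)) + off]
            dw2 = np.zeros_like(w2)
            dxs = np.empty((B, self.in_c, n), np.float32)
            for b in range(B):
                dw2 += dyf[b] @ xs[b].T
                dxs[b] = w2.T @ dyf[b]
            self.w.grad[(slice(None), slice(None)) + off] += dw2
            dxp[sl] += dxs.reshape((B, self.in_c) + S)
        p = self.kernel // 2
        crop = (slice(None), slice(None)) + (slice(p, -p),) * self.ndim
        return dxp[crop]


class BatchNorm(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c, np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(c, np.float32))
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        sh = self._bshape(x)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * invstd.reshape(sh)
        self._cache = (xhat, invstd, axes, train)
        return (self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)
                ).astype(np.float32)

    def backward(self, dy):
        xhat, invstd, axes, train = self._cache
        sh = self._bshape(dy)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value.reshape(sh)
        if not train:
            return (dxhat * invstd.reshape(sh)).astype(np.float32)
        m = dy.size // dy.shape[1]
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (invstd.reshape(sh) / m) * (m * dxhat - t1 - xhat * t2)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


def _block_perm(ndim):
    # (B, C, s0, f0, s1, f1, ...) -> (B, C, s0, s1, ..., f0, f1, ...)
    src = list(range(2 + 2 * ndim))
    return src[:2] + src[2::2] + src[3::2]


class MaxPool(Layer):
    """Non-overlapping max pooling with per-axis integer factors.

    Spatial extents must be divisible by the factors (the network pads its
    input accordingly). Ties within a block route the gradient to the first
    maximal element.
    """

    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(int(f) for f in factors)

    def _to_blocks(self, x):
        B, C = x.shape[:2]
        S = x.shape[2:]
        s_out = tuple(s // f for s, f in zip(S, self.factors))
        shp = (B, C) + tuple(v for s, f in zip(s_out, self.factors) for v in (s, f))
        perm = _block_perm(len(S))
        xb = x.reshape(shp).transpose(perm)
        F = int(np.prod(self.factors))
        return np.ascontiguousarray(xb).reshape((B, C) + s_out + (F,)), s_out, perm, shp

    def forward(self, x, train=False):
        if any(s % f for s, f in zip(x.shape[2:], self.factors)):
            raise ValueError(f"shape {x.shape[2:]} not divisible by pool "
                             f"factors {self.factors}")
        xb, s_out, perm, shp = self._to_blocks(x)
        idx = xb.argmax(axis=-1)
        y = np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, s_out, perm, shp)
        return y

    def backward(self, dy):
        idx, x_shape, s_out, perm, shp = self._cache
        B, C = x_shape[:2]
        F = int(np.prod(self.factors))
        db = np.zeros((B, C) + s_out + (F,), np.float32)
        np.put_along_axis(db, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        db = db.reshape((B, C) + s_out + self.factors)
        inv = np.argsort(_block_perm(len(s_out)))
        return np.ascontiguousarray(db.transpose(inv)).reshape(x_shape)


class TransposedConv(Layer):
    """Strided transposed convolution with kernel == stride (per-axis factors)."""

    def __init__(self, in_c: int, out_c: int, factors: tuple[int, ...],
                 rng: np.random.Generator, name: str = "up"):
        self.in_c, self.out_c = in_c, out_c
        self.factors = tuple(int(f) for f in factors)
        w = rng.normal(0.0, np.sqrt(2.0 / in_c),
                       (in_c, out_c) + self.factors).astype(np.float32)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(out_c, np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        B, C = x.shape[:2]
        S = x.shape[2:]
        ndim = len(S)
        self._x = x
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # (B, *S, O, *f)
        # interleave: (B, O, s0, f0, s1, f1, ...)
        perm = [0, ndim + 1] + [v for i in range(ndim) for v in (1 + i, ndim + 2 + i)]
        t = t.transpose(perm)
        out_S = tuple(s * f for s, f in zip(S, self.factors))
        y = np.ascontiguousarray(t).reshape((B, self.out_c) + out_S)
        return (y + self.b.value.reshape((1, -1) + (1,) * ndim)).astype(np.float32)

    def backward(self, dy):
        x = self._x
        B, C = x.shape[:2]
        S = x.shape[2:]
        ndim = len(S)
        self.b.grad += dy.sum(axis=(0,) + tuple(range(2, dy.ndim)))
        shp = (B, self.out_c) + tuple(v for s, f in zip(S, self.factors) for v in (s, f))
        db = dy.reshape(shp)
        # -> (B, *S, O, *f)
        perm = [0] + [2 + 2 * i for i in range(ndim)] + [1] + [3 + 2 * i for i in range(ndim)]
        db = np.ascontiguousarray(db.transpose(perm))
        ax_of = list(range(1 + ndim, 2 + 2 * ndim))       # O, *f axes in db
        self.w.grad += np.tensordot(x, db, axes=([0] + list(range(2, 2 + ndim)),
                                                 [0] + list(range(1, 1 + ndim))))
        dx = np.tensordot(db, self.w.value, axes=(ax_of, list(range(1, 2 + ndim))))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1)).astype(np.float32)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Global-average-pools each channel, passes the pooled vector through a
    two-layer bottleneck MLP (hidden width ``max(1, C // reduction)``), and
    rescales each channel by the resulting sigmoid gate in (0, 1).
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator,
                 name: str = "se"):
        h = max(1, c // reduction)
        self.c, self.h = c, h
        self.w1 = Param(f"{name}.w1", rng.normal(0, np.sqrt(2.0 / c), (h, c)))
        self.b1 = Param(f"{name}.b1", np.zeros(h, np.float32))
        self.w2 = Param(f"{name}.w2", rng.normal(0, np.sqrt(1.0 / h), (c, h)))
        self.b2 = Param(f"{name}.b2", np.zeros(c, np.float32))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, x, train=False):
        sp_axes = tuple(range(2, x.ndim))
        s = x.mean(axis=sp_axes)                      # (B, C)
        z = s @ self.w1.value.T + self.b1.value
        zr = np.maximum(z, 0.0)
        g = _sigmoid(zr @ self.w2.value.T + self.b2.value)
        sh = (x.shape[0], x.shape[1]) + (1,) * (x.ndim - 2)
        self._cache = (x, s, z > 0, zr, g, sp_axes, sh)
        return (x * g.reshape(sh)).astype(np.float32)

    def backward(self, dy):
        x, s, zmask, zr, g, sp_axes, sh = self._cache
        n_spatial = int(np.prod(x.shape[2:]))
        dg = (dy * x).sum(axis=sp_axes)               # (B, C)
        dx = dy * g.reshape(sh)
        du = dg * g * (1.0 - g)
        self.w2.grad += du.T @ zr
        self.b2.grad += du.sum(axis=0)
        dz = (du @ self.w2.value) * zmask
        self.w1.grad += dz.T @ s
        self.b1.grad += dz.sum(axis=0)
        ds = dz @ self.w1.value                        # (B, C)
        dx += ds.reshape(sh) / n_spatial
        return dx.astype(np.float32)


class Concat(Layer):
    """Channel-axis concatenation of two inputs (skip, upsampled)."""

    def forward2(self, a, b):
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy):
        return dy[:, :self._split], dy[:, self._split:]


class CSRBlock(Layer):
    """Convolution-SE-residual block.

    Two 3x3(x3) convolutions each followed by batch normalisation and ReLU,
    then squeeze-and-excitation channel attention, plus a residual shortcut
    (identity when channel counts match, a 1x1 convolution otherwise):

        y = SE(relu(BN(conv(relu(BN(conv(x))))))) + shortcut(x)
    """

    def __init__(self, in_c: int, out_c: int, ndim: int, rng: np.random.Generator,
                 se_reduction: int = 4, name: str = "csr"):
        self.in_c, self.out_c = in_c, out_c
        self.conv1 = Conv(in_c, out_c, 3, ndim, rng, bias=False, name=f"{name}.conv1")
        self.bn1 = BatchNorm(out_c, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv(out_c, out_c, 3, ndim, rng, bias=False, name=f"{name}.conv2")
        self.bn2 = BatchNorm(out_c, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.se = SEBlock(out_c, se_reduction, rng, name=f"{name}.se")
        self.shortcut = (None if in_c == out_c else
                         Conv(in_c, out_c, 1, ndim, rng, bias=True,
                              name=f"{name}.proj"))

    def params(self):
        ps = (self.conv1.params() + self.bn1.params() + self.conv2.params()
              + self.bn2.params() + self.se.params())
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, train), train))
        h = self.se.forward(h, train)
        sc = x if self.shortcut is None else self.shortcut.forward(x, train)
        return h + sc

    def backward(self, dy):
        dh = self.se.backward(dy)
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        dsc = dy if self.shortcut is None else self.shortcut.backward(dy)
        return dh + dsc
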