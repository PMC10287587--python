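"""Layers with explicit forward/backward passes.

All activations are NCHW ``float32``.  Each layer caches what its backward
pass needs on ``forward`` and accumulates parameter gradients into
``Parameter.grad``; ``backward`` returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter collection and train/eval mode."""

    def parameters(self) -> list[Parameter]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# Convolution


_OFFSETS3 = [(u, v) for u in range(3) for v in range(3)]


def _im2col3_fast(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) patch tensor for a 3x3 same-padding conv.

    Built from 9 shifted block copies of the padded input, so every copy
    moves contiguous rows; the result is matmul-ready without transposes.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    col = np.empty((n, c, 9, h, w), dtype=np.float32)
    for k, (u, v) in enumerate(_OFFSETS3):
        col[:, :, k] = xp[:, :, u:u + h, v:v + w]
    return col.reshape(n, c * 9, h * w)


class Conv2d(Module):
    """3x3 (same padding) or 1x1 convolution with bias, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            wmat = self.weight.data.reshape(self.out_ch, self.in_ch)
            xr = x.reshape(n, c, h * w)
            out = np.matmul(wmat[None], xr)
            out += self.bias.data[None, :, None]
            self._cache = (x, None)
            return out.reshape(n, self.out_ch, h, w)
        col = _im2col3_fast(x)  # (N, C*9, H*W)
        wmat = self.weight.data.reshape(self.out_ch, -1)  # (O, C*9)
        out = np.matmul(wmat[None], col)  # (N, O, H*W)
        out += self.bias.data[None, :, None]
        self._cache = (x, col)
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, col = self._cache
        n, c, h, w = x.shape
        dmat = dout.reshape(n, self.out_ch, h * w)
        if self.kernel == 1:
            xr = x.reshape(n, c, h * w)
            self.weight.grad += np.einsum(
                "nox,ncx->oc", dmat, xr, optimize=True
            ).reshape(self.weight.data.shape)
            self.bias.grad += dmat.sum(axis=(0, 2))
            wmat = self.weight.data.reshape(self.out_ch, self.in_ch)
            dx = np.matmul(wmat.T[None], dmat)
            return dx.reshape(n, c, h, w)
        self.weight.grad += np.einsum(
            "nox,ncx->oc", dmat, col, optimize=True
        ).reshape(self.weight.data.shape)
        self.bias.grad += dmat.sum(axis=(0, 2))
        # dx = "full" correlation of dout with the flipped kernel, which for a
        # same-padded 3x3 conv is again a same-padded 3x3 conv with the
        # spatially flipped, channel-transposed weights.
        wflip = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,3,3)
        colg = _im2col3_fast(dout)  # (N, O*9, H*W)
        dx = np.matmul(np.ascontiguousarray(wflip).reshape(self.in_ch, -1)[None], colg)
        return dx.reshape(n, c, h, w)

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics (momentum 0.9)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat
        out += self.beta.data[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += np.sum(dout * xhat, axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if not train:
            return (dout * g).astype(np.float32)
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * self.gamma.data[None, :, None, None]
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (term * inv_std[None, :, None, None]).astype(np.float32)

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MaxPool2x2(Module):
    """2x2 max-pool, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        hits = blocks == out[:, :, :, None, :, None]
        # break ties: route the gradient to the first maximal element only
        flat = np.ascontiguousarray(hits.transpose(0, 1, 2, 4, 3, 5)
                                    ).reshape(n, c, h // 2, w // 2, 4)
        first = np.argmax(flat, axis=-1)
        one_hot = np.arange(4)[None, None, None, None, :] == first[..., None]
        self._argmask = np.ascontiguousarray(
            one_hot.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5))
        self._in_shape = (n, c, h, w)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dx = self._argmask * dout[:, :, :, None, :, None]
        return np.ascontiguousarray(dx.reshape(n, c, h, w).astype(np.float32))


class ConvTranspose2x2(Module):
    """2x2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.einsum("nchw,couv->nohuwv", x, self.weight.data, optimize=True)
        out = out.reshape(n, self.out_ch, 2 * h, 2 * w)
        out += self.bias.data[None, :, None, None]
        self._cache = x
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        blocks = dout.reshape(n, self.out_ch, h, 2, w, 2)
        self.weight.grad += np.einsum("nchw,nohuwv->couv", x, blocks, optimize=True)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("nohuwv,couv->nchw", blocks, self.weight.data, optimize=True)
        return np.ascontiguousarray(dx.astype(np.float32))

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size


# ---------------------------------------------------------------------------
# Bilinear 2x upsampling (fixed linear operator and its exact adjoint)


def _up2_matrix(n: int) -> np.ndarray:
    """(2n x n) bilinear interpolation matrix, half-pixel-center convention."""
    mat = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        s = (o + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(s))
        frac = s - i0
        i0c = min(max(i0, 0), n - 1)
        i1c = min(max(i0 + 1, 0), n - 1)
        mat[o, i0c] += 1.0 - frac
        mat[o, i1c] += frac
    return mat


_UP2_CACHE: dict = {}


def _up2(n: int) -> np.ndarray:
    if n not in _UP2_CACHE:
        _UP2_CACHE[n] = _up2_matrix(n)
    return _UP2_CACHE[n]


def bilinear_up2(x: np.ndarray) -> np.ndarray:
    """Bilinear 2x spatial upsampling of an NCHW tensor."""
    h, w = x.shape[2], x.shape[3]
    out = np.einsum("Hh,nchw,Ww->ncHW", _up2(h), x, _up2(w), optimize=True)
    return np.ascontiguousarray(out.astype(np.float32))


def bilinear_up2_adjoint(dout: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`bilinear_up2` (for backprop)."""
    h2, w2 = dout.shape[2], dout.shape[3]
    uh, uw = _up2(h2 // 2), _up2(w2 // 2)
    dx = np.einsum("Hh,ncHW,Ww->nchw", uh, dout, uw, optimize=True)
    return np.ascontiguousarray(dx.astype(np.float32))


# ---------------------------------------------------------------------------
# Attention gate


class AttentionGate(Module):
    """Additive attention over a skip connection.

    The skip features ``x`` (at the skip resolution) and the coarser-level
    gating signal ``g`` (half resolution) are projected by 1x1 convolutions
    to an intermediate dimension; the projected gate is bilinearly upsampled
    to the skip resolution, the sum passes ReLU, a 1x1 convolution to one
    channel and a sigmoid, producing per-pixel coefficients in [0, 1] that
    multiply the skip features.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator,
                 inter_ch: int | None = None):
        self.inter_ch = inter_ch or max(1, skip_ch)
        self.theta_x = Conv2d(skip_ch, self.inter_ch, 1, rng)
        self.phi_g = Conv2d(gate_ch, self.inter_ch, 1, rng)
        self.psi = Conv2d(self.inter_ch, 1, 1, rng)
        self._cache = None

    def forward(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        tx = self.theta_x.forward(x)
        pg_coarse = self.phi_g.forward(g)
        pg = bilinear_up2(pg_coarse)
        pre = tx + pg
        act = np.maximum(pre, 0.0)
        logits = self.psi.forward(act)
        alpha = sigmoid(logits)  # (N,1,H,W)
        self._cache = (x, pre > 0, alpha)
        return (x * alpha).astype(np.float32)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, act_mask, alpha = self._cache
        dalpha = (dout * x).sum(axis=1, keepdims=True)
        dx_direct = dout * alpha
        dlogits = dalpha * alpha * (1.0 - alpha)
        dact = self.psi.backward(dlogits.astype(np.float32))
        dpre = np.where(act_mask, dact, 0.0).astype(np.float32)
        dtx = self.theta_x.backward(dpre)
        dg = self.phi_g.backward(bilinear_up2_adjoint(dpre))
        return (dx_direct + dtx).astype(np.float32), dg

    @property
    def n_params(self) -> int:
        return self.theta_x.n_params + self.phi_g.n_params + self.psi.n_params
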