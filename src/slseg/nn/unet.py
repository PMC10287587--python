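"""U-Net and attention U-Net assembled from the engine layers.

The encoder has ``levels`` double-convolution blocks (3x3 conv + batch norm
+ ReLU, twice) with 2x2 max-pooling between them and feature counts doubling
per level from ``root_features``.  The decoder mirrors it with 2x2 stride-2
transposed-convolution upsampling, skip concatenation (optionally through an
additive attention gate) and double convolutions; a final 1x1 convolution
with sigmoid yields a per-pixel tumor probability.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AttentionGate,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    MaxPool2x2,
    Module,
    ReLU,
    sigmoid,
)


class DoubleConv(Module):
    """(conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()

    def forward(self, x, train: bool):
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(x), train))

    def backward(self, dout):
        d = self.bn2.backward(self.relu2.backward(dout))
        d = self.conv2.backward(d)
        d = self.bn1.backward(self.relu1.backward(d))
        return self.conv1.backward(d)

    @property
    def n_params(self) -> int:
        return (self.conv1.n_params + self.bn1.n_params
                + self.conv2.n_params + self.bn2.n_params)


class UNet2D(Module):
    """Slice-wise segmentation network producing probabilities in (0, 1)."""

    def __init__(self, levels: int, root_features: int, in_channels: int = 1,
                 out_channels: int = 1, attention: bool = False, seed: int = 0):
        if levels < 1 or root_features < 1:
            raise ValueError("levels and root_features must be >= 1")
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.attention = attention
        feats = [root_features * 2 ** i for i in range(levels)]
        self.enc = [DoubleConv(in_channels if i == 0 else feats[i - 1], feats[i], rng)
                    for i in range(levels)]
        self.pools = [MaxPool2x2() for _ in range(levels - 1)]
        self.ups = [ConvTranspose2x2(feats[i + 1], feats[i], rng)
                    for i in range(levels - 1)]
        self.dec = [DoubleConv(2 * feats[i], feats[i], rng)
                    for i in range(levels - 1)]
        self.gates = ([AttentionGate(feats[i], feats[i + 1], rng)
                       for i in range(levels - 1)] if attention else [])
        self.final = Conv2d(feats[0], out_channels, 1, rng)
        self._cache = None

    # -- plumbing ----------------------------------------------------------

    def check_input(self, h: int, w: int) -> None:
        div = 2 ** (self.levels - 1)
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^(levels-1) = {div}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, C, H, W) -> probabilities (N, out, H, W)."""
        self.check_input(x.shape[2], x.shape[3])
        skips = []
        h = x.astype(np.float32)
        for i in range(self.levels):
            h = self.enc[i].forward(h, train)
            if i < self.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        gate_alphas = []
        for i in reversed(range(self.levels - 1)):
            g = h  # coarser-level features gate the skip
            up = self.ups[i].forward(h)
            skip = skips[i]
            if self.attention:
                skip = self.gates[i].forward(skip, g)
            h = self.dec[i].forward(np.concatenate([skip, up], axis=1), train)
        logits = self.final.forward(h)
        p = sigmoid(logits)
        self._cache = p
        return p

    def backward(self, dprob: np.ndarray) -> None:
        """Backprop from d(loss)/d(probability); accumulates parameter grads."""
        p = self._cache
        d = (dprob * p * (1.0 - p)).astype(np.float32)
        d = self.final.backward(d)
        dskips = [None] * (self.levels - 1)
        for i in range(self.levels - 1):
            d = self.dec[i].backward(d)
            feats_i = self.ups[i].out_ch
            dskip, dup = d[:, :feats_i], d[:, feats_i:]
            dg_extra = None
            if self.attention:
                dskip, dg_extra = self.gates[i].backward(
                    np.ascontiguousarray(dskip))
            dskips[i] = np.ascontiguousarray(dskip)
            d = self.ups[i].backward(np.ascontiguousarray(dup))
            if dg_extra is not None:
                d = d + dg_extra
        # d now holds the gradient at the bottleneck input
        for i in reversed(range(self.levels)):
            if i < self.levels - 1:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)

    # -- introspection -----------------------------------------------------

    def attention_coefficients(self, x: np.ndarray) -> list[np.ndarray]:
        """Run a forward pass and return each gate's alpha map (eval mode)."""
        if not self.attention:
            return []
        self.forward(x, train=False)
        return [g._cache[2] for g in self.gates]

    def n_params(self) -> int:
        """Total trainable scalars, by enumerating the parameter arrays."""
        return sum(p.size for p in self.parameters())

    def get_state(self) -> dict:
        """Serializable parameter + running-statistic state."""
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.data
        j = 0
        for m in self._batchnorms():
            arrays[f"bn_mean_{j}"] = m.running_mean
            arrays[f"bn_var_{j}"] = m.running_var
            j += 1
        return arrays

    def set_state(self, arrays: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.ascontiguousarray(arrays[f"param_{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.data)
        j = 0
        for m in self._batchnorms():
            m.running_mean = np.ascontiguousarray(arrays[f"bn_mean_{j}"], dtype=np.float32)
            m.running_var = np.ascontiguousarray(arrays[f"bn_var_{j}"], dtype=np.float32)
            j += 1

    def _batchnorms(self):
        for block in [*self.enc, *self.dec]:
            yield block.bn1
            yield block.bn2
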