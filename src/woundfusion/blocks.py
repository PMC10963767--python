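"""Custom computational blocks of the fusion classifier.

* :class:`ConvBlock` — convolution + ReLU.
* :class:`ChannelSE` (cSE) — channel squeeze-and-excitation: global
  average pool, bottleneck MLP (reduction ratio r), sigmoid gates that
  rescale each channel.
* :class:`SpatialSE` (sSE) — spatial squeeze-and-excitation: a 1x1
  C->1 projection, sigmoid gates that rescale each spatial position.
* :class:`ParallelSCSE` (P_scSE) — runs both and merges their outputs;
  the default merge combines max-out and addition:
  ``max(a, b) + (a + b)``. ``max`` and ``add`` merges are selectable.
* :class:`AxialAttention` — scaled dot-product self-attention restricted
  to one axis at a time, applied independently along every slice of the
  other axes, with a residual connection.
* :class:`VectorAxialAttention` — gives a flat feature vector axes by
  reshaping it into the nearest padded square grid, attending along rows
  then columns, and flattening back.
* :class:`AdaptiveGatedMLP` — the location branch: a hidden expansion is
  split in two; one half, passed through axial attention, drives a
  sigmoid gate that multiplicatively filters the other half before the
  output projection. A closed gate (g -> 0) blocks the location signal
  entirely.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, matmul, maximum, softmax
from .nn import Conv2d, Linear, Module

__all__ = [
    "ConvBlock",
    "ChannelSE",
    "SpatialSE",
    "ParallelSCSE",
    "AxialAttention",
    "VectorAxialAttention",
    "AdaptiveGatedMLP",
]


class ConvBlock(Module):
    """Convolution (same padding) followed by ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3, gain: float = 1.0):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng, padding="same", gain=gain)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


def _reduced(channels: int, r: int) -> int:
    """Bottleneck width C/r, rounded up so it never collapses to zero."""
    return max(1, int(np.ceil(channels / r)))


class ChannelSE(Module):
    """Channel squeeze-and-excitation with reduction ratio ``r``."""

    def __init__(self, channels: int, rng: np.random.Generator, r: int = 16):
        super().__init__()
        self.channels = channels
        hidden = _reduced(channels, r)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"cSE expected {self.channels} channels, got {x.shape[1]}")
        z = x.mean(axis=(2, 3))                      # (B, C) squeeze
        s = self.fc2(self.fc1(z).relu()).sigmoid()   # (B, C) excitation
        return x * s.reshape(s.shape[0], s.shape[1], 1, 1)


class SpatialSE(Module):
    """Spatial squeeze-and-excitation: 1x1 C->1 projection, sigmoid gate."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.proj = Conv2d(channels, 1, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"sSE expected {self.channels} channels, got {x.shape[1]}")
        q = self.proj(x).sigmoid()                   # (B, 1, H, W)
        return x * q


class ParallelSCSE(Module):
    """cSE and sSE in parallel, merged by max-out and addition.

    merge="maxout_add" (default): max(a,b) + (a+b); "max" and "add" are
    the single-operation alternatives.
    """

    MERGES = ("maxout_add", "max", "add")

    def __init__(self, channels: int, rng: np.random.Generator, r: int = 16, merge: str = "maxout_add"):
        super().__init__()
        if merge not in self.MERGES:
            raise ValueError(f"merge must be one of {self.MERGES}, got {merge!r}")
        self.cse = ChannelSE(channels, rng, r=r)
        self.sse = SpatialSE(channels, rng)
        self.merge = merge

    def forward(self, x: Tensor) -> Tensor:
        a = self.cse(x)
        b = self.sse(x)
        if self.merge == "max":
            return maximum(a, b)
        if self.merge == "add":
            return a + b
        return maximum(a, b) + (a + b)


class AxialAttention(Module):
    """Single-head self-attention along one axis of a token array or map.

    For token input (B, L, F) the attended axis is the token axis; for
    feature maps (B, C, H, W) pass ``axis`` "height" or "width" and the
    attention runs independently along every slice of the other spatial
    axis, with channels as features. A residual connection adds the
    input, so the block is shape-preserving.
    """

    def __init__(self, features: int, rng: np.random.Generator, head_dim: int | None = None):
        super().__init__()
        self.features = features
        self.head_dim = head_dim or features
        self.wq = Linear(features, self.head_dim, rng)
        self.wk = Linear(features, self.head_dim, rng)
        # small-gain values: the residual dominates at init, growth stays bounded
        self.wv = Linear(features, features, rng, gain=0.5)

    def _attend(self, x: Tensor) -> Tensor:
        # x: (..., L, F); softmax over keys (second-to-last axis of scores' last dim)
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = matmul(q, k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2))
        scores = scores * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        return matmul(attn, v) + x

    def forward(self, x: Tensor, axis: str = "sequence") -> Tensor:
        if x.ndim == 3:
            if axis != "sequence":
                raise ValueError(f"token input attends over axis='sequence', got {axis!r}")
            return self._attend(x)
        if x.ndim == 4:
            B, C, H, W = x.shape
            if axis == "width":
                t = x.transpose(0, 2, 3, 1).reshape(B * H, W, C)
                out = self._attend(t)
                return out.reshape(B, H, W, C).transpose(0, 3, 1, 2)
            if axis == "height":
                t = x.transpose(0, 3, 2, 1).reshape(B * W, H, C)
                out = self._attend(t)
                return out.reshape(B, W, H, C).transpose(0, 3, 2, 1)
            raise ValueError(f"feature-map input needs axis 'height' or 'width', got {axis!r}")
        raise ValueError(f"expected 3-D tokens or 4-D feature map, got ndim={x.ndim}")


class VectorAxialAttention(Module):
    """Axial attention for a flat feature vector.

    The F-length vector is zero-padded to the nearest square g*g,
    reshaped to a (g, g) grid, attended along rows then columns (each
    row/column is a token of g features), and flattened back to length F.
    This realizes "one dimension at a time" attention on dense features.
    """

    def __init__(self, features: int, rng: np.random.Generator):
        super().__init__()
        self.features = features
        self.grid = int(np.ceil(np.sqrt(features)))
        self.row_attn = AxialAttention(self.grid, rng)
        self.col_attn = AxialAttention(self.grid, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.features:
            raise ValueError(f"expected {self.features} features, got {x.shape[-1]}")
        B = x.shape[0]
        g = self.grid
        pad = g * g - self.features
        if pad:
            x = concatenate([x, Tensor(np.zeros((B, pad)))], axis=1)
        grid = x.reshape(B, g, g)
        grid = self.row_attn(grid)                       # rows as tokens
        grid = self.col_attn(grid.transpose(0, 2, 1)).transpose(0, 2, 1)
        flat = grid.reshape(B, g * g)
        return flat[:, : self.features]


class AdaptiveGatedMLP(Module):
    """Gated MLP for the one-hot body-map location vector.

    u = ReLU(W_in · loc); split u -> (u1, u2); g = sigmoid(W_g · axial(u2));
    out = W_out · (u1 ⊙ g). The learned gate selectively propagates
    location information — driven closed it zeroes the branch.
    """

    def __init__(self, location_dim: int, rng: np.random.Generator,
                 hidden: int = 64, out_features: int = 32):
        super().__init__()
        if hidden % 2:
            raise ValueError("hidden width must be even (it is split in half)")
        self.location_dim = location_dim
        self.half = hidden // 2
        self.w_in = Linear(location_dim, hidden, rng)
        self.attn = VectorAxialAttention(self.half, rng)
        self.w_gate = Linear(self.half, self.half, rng)
        self.w_out = Linear(self.half, out_features, rng)
        self.out_features = out_features

    def forward(self, loc: Tensor) -> Tensor:
        if loc.shape[-1] != self.location_dim:
            raise ValueError(f"expected location vectors of length {self.location_dim}, got {loc.shape[-1]}")
        u = self.w_in(loc).relu()
        u1 = u[:, : self.half]
        u2 = u[:, self.half :]
        g = self.w_gate(self.attn(u2)).sigmoid()
        return self.w_out(u1 * g)

    def force_gate(self, value: float) -> None:
        """Saturate the gate (diagnostic): large +/- bias opens/closes it."""
        self.w_gate.weight.data[:] = 0.0
        self.w_gate.bias.data[:] = value
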