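"""Independent brute-force reference implementations.

Everything here is plain numpy with explicit loops — no autodiff, no
shared code with the package's forward passes — so block outputs can be
checked against an implementation that cannot share their bugs.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def conv2d_naive(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, padding: int = 0):
    """Quadruple-loop 2-D cross-correlation. x: (B,C,H,W), w: (O,C,kh,kw)."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((B, O, Ho, Wo))
    for n in range(B):
        for o in range(O):
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[n, :, i * stride : i * stride + kh, j * stride : j * stride + kw]
                    out[n, o, i, j] = (patch * w[o]).sum() + b[o]
    return out


def cse_naive(x: np.ndarray, w1, b1, w2, b2):
    """Channel squeeze-excitation by explicit loops. w1: (C,hidden), w2: (hidden,C)."""
    B, C, H, W = x.shape
    out = np.zeros_like(x)
    for n in range(B):
        z = np.array([x[n, c].mean() for c in range(C)])
        s = sigmoid(np.maximum(z @ w1 + b1, 0.0) @ w2 + b2)
        for c in range(C):
            out[n, c] = s[c] * x[n, c]
    return out


def sse_naive(x: np.ndarray, w, b):
    """Spatial squeeze-excitation. w: (1,C,1,1) 1x1 projection, b: (1,)."""
    B, C, H, W = x.shape
    out = np.zeros_like(x)
    for n in range(B):
        for i in range(H):
            for j in range(W):
                q = sigmoid((x[n, :, i, j] * w[0, :, 0, 0]).sum() + b[0])
                out[n, :, i, j] = q * x[n, :, i, j]
    return out


def pscse_naive(x, cse_params, sse_params, merge="maxout_add"):
    a = cse_naive(x, *cse_params)
    b = sse_naive(x, *sse_params)
    if merge == "max":
        return np.maximum(a, b)
    if merge == "add":
        return a + b
    return np.maximum(a, b) + (a + b)


def attention_naive(tokens: np.ndarray, wq, bq, wk, bk, wv, bv, head_dim: int):
    """Full scaled dot-product self-attention + residual over (L, F) tokens."""
    q = tokens @ wq + bq
    k = tokens @ wk + bk
    v = tokens @ wv + bv
    scores = q @ k.T / np.sqrt(head_dim)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=1, keepdims=True)
    return attn @ v + tokens


def _attn_params(mod):
    return (
        mod.wq.weight.data, mod.wq.bias.data,
        mod.wk.weight.data, mod.wk.bias.data,
        mod.wv.weight.data, mod.wv.bias.data,
        mod.head_dim,
    )


def vector_axial_naive(vec: np.ndarray, attn_module) -> np.ndarray:
    """Reference for VectorAxialAttention on a single feature vector."""
    F = attn_module.features
    g = attn_module.grid
    padded = np.zeros(g * g)
    padded[:F] = vec
    grid = padded.reshape(g, g)
    grid = attention_naive(grid, *_attn_params(attn_module.row_attn))
    grid = attention_naive(grid.T, *_attn_params(attn_module.col_attn)).T
    return grid.reshape(-1)[:F]


def gated_mlp_naive(loc: np.ndarray, mod) -> np.ndarray:
    """Step-by-step reference for AdaptiveGatedMLP on one location vector."""
    u = np.maximum(loc @ mod.w_in.weight.data + mod.w_in.bias.data, 0.0)
    u1, u2 = u[: mod.half], u[mod.half :]
    a = vector_axial_naive(u2, mod.attn)
    g = sigmoid(a @ mod.w_gate.weight.data + mod.w_gate.bias.data)
    return (u1 * g) @ mod.w_out.weight.data + mod.w_out.bias.data


def finite_difference_grad(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + h
        fp = f(x)
        x[idx] = orig - h
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
        it.iternext()
    return g
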