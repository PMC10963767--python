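"""Gradient-weighted class-activation maps on the backbone branches.

For a chosen class logit and a branch's last convolutional layer, the
channel weights are the spatial means of the logit's gradient with
respect to that layer's activations; the heatmap is the ReLU of the
channel-weighted activation sum, max-normalized to [0, 1]. Overlays
upsample the map bilinearly and alpha-blend it with the input image
under a fixed colormap ("jet"), so figures are reproducible bytewise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .autodiff import Tensor
from .network import FusionNetwork

__all__ = ["CamMap", "gradcam", "overlay"]


@dataclass
class CamMap:
    heatmap: np.ndarray  # (h, w), in [0, 1]
    target_class: int
    layer_id: str


def gradcam(
    net: FusionNetwork,
    image: np.ndarray,
    target_class: int,
    layer_id: str,
    location: np.ndarray | None = None,
) -> CamMap:
    """Class-activation map for one image at one branch layer.

    ``image`` is a single CHW array (already resized/normalized);
    ``layer_id`` must be one of ``net.branch_layer_ids()``.
    """
    if target_class >= net.config.num_classes:
        raise ValueError(f"target_class {target_class} >= K={net.config.num_classes}")
    ids = net.branch_layer_ids()
    if layer_id not in ids:
        raise KeyError(f"unknown layer {layer_id!r}; eligible layers: {ids}")
    net.eval()
    net.zero_grad()
    # input requires grad so activations collect gradients even on frozen nets
    x = Tensor(np.asarray(image)[None], requires_grad=True)
    loc = None
    if net.config.use_location:
        if location is None:
            raise ValueError("this network needs a location vector for the forward pass")
        loc = Tensor(np.asarray(location)[None])
    logits = net(x, loc)
    act = net.branch_activation(layer_id)
    logits.backward(_one_hot_grad(logits.shape, target_class))
    if act.grad is None:
        raise RuntimeError("no gradient reached the requested layer")
    weights = act.grad[0].mean(axis=(1, 2))  # (C,) spatial mean of d logit / d activation
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CamMap(heatmap=cam, target_class=target_class, layer_id=layer_id)


def _one_hot_grad(shape: tuple, target: int) -> np.ndarray:
    g = np.zeros(shape)
    g[0, target] = 1.0
    return g


def overlay(image: np.ndarray, cam: CamMap, out_path: str | Path, alpha: float = 0.45) -> Path:
    """Blend a heatmap over an HWC [0,1] image and write a PNG."""
    from matplotlib import colormaps

    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    heat = np.asarray(
        Image.fromarray((cam.heatmap * 255).astype(np.uint8)).resize((w, h), Image.BILINEAR),
        dtype=float,
    ) / 255.0
    colored = colormaps["jet"](heat)[..., :3]
    # zero heat leaves the base image untouched
    mix = image * (1.0 - alpha * heat[..., None]) + colored * (alpha * heat[..., None])
    out_path = Path(out_path)
    Image.fromarray((np.clip(mix, 0, 1) * 255).astype(np.uint8)).save(out_path)
    return out_path
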