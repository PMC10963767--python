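"""The multi-modal fusion classifier.

Three convolutional backbones run in parallel on the input image; their
feature maps are pooled to a common grid, concatenated along channels,
and passed through repeated ConvBlock -> P_scSE -> dropout stages. The
result is flattened into a dense layer feeding a head of two dense
layers interleaved with axial attention, ReLU and dropout. When the
location branch is enabled, the adaptive-gated MLP embedding of the
one-hot body-map vector is concatenated with the head features before
the final dense layers; the last dense layer maps to K class logits.

Backbones are registered by name with a versioned truncation recipe.
The registry ships three desk-scale architecture families — each ends at
a mid-depth feature map, i.e. already "truncated" below any classifier
head:

* ``tiny_a`` (recipe v1) — plain stacked 3x3 convolutions (VGG family).
* ``tiny_b`` (recipe v1) — a residual bottleneck stage (ResNet family).
* ``tiny_c`` (recipe v1) — depthwise-separable convolutions
  (EfficientNet family).

Pretrained ImageNet weights are not bundled, so ``pretrained=True``
raises; every build is reproducible from its seed. The per-recipe
Grad-CAM target (the last convolutional layer of the branch) is pinned
in the same table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, adaptive_avg_pool2d, concatenate
from .blocks import AdaptiveGatedMLP, ConvBlock, ParallelSCSE, VectorAxialAttention
from .nn import Conv2d, Dropout, Linear, Module

__all__ = [
    "NetworkConfig",
    "FusionNetwork",
    "build_backbone",
    "build_network",
    "count_parameters",
    "describe",
    "save_checkpoint",
    "load_checkpoint",
    "BACKBONE_RECIPES",
]


class BackboneError(ValueError):
    pass


class _TinyPlain(Module):
    """VGG-family: two stride-2 conv+ReLU stages, 3 -> 8 -> 16 channels."""

    out_channels = 16

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 8, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(8, 16, 3, rng, stride=2, padding=1)
        self.last_activation: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        self.last_activation = h
        return h


class _TinyResidual(Module):
    """ResNet-family: stride-2 stem, one residual 3x3/3x3 block, stride-2 exit."""

    out_channels = 16

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = Conv2d(3, 12, 3, rng, stride=2, padding=1)
        self.res1 = Conv2d(12, 12, 3, rng, padding="same")
        self.res2 = Conv2d(12, 12, 3, rng, padding="same")
        self.exit = Conv2d(12, 16, 3, rng, stride=2, padding=1)
        self.last_activation: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        r = self.res2(self.res1(h).relu())
        h = (h + r).relu()
        h = self.exit(h).relu()
        self.last_activation = h
        return h


class _TinySeparable(Module):
    """EfficientNet-family: depthwise 3x3 + pointwise 1x1 stages."""

    out_channels = 16

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = Conv2d(3, 8, 3, rng, stride=2, padding=1)
        self.dw = Conv2d(8, 8, 3, rng, stride=2, padding=1, groups=8)
        self.pw = Conv2d(8, 16, 1, rng, padding=0)
        self.last_activation: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        h = self.dw(h).relu()
        h = self.pw(h).relu()
        self.last_activation = h
        return h


#: name -> {recipe_id -> (factory, description)}
BACKBONE_RECIPES: dict[str, dict[str, tuple]] = {
    "tiny_a": {"v1": (_TinyPlain, "plain 3x3 conv stack (VGG family), cut at the second conv")},
    "tiny_b": {"v1": (_TinyResidual, "residual stage (ResNet family), cut after the exit conv")},
    "tiny_c": {"v1": (_TinySeparable, "depthwise-separable stack (EfficientNet family), cut after the pointwise conv")},
}

_UNAVAILABLE = {
    "resnet152": "remove avg-pool/FC, last two layers of stage-2 block 3, final four layers",
    "vgg16": "drop the last twelve layers",
    "efficientnet_b2": "drop the final layer",
}


def build_backbone(name: str, truncation: str = "v1", pretrained: bool = False,
                   rng: np.random.Generator | None = None) -> Module:
    """Build a named backbone feature extractor from its truncation recipe."""
    if name in _UNAVAILABLE:
        raise BackboneError(
            f"backbone {name!r} (truncation: {_UNAVAILABLE[name]}) requires pretrained "
            f"ImageNet weights, which are not bundled with this package; available "
            f"desk-scale recipes: {_recipe_list()}"
        )
    if name not in BACKBONE_RECIPES:
        raise BackboneError(f"unknown backbone {name!r}; available recipes: {_recipe_list()}")
    if truncation not in BACKBONE_RECIPES[name]:
        raise BackboneError(
            f"unknown truncation recipe {truncation!r} for {name}; available: {_recipe_list()}"
        )
    if pretrained:
        raise BackboneError(f"no pretrained weights are bundled for {name!r}; use pretrained=False")
    factory, _ = BACKBONE_RECIPES[name][truncation]
    return factory(rng if rng is not None else np.random.default_rng(0))


def _recipe_list() -> list[str]:
    return [f"{n}:{r}" for n, recs in BACKBONE_RECIPES.items() for r in recs]


@dataclass
class NetworkConfig:
    backbones: tuple[str, ...] = ("tiny_a", "tiny_b", "tiny_c")
    truncation: str = "v1"
    num_classes: int = 6
    class_names: tuple[str, ...] | None = None
    image_size: int = 32
    use_location: bool = False
    location_dim: int = 484
    fusion_channels: int = 16
    agg_repeats: int = 2
    head_widths: tuple[int, int] = (64, 32)
    dropout: float = 0.3
    # canonical SE reduction is 16, sized for hundreds of channels; at the
    # desk-scale default of 16 fusion channels that collapses the excitation
    # bottleneck to one unit, so the default here keeps it a few units wide
    se_reduction: int = 4
    scse_merge: str = "maxout_add"
    loc_hidden: int = 64
    loc_out: int = 32

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        self.backbones = tuple(self.backbones)
        self.head_widths = tuple(self.head_widths)
        if self.class_names is not None:
            self.class_names = tuple(self.class_names)
            if len(self.class_names) != self.num_classes:
                raise ValueError("class_names length must equal num_classes")


class FusionNetwork(Module):
    """The assembled three-branch classifier (see module docstring)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.branches = [build_backbone(n, config.truncation, False, rng) for n in config.backbones]

        concat_channels = sum(b.out_channels for b in self.branches)
        self.agg: list[Module] = []
        c_in = concat_channels
        for i in range(config.agg_repeats):
            # half-gain convs offset the ~2x amplification of the scSE merge
            self.agg.append(ConvBlock(c_in, config.fusion_channels, rng, gain=0.5))
            self.agg.append(ParallelSCSE(config.fusion_channels, rng,
                                         r=config.se_reduction, merge=config.scse_merge))
            self.agg.append(Dropout(config.dropout, seed=int(rng.integers(2**31))))
            c_in = config.fusion_channels

        flat_dim = self._probe_flat_dim()
        w0, w1 = config.head_widths
        self.fc_in = Linear(flat_dim, w0, rng)
        self.head_attn1 = VectorAxialAttention(w0, rng)
        self.head_fc1 = Linear(w0, w0, rng)
        self.head_drop1 = Dropout(config.dropout, seed=int(rng.integers(2**31)))
        self.head_attn2 = VectorAxialAttention(w0, rng)
        self.head_fc2 = Linear(w0, w1, rng)
        self.head_drop2 = Dropout(config.dropout, seed=int(rng.integers(2**31)))

        if config.use_location:
            self.loc_branch = AdaptiveGatedMLP(config.location_dim, rng,
                                               hidden=config.loc_hidden, out_features=config.loc_out)
            penult_in = w1 + config.loc_out
        else:
            self.loc_branch = None
            penult_in = w1
        self.fc_penult = Linear(penult_in, w1, rng)
        # small-gain output layer: near-uniform initial class probabilities
        self.fc_out = Linear(w1, config.num_classes, rng, gain=0.1)

    # -- internals --------------------------------------------------------
    def _probe_flat_dim(self) -> int:
        s = self.config.image_size
        probe = Tensor(np.zeros((1, 3, s, s)))
        maps = [b(probe) for b in self.branches]
        gh = min(m.shape[2] for m in maps)
        gw = min(m.shape[3] for m in maps)
        self._grid = (gh, gw)
        return self.config.fusion_channels * gh * gw

    def _image_path(self, image: Tensor) -> Tensor:
        maps = [b(image) for b in self.branches]
        gh, gw = self._grid
        pooled = [adaptive_avg_pool2d(m, (gh, gw)) for m in maps]
        h = concatenate(pooled, axis=1)
        for layer in self.agg:
            h = layer(h)
        B = h.shape[0]
        h = h.reshape(B, int(np.prod(h.shape[1:])))
        h = self.fc_in(h).relu()
        h = self.head_drop1(self.head_fc1(self.head_attn1(h)).relu())
        h = self.head_drop2(self.head_fc2(self.head_attn2(h)).relu())
        return h

    def forward(self, image: Tensor | np.ndarray, location: Tensor | np.ndarray | None = None) -> Tensor:
        image = image if isinstance(image, Tensor) else Tensor(image)
        if image.ndim != 4 or image.shape[1] != 3:
            raise ValueError(f"expected image batch (B, 3, H, W), got {image.shape}")
        if self.config.use_location and location is None:
            raise ValueError("this network was built with use_location=True; pass a location batch")
        if not self.config.use_location and location is not None:
            raise ValueError("this network was built without a location branch")
        h = self._image_path(image)
        if self.config.use_location:
            loc = location if isinstance(location, Tensor) else Tensor(location)
            h = concatenate([h, self.loc_branch(loc)], axis=1)
        h = self.fc_penult(h).relu()
        return self.fc_out(h)

    # -- Grad-CAM plumbing -------------------------------------------------
    def branch_layer_ids(self) -> list[str]:
        return [f"{name}.last_conv" for name in self.config.backbones]

    def branch_activation(self, layer_id: str) -> Tensor:
        ids = self.branch_layer_ids()
        if layer_id not in ids:
            raise KeyError(f"unknown layer {layer_id!r}; eligible layers: {ids}")
        branch = self.branches[ids.index(layer_id)]
        if branch.last_activation is None:
            raise RuntimeError("run a forward pass before requesting activations")
        return branch.last_activation


def build_network(config: NetworkConfig, seed: int = 0) -> FusionNetwork:
    return FusionNetwork(config, seed=seed)


def count_parameters(net: FusionNetwork) -> int:
    return int(sum(p.size for p in net.parameters()))


def describe(net: FusionNetwork) -> str:
    """Deterministic architecture summary with probe output shapes."""
    cfg = net.config
    s = cfg.image_size
    probe = Tensor(np.zeros((1, 3, s, s)))
    lines = [f"FusionNetwork: {len(net.branches)} backbone branches, K={cfg.num_classes}"]
    for name, b in zip(cfg.backbones, net.branches):
        out = b(probe)
        lines.append(f"  branch {name}:{cfg.truncation} -> {out.shape}")
    lines.append(f"  common grid: {net._grid}, fusion channels: {cfg.fusion_channels}")
    lines.append(f"  aggregation: {cfg.agg_repeats} x (ConvBlock -> P_scSE[{cfg.scse_merge}] -> Dropout)")
    lines.append(f"  head widths: {cfg.head_widths} with axial attention")
    if cfg.use_location:
        lines.append(f"  location branch: one-hot {cfg.location_dim} -> gated MLP -> {cfg.loc_out}")
    lines.append(f"  parameters: {count_parameters(net)}")
    return "\n".join(lines)


def save_checkpoint(net: FusionNetwork, path: str | Path) -> None:
    path = Path(path)
    state = net.state_dict()
    np.savez(path.with_suffix(".npz"), __config__=json.dumps(asdict(net.config)), **state)


def load_checkpoint(path: str | Path) -> FusionNetwork:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        for key in ("backbones", "head_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        if cfg_dict.get("class_names") is not None:
            cfg_dict["class_names"] = tuple(cfg_dict["class_names"])
        config = NetworkConfig(**cfg_dict)
        net = FusionNetwork(config, seed=0)
        net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net
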