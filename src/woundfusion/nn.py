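"""Neural-network layer library over :mod:`woundfusion.autodiff`.

Modules follow the familiar container convention: parameters are
registered by attribute assignment, ``parameters()`` walks the tree, and
``train()`` / ``eval()`` toggle stochastic layers (dropout). Every module
takes an explicit ``rng`` for initialization so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "ReLU",
    "Dropout",
    "Sequential",
    "Adam",
    "ReduceLROnPlateau",
]


class Parameter(Tensor):
    """A leaf tensor that is updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        missing = set(named) - set(state)
        extra = set(state) - set(named)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _collect(v):
    if isinstance(v, Parameter):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    """Dense layer; Xavier init by default (``gain`` rescales it)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 gain: float = 1.0):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        std = gain * np.sqrt(2.0 / (in_features + out_features))
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(f"Linear expected {self.in_features} features, got {x.shape[-1]}")
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | str = "same",
        groups: int = 1,
        gain: float = 1.0,
    ):
        super().__init__()
        if padding == "same":
            padding = kernel_size // 2
        if groups not in (1, in_channels):
            raise ValueError("groups must be 1 or in_channels (depthwise)")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.padding = int(padding)
        self.groups = groups
        cin = in_channels // groups
        fan_in = cin * kernel_size * kernel_size
        self.weight = Parameter(gain * _kaiming(rng, fan_in, (out_channels, cin, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.groups == 1:
            return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)
        # depthwise: one filter per input channel
        from .autodiff import concatenate

        outs = []
        for c in range(self.in_channels):
            outs.append(
                conv2d(
                    x[:, c : c + 1],
                    self.weight[c : c + 1],
                    self.bias[c : c + 1],
                    stride=self.stride,
                    padding=self.padding,
                )
            )
        return concatenate(outs, axis=1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout driven by a per-module seeded generator."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored value stops improving.

    The rate is clamped at ``min_lr`` and never raised again — the
    "minimum rate limit" contract of the training schedule.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5, min_lr: float = 1e-5):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> None:
        if value < self.best - 1e-12:
            self.best = value
            self.bad_epochs = 0
            return
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
            self.bad_epochs = 0
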