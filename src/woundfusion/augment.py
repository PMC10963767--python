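"""Training-time stochastic image transformations.

The training pipeline is resize -> {rotate, horizontal flip, vertical
flip, affine (scale/shift/rotate), Gaussian noise, coarse dropout}, each
fired independently with its configured probability, followed by channel
normalization. Evaluation data passes through resize + normalization
only — augmentation is strictly training-side, so held-out metrics
measure generalization on unmodified images.

Magnitudes default to conventional ranges (rotations up to 30°, affine
scale 0.9–1.1, shifts up to 10%, unit-scale noise sigma 0.03, up to 8
dropout holes of 8–32 px); all are tunable and none is load-bearing for
the method. Normalization defaults to the ImageNet channel statistics,
the input convention of the backbone families used downstream.

Images are float arrays in [0, 1], HWC inside the pipeline; the output
is CHW, ready for the network. Labels and locations are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class AugmentConfig:
    target_size: tuple[int, int] = (256, 256)
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rotate: float = 0.5
    p_affine: float = 0.5
    p_noise: float = 0.5
    p_dropout: float = 0.5
    rotate_limit: float = 30.0
    affine_scale: tuple[float, float] = (0.9, 1.1)
    affine_shift: float = 0.1
    affine_rotate: float = 15.0
    noise_sigma: float = 0.03
    dropout_max_holes: int = 8
    dropout_hole_size: tuple[int, int] = (8, 32)
    dropout_fill: float = 0.0
    normalize: bool = True
    mean: np.ndarray = field(default_factory=lambda: IMAGENET_MEAN.copy())
    std: np.ndarray = field(default_factory=lambda: IMAGENET_STD.copy())

    def __post_init__(self):
        for name in ("p_hflip", "p_vflip", "p_rotate", "p_affine", "p_noise", "p_dropout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")


class Transform:
    """A built pipeline; call :meth:`apply` with an image and RNG state.

    ``last_applied`` records which stochastic ops fired on the most
    recent call (useful for auditing the firing rates).
    """

    def __init__(self, config: AugmentConfig, seed: int = 0, training: bool = True):
        self.config = config
        self.training = training
        self._rng = np.random.default_rng(seed)
        self.last_applied: list[str] = []

    def apply(self, image: np.ndarray, rng_state: int | np.random.Generator | None = None) -> np.ndarray:
        """Transform one HWC float image in [0,1]; returns CHW float."""
        rng = _as_rng(rng_state, self._rng)
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an HWC image with 3 channels, got shape {img.shape}")
        cfg = self.config
        self.last_applied = []

        if img.shape[:2] != cfg.target_size:
            img = sktf.resize(img, cfg.target_size, anti_aliasing=True, mode="reflect")

        if self.training:
            if rng.random() < cfg.p_rotate:
                angle = rng.uniform(-cfg.rotate_limit, cfg.rotate_limit)
                img = sktf.rotate(img, angle, mode="reflect")
                self.last_applied.append("rotate")
            if rng.random() < cfg.p_hflip:
                img = img[:, ::-1].copy()
                self.last_applied.append("hflip")
            if rng.random() < cfg.p_vflip:
                img = img[::-1].copy()
                self.last_applied.append("vflip")
            if rng.random() < cfg.p_affine:
                img = self._affine(img, rng)
                self.last_applied.append("affine")
            if rng.random() < cfg.p_noise:
                img = np.clip(img + rng.normal(0.0, cfg.noise_sigma, img.shape), 0.0, 1.0)
                self.last_applied.append("noise")
            if rng.random() < cfg.p_dropout:
                img = self._coarse_dropout(img, rng)
                self.last_applied.append("dropout")

        if cfg.normalize:
            img = (img - cfg.mean.reshape(1, 1, 3)) / cfg.std.reshape(1, 1, 3)
        return img.transpose(2, 0, 1)

    __call__ = apply

    def _affine(self, img: np.ndarray, rng) -> np.ndarray:
        cfg = self.config
        h, w = img.shape[:2]
        scale = rng.uniform(*cfg.affine_scale)
        angle = np.deg2rad(rng.uniform(-cfg.affine_rotate, cfg.affine_rotate))
        tx = rng.uniform(-cfg.affine_shift, cfg.affine_shift) * w
        ty = rng.uniform(-cfg.affine_shift, cfg.affine_shift) * h
        # rotate/scale about the image center, then shift
        center = np.array([w / 2, h / 2])
        tf = (
            sktf.AffineTransform(translation=-center)
            + sktf.AffineTransform(scale=scale, rotation=angle)
            + sktf.AffineTransform(translation=center + [tx, ty])
        )
        return sktf.warp(img, tf.inverse, mode="reflect")

    def _coarse_dropout(self, img: np.ndarray, rng) -> np.ndarray:
        cfg = self.config
        h, w = img.shape[:2]
        img = img.copy()
        n_holes = int(rng.integers(1, cfg.dropout_max_holes + 1))
        lo, hi = cfg.dropout_hole_size
        lo, hi = min(lo, h, w), min(hi, h, w)
        for _ in range(n_holes):
            hh = int(rng.integers(lo, hi + 1))
            ww = int(rng.integers(lo, hi + 1))
            y0 = int(rng.integers(0, max(h - hh, 0) + 1))
            x0 = int(rng.integers(0, max(w - ww, 0) + 1))
            img[y0 : y0 + hh, x0 : x0 + ww] = cfg.dropout_fill
        return img


def build_transform(config: AugmentConfig, seed: int = 0, training: bool = True) -> Transform:
    """Build the training pipeline, or resize+normalize only when ``training=False``."""
    return Transform(config, seed=seed, training=training)


def apply(transform: Transform, image: np.ndarray, rng_state=None) -> np.ndarray:
    return transform.apply(image, rng_state)


def _as_rng(state, default: np.random.Generator) -> np.random.Generator:
    if state is None:
        return default
    if isinstance(state, np.random.Generator):
        return state
    return np.random.default_rng(state)
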