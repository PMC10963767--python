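"""Desk-scale synthetic wound datasets (images + manifest).

The generator emulates the statistical structure the classifier relies
on, not wound photography: each class has a distinct parametric
appearance (base hue + texture family), and each wound sample's body-map
location is drawn from a class-preferred anatomical region set with
probability ``location_assoc`` (else uniformly over all 484 regions).
Appearance families:

* BG — smooth two-color gradient (clutter/backdrop).
* N — skin-tone base with fine speckle noise.
* D/P/S/V — skin background plus an elliptical lesion whose hue,
  eccentricity, granularity and edge darkness are class-specific
  (S is a thin elongated incision; V a large smooth brownish patch).

An optional ``ambiguous_pair`` renders one class with another's
appearance, making the image signal uninformative between the two — the
location signal then carries the class, which is the fixture used to
demonstrate the multi-modal advantage.

Everything is drawn from one seeded generator: the same spec and seed
reproduce byte-identical images and manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .bodymap import CANONICAL_SIZE
from .manifest import CLASS_SYMBOLS, WOUND_CLASSES, Manifest, SampleRecord, write_manifest

#: Fixed, pairwise-disjoint preferred body-map regions per wound class:
#: a band of 8 typical sites each (wounds concentrate at few anatomical
#: sites). Diabetic ulcers favor the foot — the band contains region
#: 135, the right fifth toe tip.
PREFERRED_LOCATIONS: dict[str, frozenset[int]] = {
    "D": frozenset(range(130, 138)),
    "V": frozenset(range(250, 258)),
    "P": frozenset(range(300, 308)),
    "S": frozenset(range(360, 368)),
}

_SKIN = np.array([0.80, 0.60, 0.48])
_LESION_STYLE = {
    # hue (RGB), eccentricity (minor/major axis ratio), granularity, edge darkness
    "D": (np.array([0.55, 0.10, 0.10]), 0.80, 0.12, 0.5),
    "P": (np.array([0.45, 0.20, 0.45]), 0.65, 0.06, 0.3),
    "S": (np.array([0.75, 0.15, 0.20]), 0.18, 0.03, 0.2),
    "V": (np.array([0.50, 0.28, 0.15]), 0.90, 0.02, 0.1),
}


@dataclass(frozen=True)
class SyntheticSpec:
    classes: tuple[str, ...] = CLASS_SYMBOLS
    per_class_n: int = 40
    image_size: int = 32
    location_assoc: float = 0.9
    groups_per_class: int = 5
    seed: int = 0
    ambiguous_pair: tuple[str, str] | None = None

    def __post_init__(self):
        if self.per_class_n < 1:
            raise ValueError("per_class_n must be >= 1")
        if not 0.0 <= self.location_assoc <= 1.0:
            raise ValueError("location_assoc must be in [0, 1]")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = sorted(set(self.classes) - set(CLASS_SYMBOLS))
        if unknown:
            raise ValueError(f"unknown class symbol(s): {unknown}")
        if self.ambiguous_pair is not None:
            a, b = self.ambiguous_pair
            if a not in self.classes or b not in self.classes:
                raise ValueError("ambiguous_pair classes must be in the spec's class list")


def preferred_locations(cls: str) -> frozenset[int]:
    """The fixed preferred body-map region set of a wound class."""
    if cls not in WOUND_CLASSES:
        raise ValueError(f"class {cls!r} has no body-map location (wound classes: {WOUND_CLASSES})")
    return PREFERRED_LOCATIONS[cls]


def draw_location(cls: str, assoc: float, rng: np.random.Generator) -> int:
    if rng.random() < assoc:
        ids = sorted(preferred_locations(cls))
        return int(ids[rng.integers(len(ids))])
    return int(rng.integers(1, CANONICAL_SIZE + 1))


# ---------------------------------------------------------------------------
# Appearance renderers (float HWC in [0, 1])

def _render_bg(size: int, rng) -> np.ndarray:
    # cool, non-skin hues: blue channel dominant, red suppressed
    c0 = np.array([rng.uniform(0.05, 0.25), rng.uniform(0.2, 0.5), rng.uniform(0.5, 0.9)])
    c1 = np.array([rng.uniform(0.05, 0.25), rng.uniform(0.2, 0.5), rng.uniform(0.5, 0.9)])
    t = np.linspace(0, 1, size)
    axis = rng.integers(2)
    ramp = t[:, None] if axis == 0 else t[None, :]
    img = c0 * (1 - ramp[..., None]) + c1 * ramp[..., None]
    return np.broadcast_to(img, (size, size, 3)).copy()

def _render_skin(size: int, rng, speckle: float = 0.04) -> np.ndarray:
    tone = _SKIN * rng.uniform(0.85, 1.1)
    img = np.tile(tone, (size, size, 1))
    img += rng.normal(0, speckle, img.shape)
    return np.clip(img, 0, 1)

def _render_wound(cls: str, size: int, rng) -> np.ndarray:
    hue, ecc, gran, edge_dark = _LESION_STYLE[cls]
    img = _render_skin(size, rng, speckle=0.02)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = rng.uniform(0.35, 0.65, 2) * size
    major = rng.uniform(0.22, 0.36) * size
    minor = max(major * ecc * rng.uniform(0.85, 1.15), 1.5)
    theta = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r = (u / major) ** 2 + (v / minor) ** 2
    inside = r <= 1.0
    lesion = hue * rng.uniform(0.85, 1.15) + rng.normal(0, gran, (size, size, 3))
    img[inside] = np.clip(lesion, 0, 1)[inside]
    ring = (r > 1.0) & (r <= 1.35)
    img[ring] = np.clip(img[ring] * (1.0 - edge_dark), 0, 1)
    return np.clip(img, 0, 1)


def render_sample(cls: str, size: int, rng: np.random.Generator,
                  appearance_cls: str | None = None) -> np.ndarray:
    """Render one image for ``cls`` (optionally wearing another class's look)."""
    look = appearance_cls or cls
    if look == "BG":
        return _render_bg(size, rng)
    if look == "N":
        return _render_skin(size, rng)
    return _render_wound(look, size, rng)


# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec, out_dir: str | Path) -> Manifest:
    """Emit ``per_class_n`` PNGs per class plus ``manifest.csv``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    swap = {}
    if spec.ambiguous_pair is not None:
        a, b = spec.ambiguous_pair
        swap[b] = a  # b wears a's appearance
    records: list[SampleRecord] = []
    for cls in spec.classes:
        for i in range(spec.per_class_n):
            img = render_sample(cls, spec.image_size, rng, appearance_cls=swap.get(cls))
            fname = f"{cls}_{i:04d}.png"
            Image.fromarray((img * 255).astype(np.uint8)).save(out / fname)
            loc = draw_location(cls, spec.location_assoc, rng) if cls in WOUND_CLASSES else None
            group = f"{cls}-g{i * spec.groups_per_class // spec.per_class_n}"
            records.append(SampleRecord(str(out / fname), cls, loc, group))
    manifest = Manifest(records, spec.classes)
    write_manifest(manifest, out / "manifest.csv")
    return manifest


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as float HWC RGB in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
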