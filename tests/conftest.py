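import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from woundfusion import AugmentConfig, SyntheticSpec, generate

#: Desk-scale study conditions used by training tests: 32x32 images,
#: small batches, a higher learning rate than the full-scale reference
#: configuration, and augmentation disabled for the optimization oracles.
DESK = dict(batch_size=2, epochs=50, lr=3e-3, lr_min=3e-4, warmup_epochs=5)


def no_augment(size: int = 32) -> AugmentConfig:
    return AugmentConfig(
        target_size=(size, size),
        p_hflip=0, p_vflip=0, p_rotate=0, p_affine=0, p_noise=0, p_dropout=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """36-image six-class synthetic dataset (6 per class, 32x32)."""
    out = tmp_path_factory.mktemp("synth6")
    spec = SyntheticSpec(per_class_n=6, image_size=32, seed=11)
    manifest = generate(spec, out)
    return manifest


@pytest.fixture(scope="session")
def wound_dataset(tmp_path_factory):
    """Four-wound-class dataset with locations (12 per class, 32x32)."""
    out = tmp_path_factory.mktemp("synth_wounds")
    spec = SyntheticSpec(classes=("D", "P", "S", "V"), per_class_n=12, image_size=32, seed=7)
    return generate(spec, out)
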