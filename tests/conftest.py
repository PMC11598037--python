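import numpy as np
import pytest

from phenonet.samples import VARIETIES
from phenonet.synthetic_data import SynthConfig, generate_sample, vary_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Desk-scale scene: small frame, no depth corruption."""
    return SynthConfig(image_width=160, image_height=120, plant_radius_px=40,
                       px_per_cm=3.0, n_leaves=9, hole_fraction=0.0,
                       boundary_hole_px=0, seed=7)


@pytest.fixture
def holey_config(small_config):
    from dataclasses import replace
    return replace(small_config, hole_fraction=0.3, boundary_hole_px=2)


@pytest.fixture
def small_sample(small_config):
    return generate_sample(small_config, variety="Salanova", image_id="s0")


def make_tiny_items(n=8, seed=1, size=96):
    """Reduced-scale annotated samples converted to training items."""
    from phenonet.training import sample_to_item

    master = np.random.default_rng(seed)
    base = SynthConfig(image_width=size, image_height=size,
                       plant_radius_px=int(size * 0.31), px_per_cm=3.0,
                       n_leaves=8, hole_fraction=0.0, boundary_hole_px=0,
                       seed=seed)
    samples = [generate_sample(vary_config(base, master),
                               variety=VARIETIES[i % 4], image_id=f"p{i}")
               for i in range(n)]
    return samples, [sample_to_item(s) for s in samples]
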