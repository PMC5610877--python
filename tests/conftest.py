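import numpy as np
import pytest

from atlascut import (
    AtlasConfig,
    PhantomSpec,
    build_atlas,
    make_phantom,
    simulate_seeds,
)
from atlascut.phantom import Distractor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_case():
    """Well-contrasted phantom with seeds: the graph cut should nail it."""
    spec = PhantomSpec(
        shape=(32, 32, 24),
        organ_axes=(7.0, 6.0, 5.0),
        organ_intensity=(110.0, 5.0),
        background_intensity=(60.0, 5.0),
        noise_sd=2.0,
        rng_seed=42,
    )
    vol, truth = make_phantom(spec)
    seeds = simulate_seeds(truth, n_organ_strokes=3, n_bg_strokes=6, rng_seed=43)
    return vol, truth, seeds


@pytest.fixture(scope="session")
def confounded_case():
    """Phantom with a distractor sharing the organ intensity distribution."""
    spec = PhantomSpec(
        shape=(48, 48, 32),
        organ_center=(17.0, 22.0, 15.0),
        organ_axes=(9.0, 6.5, 5.0),
        distractors=[Distractor(center=(38.0, 30.0, 16.0), axes=(5.0, 5.0, 4.0))],
        rng_seed=11,
    )
    vol, truth = make_phantom(spec)
    seeds = simulate_seeds(truth, rng_seed=100)
    return vol, truth, seeds


@pytest.fixture(scope="session")
def ellipsoid_atlas():
    """Single-case atlas over a smooth ellipsoid, margin-padded lattice."""
    spec = PhantomSpec(shape=(40, 40, 28), organ_axes=(9.0, 7.0, 5.5), rng_seed=400)
    _, truth = make_phantom(spec)
    cfg = AtlasConfig(lattice=(32, 32, 24), gain=1.0, margin=0.25)
    return build_atlas([truth], cfg), truth
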