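"""Shared fixtures: small synthetic acquisitions reused across test modules."""

import numpy as np
import pytest

from prfthermo.phantom import (
    HotspotSpec,
    PhantomConfig,
    Sonication,
    SonicationSchedule,
    gen_phantom_series,
)

#: a practically-noiseless value (exactly zero is rejected by the config)
TINY_NOISE = 1e-12


@pytest.fixture(scope="session")
def small_config():
    """64×64 phantom at 2.5 mm spacing — fast but geometrically complete."""
    return PhantomConfig(grid_shape=(64, 64), pixel_spacing_mm=(2.5, 2.5))


@pytest.fixture(scope="session")
def noiseless_config(small_config):
    cfg = PhantomConfig(**{**small_config.__dict__, "noise_sigma": TINY_NOISE})
    return cfg


@pytest.fixture(scope="session")
def single_sonication_schedule():
    return SonicationSchedule(
        [Sonication(start_s=3.0, heat_duration_s=20.0, cooling_s=85.0, energy_j=2353.0)]
    )


@pytest.fixture(scope="session")
def static_hot_bundle(noiseless_config):
    """One noiseless frame holding a 16 °C Gaussian hot spot at its peak."""
    return gen_phantom_series(
        noiseless_config, hotspot=HotspotSpec(peak_deltaT=16.0), n_frames=1, seed=0
    )


@pytest.fixture(scope="session")
def heated_bundle(noiseless_config, single_sonication_schedule):
    """Noiseless heating/cooling acquisition: frame 0 unheated, heat from 3 s."""
    return gen_phantom_series(
        noiseless_config,
        schedule=single_sonication_schedule,
        hotspot=HotspotSpec(peak_deltaT=16.0),
        n_frames=12,
        seed=1,
    )


@pytest.fixture(scope="session")
def noisy_null_bundle(small_config):
    """Unheated noisy acquisition (σ_g = 1), three frames."""
    return gen_phantom_series(small_config, n_frames=3, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
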