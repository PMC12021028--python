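import numpy as np
import pytest

from ciliacoat.synthetic import (
    RepeatChainSpec,
    TomoPhantomSpec,
    simulate_repeat_chain,
    simulate_tomogram,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A small coated-tube phantom with truth (64³, 8 particles)."""
    spec = TomoPhantomSpec(
        shape=(64, 64, 64), tube_radius=140.0, n_particles=8, noise_sigma=0.3, seed=1
    )
    vol, truth = simulate_tomogram(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, wedge-free phantom with bare particles (construction tests)."""
    spec = TomoPhantomSpec(
        shape=(64, 64, 64),
        tube_radius=140.0,
        n_particles=4,
        min_spacing=200.0,  # > template box so patches never overlap
        noise_sigma=0.0,
        apply_wedge=False,
        membrane_amplitude=0.0,
        with_axoneme=False,
        seed=2,
    )
    vol, truth = simulate_tomogram(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def repeat_chain_k5():
    spec = RepeatChainSpec(k=5, coord_noise=0.3, seed=501)
    model, bounds, records = simulate_repeat_chain(spec)
    return spec, model, bounds, records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
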