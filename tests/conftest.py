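"""Shared fixtures: small synthetic connectomes generated at test time."""

import numpy as np
import pytest

from walksum import SynthConfig, bare_resolvent, make_connectome
from walksum.connectome import Connectome
from walksum.resolvent import FrequencyGrid


@pytest.fixture(scope="session")
def ring24():
    """Noise-free 24-node ring: circulant, analytically transparent."""
    return make_connectome(
        SynthConfig(n_nodes=24, geometry="ring", hub_fraction=0.0,
                    weight_noise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def ring24_field(ring24):
    return bare_resolvent(ring24, FrequencyGrid.default())


@pytest.fixture(scope="session")
def hub48():
    """48-node box3d connectome with the full three-tier architecture."""
    return make_connectome(SynthConfig(n_nodes=48, geometry="box3d", seed=0))


@pytest.fixture(scope="session")
def hub48_field(hub48):
    return bare_resolvent(hub48, FrequencyGrid.default())


@pytest.fixture()
def two_node():
    """2-node connectome with coupling 0.5 at 80 mm."""
    return Connectome(
        weights=np.array([[0.0, 0.5], [0.5, 0.0]]),
        distances=np.array([[0.0, 80.0], [80.0, 0.0]]),
    )


def random_subunity_connectome(rng: np.random.Generator, n: int) -> Connectome:
    """Random symmetric connectome with spectral radius < 1 (test helper)."""
    w = rng.random((n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    from walksum.connectome import normalize_spectral_radius

    w, _ = normalize_spectral_radius(w)
    d = rng.uniform(5.0, 150.0, size=(n, n))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return Connectome(weights=w, distances=d)
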