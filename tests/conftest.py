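import numpy as np
import pytest

from steerkit.neurons import ElectrodeArrayGeometry, make_neuron
from steerkit.stimulus import build_grid


@pytest.fixture(scope="session")
def triplet_geometry():
    return ElectrodeArrayGeometry.triangular_triplet(pitch=30.0)


@pytest.fixture(scope="session")
def standard_grid():
    """The full three-electrode protocol grid (20 levels, ±1.8 μA)."""
    return build_grid(3, 20, -1.8, 1.8)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 9-level grid for fast fitting tests."""
    return build_grid(3, 9, -1.8, 1.8)


@pytest.fixture(scope="session")
def single_site_neuron(triplet_geometry):
    """One cathodic site under the triplet: planar (logistic) ground truth."""
    return make_neuron(triplet_geometry, soma=[15.0, 8.66],
                       axon_direction=[1.0, 0.0, 0.0], m=1,
                       polarity_mode="cathodic_only", seed=11,
                       cell_id="single")


@pytest.fixture(scope="session")
def dual_site_neuron(triplet_geometry):
    """One anatomical site with its anodic mirror: paired-plane geometry."""
    return make_neuron(triplet_geometry, soma=[15.0, 8.66],
                       axon_direction=[1.0, 0.0, 0.0], m=1,
                       polarity_mode="dual", seed=11, cell_id="dual")


class FrozenPosterior:
    """Stand-in surrogate with a preset posterior, for exact rule tests."""

    def __init__(self, mu, sd, X):
        self.mu = np.asarray(mu, float)
        self.sd = np.asarray(sd, float)
        self._X = np.atleast_2d(np.asarray(X, float))
        self.fitted = True

    def posterior(self, Xq):
        Xq = np.atleast_2d(np.asarray(Xq, float))
        idx = [int(np.argmin(np.linalg.norm(self._X - x, axis=1))) for x in Xq]
        return self.mu[idx], self.sd[idx]


@pytest.fixture
def frozen_posterior_factory():
    return FrozenPosterior
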