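import numpy as np
import pytest

import fibercell as fc


@pytest.fixture(scope="session")
def fish_cell():
    return fc.make_unit_cell(470.0, 470.0, 429.6)


@pytest.fixture(scope="session")
def insect_cell():
    return fc.make_unit_cell(510.0, 510.0, 1160.0)


@pytest.fixture(scope="session")
def vertebrate_toy():
    """Default C3 vertebrate-like toy filament (compact head pairs)."""
    return fc.build_toy_filament(fc.vertebrate_spec(seed=0))


@pytest.fixture(scope="session")
def small_toy():
    """A cut-down vertebrate toy for fast structure-factor tests."""
    return fc.build_toy_filament(
        fc.vertebrate_spec(seed=1, blob_n=8, backbone_n=40))


@pytest.fixture(scope="session")
def random_model():
    """50 random scatterers with random weights, no symmetry."""
    rng = np.random.default_rng(42)
    pos = rng.uniform(-150, 150, size=(50, 3))
    w = rng.uniform(0.5, 10.0, size=50)
    return fc.FilamentModel(pos, w, symmetry_order=1, axial_repeat=429.6,
                            label="random50")


def brute_force_structure_factor(placed, h, k, l):
    """Independent direct double-precision sum, term by term."""
    total = 0.0 + 0.0j
    for (x, y, z), w in zip(placed.frac, placed.weights):
        phase = 2.0 * np.pi * (h * x + k * y + l * z)
        total += w * complex(np.cos(phase), np.sin(phase))
    return total
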