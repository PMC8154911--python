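import numpy as np
import pytest

from geothermflora.synthetic import SyntheticConfig, generate
from geothermflora.trees import patristic_matrix


@pytest.fixture(scope="session")
def dataset():
    """Full-scale synthetic dataset (292 species, 60 families)."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def distmatrix(dataset):
    return patristic_matrix(dataset.tree)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale config for fast pipeline runs."""
    return SyntheticConfig(
        n_families=12,
        tips_per_family=(1, 6),
        n_species=40,
        n_obligate=5,
        n_facultative=7,
        zone_richness=(14, 10, 7, 5),
        n_plots=10,
        n_cover_species=12,
        n_cover_thermal=5,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
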