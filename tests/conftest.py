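import numpy as np
import pytest

from seedscape.landscape import Landscape
from seedscape.synth import CropSpec, SyntheticLandscapeSpec, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_landscape():
    """1x3 strip of 20 m cells with varied cover and fruit."""
    return Landscape(
        rows=1, cols=3, cell_size=20.0,
        cover_m2=np.array([0.0, 200.0, 400.0]),
        plant_species=["holly"],
        fruits=np.array([[0], [50], [200]]),
    )


def make_fit_landscape(seed: int = 11) -> Landscape:
    """Heterogeneous 12x12 landscape used by the fitting experiments."""
    spec = SyntheticLandscapeSpec(
        rows=12, cols=12, cell_size=20.0,
        cover_mean=0.45, cover_sd=0.35, cover_corr_cells=1.5,
        crops=[
            CropSpec("A", 120, clustering=5, cluster_sd_m=25.0),
            CropSpec("B", 80, clustering=3, cluster_sd_m=30.0),
        ],
    )
    ls, _ = generate_landscape(spec, np.random.default_rng(seed))
    return ls


@pytest.fixture(scope="session")
def fit_landscape():
    return make_fit_landscape()


@pytest.fixture(scope="session")
def study_landscape():
    """A landscape at the emulated study-plot scale (22x20 cells of 20 m)."""
    from seedscape.defaults import default_landscape_spec

    ls, _ = generate_landscape(default_landscape_spec(), np.random.default_rng(1))
    return ls


@pytest.fixture(scope="session")
def assemblage():
    from seedscape.defaults import default_assemblage

    return default_assemblage()


def uniform_landscape(rows=8, cols=8, cell=20.0, fruit=2000, plants=("A", "B", "C")):
    """Spatially uniform landscape: equal cover and equal fruit everywhere."""
    n = rows * cols
    return Landscape(
        rows=rows, cols=cols, cell_size=cell,
        cover_m2=np.full(n, 0.5 * cell * cell),
        plant_species=list(plants),
        fruits=np.full((n, len(plants)), fruit, dtype=np.int64),
    )
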