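import numpy as np
import pytest

from dynspom.landscape import Landscape
from dynspom.species import SpeciesParams


def make_landscape(x, y, area, age=None, side=1000.0, **kw):
    """Build an explicit landscape from coordinate/area lists."""
    x = np.asarray(x, dtype=float)
    n = x.size
    age = np.zeros(n, dtype=np.int64) if age is None else np.asarray(age)
    defaults = dict(target_cover=0.1, mean_area=0.5, sd_area=0.2, min_dist=10.0)
    defaults.update(kw)
    return Landscape(
        ids=np.arange(n), x=x, y=np.asarray(y, dtype=float),
        area=np.asarray(area, dtype=float), age=age, side=side, **defaults,
    )


@pytest.fixture
def two_patch_landscape():
    return make_landscape(x=[0.0, 3.0], y=[0.0, 4.0], area=[1.0, 1.0])


@pytest.fixture
def mid_species():
    return SpeciesParams(species_id=0, alpha=0.004, y=10.0, A0=0.05,
                         preference="mid")


@pytest.fixture
def late_species():
    return SpeciesParams(species_id=0, alpha=0.001, y=5.0, A0=0.05,
                         preference="late")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
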