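import numpy as np
import pytest

from arealife.pipeline import estimate_denominators
from arealife.synthetic import simulate_city


@pytest.fixture(scope="session")
def city36():
    """A small synthetic city shared by the integration-level tests."""
    return simulate_city(n_areas=36, n_units=6, seed=5)


@pytest.fixture(scope="session")
def exposure36(city36):
    return estimate_denominators(
        city36.census, city36.projections, city36.units, city36.open_age,
        2010, (2015, 2016, 2017))


def exposure_matrix(exposure, city, sex):
    """Pivot the long exposure table to (n_areas, n_ages) for one sex."""
    return (exposure[exposure["sex"] == sex]
            .pivot_table(index="area", columns="age", values="exposure",
                         fill_value=0.0)
            .reindex(index=city.areas, columns=city.ages(sex), fill_value=0.0)
            .to_numpy(dtype=float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
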