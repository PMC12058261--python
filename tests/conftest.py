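import numpy as np
import pytest

from bcrisk import IncidenceTable, default_model, packaged_incidence_table


@pytest.fixture(scope="session")
def synthetic_table():
    return packaged_incidence_table()


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture
def toy_table():
    """Small multi-band table spanning [40, 80) with varying rates."""
    return IncidenceTable.from_bands(
        [(40, 45, 120), (45, 50, 190), (50, 55, 240), (55, 60, 300),
         (60, 65, 360), (65, 70, 400), (70, 75, 380), (75, 80, 390)]
    )


@pytest.fixture
def zero_table():
    return IncidenceTable.from_bands([(40, 80, 0.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
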