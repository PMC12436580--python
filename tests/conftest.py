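import numpy as np
import pytest

from epdscat import CohortSpec, ItemBank, LatentModel, QuadratureGrid, generate_cohort, generate_item_bank

ITEMS = [f"item{i}" for i in range(1, 11)]


def item_matrix(df):
    return df[ITEMS].to_numpy(dtype=int)


@pytest.fixture(scope="session")
def bank1():
    """Default-seed unidimensional 10-item bank."""
    return generate_item_bank(1, seed=0)


@pytest.fixture(scope="session")
def latent1():
    return LatentModel(1)


@pytest.fixture(scope="session")
def grid1(latent1):
    return QuadratureGrid.build(latent1)


@pytest.fixture(scope="session")
def cohort1(bank1):
    """Unidimensional synthetic cohort (N=800) with hidden traits."""
    spec = CohortSpec(n=800, dimension=1, seed=42)
    return generate_cohort(spec, bank1)


def toy_item_bank(a=1.5, b=(-1.0, 0.0, 1.0)):
    """Single-item unidimensional bank from slope/threshold values."""
    a_arr = np.array([a])
    b_arr = np.array([list(b)])
    return ItemBank.from_thresholds(a_arr, b_arr, dimension=1, si_item=0)
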