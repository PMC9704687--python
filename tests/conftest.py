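import numpy as np
import pytest

from scorelink import (
    GRMItem,
    ResponseMatrix,
    ThetaGrid,
    bsi_items_8a_linked,
    bsi_items_18item_linked,
    default_anchor_bank,
)


@pytest.fixture(scope="session")
def bsi_8a():
    """Six published legacy-scale items linked through the 8-item anchor form."""
    return bsi_items_8a_linked()


@pytest.fixture(scope="session")
def bsi_18():
    """The same items linked through the 18-item anchor set."""
    return bsi_items_18item_linked()


@pytest.fixture(scope="session")
def anchors():
    return default_anchor_bank(8)


@pytest.fixture(scope="session")
def grid49():
    return ThetaGrid.equally_spaced(49, -4, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230817)


@pytest.fixture()
def symmetric_item():
    return GRMItem("sym", slope=2.0, thresholds=(-1.0, 1.0))


def random_item(rng, item_id="rand", n_categories=None):
    """Draw a valid GRM item: slope in [0.5, 4], spread ordered thresholds."""
    K = n_categories or int(rng.integers(2, 6))
    a = float(rng.uniform(0.5, 4.0))
    b = np.sort(rng.uniform(-3, 3, size=K - 1))
    b += np.arange(K - 1) * 1e-3  # break ties
    return GRMItem(item_id, a, tuple(b))


@pytest.fixture()
def toy_responses():
    """3 persons x 2 binary items, complete data."""
    items = [
        GRMItem("i1", 1.2, (-0.5,), fixed=True),
        GRMItem("i2", 0.8, (0.7,)),
    ]
    resp = ResponseMatrix(
        np.array([[0, 0], [1, 0], [1, 1]]), ("i1", "i2"), ("a", "b", "c")
    )
    return resp, items
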