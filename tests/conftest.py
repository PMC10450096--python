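import numpy as np
import pytest

from jitaema import Item, generate_synthetic_bank


@pytest.fixture(scope="session")
def bank():
    """Default 13-item, 5-category synthetic fatigue-style bank."""
    return generate_synthetic_bank(seed=1)


@pytest.fixture
def sym_item():
    """A symmetric 3-category item: information peaks at theta = 0."""
    return Item("sym", 2.0, (-0.5, 0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_responses(bank, rng, n_items=None):
    """Draw a random response set (item, category) from the bank."""
    if n_items is None:
        n_items = int(rng.integers(1, 6))
    idx = rng.choice(len(bank), size=n_items, replace=False)
    return [
        (bank.items[i], int(rng.integers(1, bank.items[i].n_categories + 1)))
        for i in idx
    ]


@pytest.fixture(name="random_responses")
def random_responses_fixture():
    return random_responses
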