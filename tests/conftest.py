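import numpy as np
import pandas as pd
import pytest

from nrkg.data_io import InteractionTable, RecipeTable, NUTRIENT_COLUMNS
from nrkg.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_interactions() -> InteractionTable:
    rows = [
        ("u1", "r1", 5, 0),
        ("u1", "r2", 3, 1),
        ("u1", "r4", 5, 2),
        ("u2", "r2", 3, 0),
        ("u2", "r3", 4, 1),
        ("u3", "r9", 5, 0),
    ]
    return InteractionTable(
        pd.DataFrame(rows, columns=["user_id", "recipe_id", "rating", "order_index"])
    )


@pytest.fixture
def tiny_recipes() -> RecipeTable:
    rng = np.random.default_rng(42)
    ids = [f"r{i}" for i in range(1, 11)]
    values = rng.uniform(1, 500, size=(len(ids), 7))
    return RecipeTable(
        pd.DataFrame(values, index=pd.Index(ids, name="recipe_id"),
                     columns=list(NUTRIENT_COLUMNS))
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-structure dataset shared by training tests."""
    return generate_dataset(SyntheticConfig(n_users=60, n_recipes=90, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions."""
    return generate_dataset(SyntheticConfig(seed=0))
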