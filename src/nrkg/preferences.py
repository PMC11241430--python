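"""User nutrition preference profiles.

A user's preferred-recipe collection holds every recipe they rated 5, in
interaction order; a user with no 5-star rating falls back to the single
first recipe they interacted with. The preference profile is the
component-wise mean nutrient vector over that collection — one 7-vector
per user, kept on the raw scale for correlation analysis and additionally
standardized with the recipe corpus transforms for use as a model feature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import InteractionTable, RecipeTable, NUTRIENT_COLUMNS
from .graph_construction import NutrientStandardizer

logger = logging.getLogger(__name__)


def preferred_recipes(interactions: InteractionTable) -> dict:
    """Map each user to their preferred-recipe collection.

    All 5-star recipes in interaction order; if none, the first interacted
    recipe alone (regardless of its rating).
    """
    out: dict = {}
    df = interactions.records.sort_values(["user_id", "order_index"], kind="stable")
    for user, grp in df.groupby("user_id", sort=False):
        fives = grp.loc[grp["rating"] == 5, "recipe_id"].tolist()
        out[user] = fives if fives else [grp["recipe_id"].iloc[0]]
    return out


def compute_profiles(preferred: dict, recipes: RecipeTable) -> pd.DataFrame:
    """Mean nutrient 7-vector over each user's preferred recipes (raw scale)."""
    missing = sorted(
        {r for lam in preferred.values() for r in lam if r not in recipes.table.index}, key=str
    )
    if missing:
        raise KeyError(f"preferred recipes missing from recipe table: {missing}")
    rows = {user: recipes.matrix(lam).mean(axis=0) for user, lam in preferred.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(NUTRIENT_COLUMNS))


def batch_profiles(users, profiles: pd.DataFrame) -> np.ndarray:
    """Stack profile rows in the given user order (duplicates repeated)."""
    unknown = [u for u in users if u not in profiles.index]
    if unknown:
        raise KeyError(f"users without profiles: {unknown}")
    return profiles.loc[list(users)].to_numpy(dtype=float)


class PreferenceProfiler(BaseEstimator):
    """Derive per-user nutrition preference profiles from interactions.

    Parameters
    ----------
    cold_user_fallback : bool
        When True (default), users absent at fit time receive the global
        mean profile at lookup instead of raising.

    Attributes
    ----------
    preferred_ : dict
        user id -> preferred-recipe collection.
    profiles_ : pandas.DataFrame
        Raw-scale profiles, one row per user, canonical nutrient columns.
    profiles_std_ : pandas.DataFrame
        Profiles standardized with the recipe-corpus column transforms.
    global_profile_ : numpy.ndarray
        Mean of all raw profiles; the cold-user fallback.
    """

    def __init__(self, cold_user_fallback: bool = True):
        self.cold_user_fallback = cold_user_fallback

    def fit(self, interactions: InteractionTable, recipes: RecipeTable,
            scaler: NutrientStandardizer | None = None):
        self.preferred_ = preferred_recipes(interactions)
        self.profiles_ = compute_profiles(self.preferred_, recipes)
        if scaler is None:
            scaler = NutrientStandardizer().fit(recipes.matrix())
        self.scaler_ = scaler
        self.profiles_std_ = pd.DataFrame(
            scaler.transform(self.profiles_.to_numpy(dtype=float)),
            index=self.profiles_.index,
            columns=self.profiles_.columns,
        )
        self.global_profile_ = self.profiles_.to_numpy(dtype=float).mean(axis=0)
        return self

    def lookup(self, users, standardized: bool = False) -> np.ndarray:
        """Profile matrix for a user batch, with cold-user fallback."""
        table = self.profiles_std_ if standardized else self.profiles_
        known = [u for u in users if u in table.index]
        if len(known) == len(users):
            return batch_profiles(users, table)
        if not self.cold_user_fallback:
            return batch_profiles(users, table)  # raises with offender list
        cold = [u for u in users if u not in table.index]
        logger.info("using global mean profile for %d cold users", len(cold))
        fallback = self.global_profile_
        if standardized:
            fallback = self.scaler_.transform(fallback.reshape(1, -1))[0]
        rows = [
            table.loc[u].to_numpy(dtype=float) if u in table.index else fallback
            for u in users
        ]
        return np.asarray(rows, dtype=float)
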