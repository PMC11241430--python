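"""Reading, validating and splitting the interaction and recipe tables.

Two CSV dialects are supported:

``canonical``
    ``interactions.csv``: columns ``user_id, recipe_id, rating``
    (extra columns ignored); ``recipes.csv``: ``recipe_id`` followed by the
    seven nutrient columns in canonical order.

``foodcom``
    The Kaggle Food.com export: interactions carry ``user_id, recipe_id,
    date, rating, review`` and recipes store nutrition as a bracketed
    7-value list ``"[calories, total fat, sugar, sodium, protein,
    saturated fat, carbohydrates]"`` which is remapped to canonical order
    on load.

Canonical nutrient order, used everywhere in the package:
calories, total fat, saturated fat, sodium, protein, sugar, carbohydrates.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUTRIENT_COLUMNS = (
    "calories",
    "total_fat",
    "saturated_fat",
    "sodium",
    "protein",
    "sugar",
    "carbohydrates",
)
N_NUTRIENTS = len(NUTRIENT_COLUMNS)

# Position of each canonical nutrient inside the Food.com bracketed list
# (calories, total fat, sugar, sodium, protein, saturated fat, carbohydrates).
_FOODCOM_TO_CANONICAL = (0, 1, 5, 3, 4, 2, 6)

DIALECTS = ("canonical", "foodcom")


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A cell value violates the table contract."""


@dataclass
class InteractionTable:
    """Ordered (user, recipe, rating, order) records.

    ``order_index`` counts interactions within each user, following file
    row order (or timestamp order in the foodcom dialect when present),
    starting at 0.
    """

    records: pd.DataFrame  # columns: user_id, recipe_id, rating, order_index

    def __post_init__(self) -> None:
        required = {"user_id", "recipe_id", "rating", "order_index"}
        missing = required - set(self.records.columns)
        if missing:
            raise SchemaError(f"interaction table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def users(self) -> list:
        return list(pd.unique(self.records["user_id"]))

    @property
    def recipes(self) -> list:
        return list(pd.unique(self.records["recipe_id"]))

    def for_user(self, user_id) -> pd.DataFrame:
        sub = self.records[self.records["user_id"] == user_id]
        return sub.sort_values("order_index")


@dataclass
class RecipeTable:
    """Per-recipe 7-component nutrient vectors in canonical order."""

    table: pd.DataFrame  # index: recipe_id; columns: NUTRIENT_COLUMNS

    def __post_init__(self) -> None:
        missing = set(NUTRIENT_COLUMNS) - set(self.table.columns)
        if missing:
            raise SchemaError(f"recipe table missing nutrient columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate recipe ids: {dupes}")
        values = self.table[list(NUTRIENT_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = self.table.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValidationError(f"non-finite nutrient values for recipes: {bad}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def recipe_ids(self) -> list:
        return list(self.table.index)

    def vector(self, recipe_id) -> np.ndarray:
        try:
            return self.table.loc[recipe_id, list(NUTRIENT_COLUMNS)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"unknown recipe id: {recipe_id!r}") from None

    def matrix(self, recipe_ids: Sequence | None = None) -> np.ndarray:
        ids = self.recipe_ids if recipe_ids is None else list(recipe_ids)
        unknown = [r for r in ids if r not in self.table.index]
        if unknown:
            raise KeyError(f"unknown recipe ids: {unknown}")
        return self.table.loc[ids, list(NUTRIENT_COLUMNS)].to_numpy(dtype=float)


@dataclass
class SplitAssignment:
    """Record-level train/val/test partition of an interaction table."""

    partition: np.ndarray  # array of {"train","val","test"}, aligned to records
    ratios: tuple
    seed: int

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.partition == part)

    def subset(self, table: InteractionTable, part: str) -> InteractionTable:
        sub = table.records.iloc[self.indices(part)].reset_index(drop=True)
        return InteractionTable(sub)


def _read_csv(path) -> pd.DataFrame:
    # pandas handles gzip transparently by extension
    return pd.read_csv(path)


def read_interactions(path, dialect: str = "canonical") -> InteractionTable:
    """Load a user-recipe interaction table.

    Ratings must lie in 0..5. Duplicate (user, recipe) pairs keep the first
    occurrence; the dropped count is logged. ``order_index`` is assigned per
    user from file row order (foodcom rows are first ordered by ``date``
    when that column exists).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path)
    for col in ("user_id", "recipe_id", "rating"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path.name} (dialect {dialect!r})")
    if dialect == "foodcom" and "date" in df.columns:
        df = df.sort_values(["user_id", "date"], kind="stable")
    df = df.reset_index(drop=True)

    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad = ratings.isna() | (ratings < 0) | (ratings > 5) | (ratings % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"rating {df['rating'].iloc[row]!r} outside 0-5 on row {row + 2} of {path.name}"
        )
    df["rating"] = ratings.astype(int)

    n_before = len(df)
    df = df.drop_duplicates(subset=["user_id", "recipe_id"], keep="first")
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d duplicate (user, recipe) interactions", dropped)
    df = df.reset_index(drop=True)
    df["order_index"] = df.groupby("user_id", sort=False).cumcount()
    return InteractionTable(df[["user_id", "recipe_id", "rating", "order_index"]])


def write_interactions(table: InteractionTable, path) -> None:
    table.records[["user_id", "recipe_id", "rating"]].to_csv(path, index=False)


def _parse_foodcom_nutrition(cell, row_label) -> list:
    try:
        values = ast.literal_eval(str(cell))
    except (ValueError, SyntaxError):
        raise ValidationError(f"unparseable nutrition list on row {row_label}: {cell!r}") from None
    if not isinstance(values, (list, tuple)) or len(values) != N_NUTRIENTS:
        raise ValidationError(
            f"expected {N_NUTRIENTS} nutrition values on row {row_label}, got {cell!r}"
        )
    return [float(values[i]) for i in _FOODCOM_TO_CANONICAL]


def read_recipes(path, dialect: str = "canonical") -> RecipeTable:
    """Load recipe nutrient vectors, remapping Food.com order to canonical."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path)
    id_col = "recipe_id" if "recipe_id" in df.columns else "id" if "id" in df.columns else None
    if id_col is None:
        raise SchemaError(f"missing column 'recipe_id' in {path.name}")

    if dialect == "foodcom":
        if "nutrition" not in df.columns:
            raise SchemaError(f"missing column 'nutrition' in {path.name} (dialect 'foodcom')")
        rows = [
            _parse_foodcom_nutrition(cell, i + 2)
            for i, cell in enumerate(df["nutrition"])
        ]
        out = pd.DataFrame(rows, columns=list(NUTRIENT_COLUMNS))
    else:
        missing = [c for c in NUTRIENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing nutrient columns {missing} in {path.name}")
        out = df[list(NUTRIENT_COLUMNS)].copy()
        for col in NUTRIENT_COLUMNS:
            vals = pd.to_numeric(out[col], errors="coerce")
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise ValidationError(
                    f"unparseable {col} value {out[col].iloc[row]!r} on row {row + 2}"
                )
            out[col] = vals.astype(float)
    out.index = pd.Index(df[id_col], name="recipe_id")
    return RecipeTable(out)


def write_recipes(recipes: RecipeTable, path) -> None:
    recipes.table.to_csv(path, index=True, index_label="recipe_id")


def split_interactions(
    table: InteractionTable,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign interaction records to train/val/test.

    Sizes follow largest-remainder rounding of ``ratios`` so realized
    proportions are within one record of the request. Every user with at
    least 3 records is guaranteed at least one training record (violating
    users have one record swapped in from val/test deterministically).
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3:
        raise ValueError("ratios must have exactly three components")
    if any(r < 0 for r in ratios):
        raise ValueError(f"negative split ratio: {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {sum(ratios)}")

    n = len(table)
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment
    raw = np.array(ratios) * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    for k in range(remainder):
        sizes[order[k]] += 1

    labels = np.array(["train"] * sizes[0] + ["val"] * sizes[1] + ["test"] * sizes[2])
    perm = rng.permutation(n)
    partition = np.empty(n, dtype=object)
    partition[perm] = labels

    # per-user guarantee: users with >=3 records keep at least one in train
    users = table.records["user_id"].to_numpy()
    for user in pd.unique(users):
        idx = np.flatnonzero(users == user)
        if len(idx) >= 3 and not np.any(partition[idx] == "train"):
            swap_in = idx[int(rng.integers(len(idx)))]
            # swap with a train record of a multi-train user to keep sizes
            train_idx = np.flatnonzero(partition == "train")
            train_users = users[train_idx]
            counts = pd.Series(train_users).value_counts()
            rich = train_idx[np.isin(train_users, counts[counts > 1].index)]
            if len(rich):
                swap_out = rich[int(rng.integers(len(rich)))]
                partition[swap_out] = partition[swap_in]
                partition[swap_in] = "train"
    return SplitAssignment(partition=partition, ratios=ratios, seed=seed)
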