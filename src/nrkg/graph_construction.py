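"""Standardized nutrient features, the nutrition-similarity graph, and the
heterogeneous user-recipe graph.

Recipe nutrient vectors are column-standardized (zero mean, unit population
standard deviation). Recipe pairs whose standardized vectors have cosine
similarity above a threshold (default 0.98) are linked in a recipe-recipe
similarity graph; those edges join the rated user-recipe edges in a single
heterogeneous undirected graph used for message passing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import InteractionTable, N_NUTRIENTS

logger = logging.getLogger(__name__)

DEFAULT_SIMILARITY_THRESHOLD = 0.98
_EXACT_ALLPAIRS_LIMIT = 20_000
_BLOCK = 2048


class NutrientStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise standardization to zero mean and unit population std.

    Zero-variance columns are mapped to all zeros rather than dividing by
    zero. The fitted ``mean_`` / ``scale_`` are reused to place user
    preference profiles on the same scale as recipe features.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)  # population std (ddof=0)
        self.zero_variance_ = std == 0.0
        self.scale_ = np.where(self.zero_variance_, 1.0, std)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        out = (X - self.mean_) / self.scale_
        out[:, self.zero_variance_] = 0.0
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.size and not np.all(np.isfinite(X)):
            r, c = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(f"non-finite nutrient value at row {r}, column {c}")
        if X.shape[0] < 1:
            raise ValueError("need at least one row to standardize")
        return X


@dataclass
class NutrientMatrix:
    """Recipe nutrient matrix with its row identity and scale flag."""

    recipe_ids: list
    values: np.ndarray  # N x 7
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_NUTRIENTS:
            raise ValueError(f"expected an N x {N_NUTRIENTS} matrix, got {self.values.shape}")
        if len(self.recipe_ids) != self.values.shape[0]:
            raise ValueError("recipe_ids length does not match matrix rows")

    def row(self, recipe_id) -> np.ndarray:
        return self.values[self.recipe_ids.index(recipe_id)]


def standardize(values, recipe_ids: Sequence | None = None) -> NutrientMatrix:
    """Standardize a raw nutrient matrix column-wise (population sigma)."""
    scaler = NutrientStandardizer().fit(values)
    out = scaler.transform(values)
    ids = list(recipe_ids) if recipe_ids is not None else list(range(out.shape[0]))
    return NutrientMatrix(recipe_ids=ids, values=out, standardized=True)


def cosine(a, b) -> float:
    """Cosine similarity of two nutrient vectors; 0 for a zero vector.

    A recipe sitting exactly at every column mean standardizes to the zero
    vector, whose cosine is undefined; such recipes get similarity 0 so they
    never enter the similarity graph.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.info("cosine of zero vector requested; returning 0")
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class SimilarityGraph:
    """Unordered recipe pairs whose cosine similarity exceeds a threshold."""

    pairs: list  # list of (recipe_id_a, recipe_id_b)
    scores: list  # matching cosine values
    threshold: float

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.scores):
            raise ValueError("pairs and scores length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set:
        return {frozenset(p) for p in self.pairs}


def build_similarity_graph(
    matrix: NutrientMatrix,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    block_size: int | None = None,
) -> SimilarityGraph:
    """All unordered recipe pairs with cosine strictly above ``threshold``.

    Exact all-pairs comparison, computed blockwise above a few thousand
    rows (or at ``block_size`` rows when given) to bound the memory of the
    N x N similarity matrix. Zero rows (cosine undefined) never pair.
    """
    if not (-1.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (-1, 1], got {threshold}")
    X = matrix.values
    n = X.shape[0]
    if n == 0:
        return SimilarityGraph([], [], threshold)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0.0
    if zero.any():
        logger.info("%d zero-vector recipes excluded from similarity graph", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    U = X / safe[:, None]
    U[zero] = 0.0

    pairs: list = []
    scores: list = []
    ids = matrix.recipe_ids
    if block_size is not None:
        block = int(block_size)
    else:
        block = n if n <= _EXACT_ALLPAIRS_LIMIT else _BLOCK
    for start in range(0, n, block):
        stop = min(start + block, n)
        S = U[start:stop] @ U.T  # (stop-start) x n
        S[zero[start:stop], :] = -np.inf  # undefined cosine never pairs
        S[:, zero] = -np.inf
        rows, cols = np.nonzero(S > threshold)
        for r, c in zip(rows, cols):
            i = start + r
            if i < c:  # each unordered pair once; excludes the diagonal
                pairs.append((ids[i], ids[c]))
                scores.append(float(np.clip(S[r, c], -1.0, 1.0)))
    return SimilarityGraph(pairs=pairs, scores=scores, threshold=threshold)


@dataclass
class HeteroGraph:
    """Heterogeneous undirected graph of users and recipes.

    ``rated_edges`` carry the rating as weight (or 1 when
    ``rating_weights`` was disabled); ``similar_edges`` carry weight 1 by
    default or the cosine score. Edges are stored once and expanded to both
    directions for message passing.
    """

    user_nodes: list
    recipe_nodes: list
    rated_edges: list  # (user_id, recipe_id, weight)
    similar_edges: list  # (recipe_id_a, recipe_id_b, weight)
    recipe_features: NutrientMatrix

    def __post_init__(self) -> None:
        users = set(self.user_nodes)
        recipes = set(self.recipe_nodes)
        bad = [e for e in self.rated_edges if e[0] not in users or e[1] not in recipes]
        bad += [e for e in self.similar_edges if e[0] not in recipes or e[1] not in recipes]
        if bad:
            raise ValueError(f"edges reference unknown nodes: {bad[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.user_nodes) + len(self.recipe_nodes)

    def node_index(self) -> dict:
        """Global node numbering: users first, then recipes."""
        index = {("user", u): i for i, u in enumerate(self.user_nodes)}
        offset = len(self.user_nodes)
        index.update({("recipe", r): offset + i for i, r in enumerate(self.recipe_nodes)})
        return index


def assemble_hetero_graph(
    train: InteractionTable,
    features: NutrientMatrix,
    similarity: SimilarityGraph,
    rating_weights: bool = True,
    cosine_weights: bool = False,
) -> HeteroGraph:
    """Assemble the heterogeneous graph from training interactions only.

    Recipes without interactions and users without similarity links are
    kept as (possibly isolated) nodes; all recipe ids referenced by
    interactions or similarity pairs must exist in ``features``.
    """
    known = set(features.recipe_ids)
    offenders = sorted(
        {r for r in train.records["recipe_id"] if r not in known}
        | {r for p in similarity.pairs for r in p if r not in known},
        key=str,
    )
    if offenders:
        raise ValueError(f"recipe ids missing from nutrient matrix: {offenders}")

    rated = [
        (u, r, float(t) if rating_weights else 1.0)
        for u, r, t in zip(
            train.records["user_id"], train.records["recipe_id"], train.records["rating"]
        )
    ]
    similar = [
        (a, b, float(s) if cosine_weights else 1.0)
        for (a, b), s in zip(similarity.pairs, similarity.scores)
    ]
    return HeteroGraph(
        user_nodes=list(dict.fromkeys(train.records["user_id"])),
        recipe_nodes=list(features.recipe_ids),
        rated_edges=rated,
        similar_edges=similar,
        recipe_features=features,
    )
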