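"""Synthetic interaction and recipe tables with planted nutrition structure.

Recipes cluster around a small number of nutritional archetypes (e.g.
high-protein, high-sugar, high-fat, light) whose anchor 7-vectors are
drawn from distinct log-normal regimes; every recipe is its archetype's
anchor plus non-negative Gaussian noise. Each user belongs to one
archetype: their interactions are biased toward recipes of that archetype
and their 5-star ratings concentrate on it, so preference profiles and
nutrition-aware models have recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import InteractionTable, RecipeTable, NUTRIENT_COLUMNS, N_NUTRIENTS


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``rating5_prob_match`` / ``rating5_prob_mismatch`` give the chance an
    interaction is rated 5 when the recipe does / does not share the
    user's archetype; other ratings are uniform on 1..4.
    ``interact_match_prob`` biases which recipes a user interacts with
    toward their own archetype — the planted signal that makes held-out
    interactions predictable. ``nutrient_noise_sd`` scales per-component
    noise relative to the anchor value.
    """

    n_users: int = 200
    n_recipes: int = 300
    n_archetypes: int = 4
    interactions_per_user: int = 12
    rating5_prob_match: float = 0.7
    rating5_prob_mismatch: float = 0.1
    interact_match_prob: float = 0.7
    nutrient_noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.rating5_prob_match, self.rating5_prob_mismatch, self.interact_match_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_archetypes > self.n_recipes:
            raise ValueError("more archetypes than recipes")
        if self.interactions_per_user > self.n_recipes:
            raise ValueError("interactions_per_user exceeds the recipe universe")


# Log-normal regimes per archetype: (mu, sigma) of log nutrient value, per
# canonical component. Magnitudes emulate per-serving values: calories in
# the hundreds, macronutrients in tens of grams / percent-DV units.
_ARCHETYPE_REGIMES = {
    "high_protein": [(6.1, 0.2), (2.9, 0.3), (1.8, 0.3), (5.6, 0.3), (3.9, 0.2), (1.6, 0.4), (2.7, 0.3)],
    "high_sugar": [(6.0, 0.2), (2.3, 0.3), (2.1, 0.3), (4.6, 0.3), (1.6, 0.4), (4.1, 0.2), (3.9, 0.2)],
    "high_fat": [(6.4, 0.2), (4.0, 0.2), (3.4, 0.2), (6.0, 0.3), (2.9, 0.3), (2.3, 0.4), (3.0, 0.3)],
    "light": [(4.9, 0.2), (1.6, 0.4), (0.9, 0.4), (4.2, 0.3), (2.3, 0.3), (2.1, 0.3), (2.9, 0.2)],
}


def archetype_anchors(cfg: SyntheticConfig) -> np.ndarray:
    """Anchor nutrient 7-vectors, one per archetype (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    names = list(_ARCHETYPE_REGIMES)
    anchors = []
    for k in range(cfg.n_archetypes):
        regime = _ARCHETYPE_REGIMES[names[k % len(names)]]
        anchor = np.array([rng.lognormal(mu, sigma) for mu, sigma in regime])
        if k >= len(names):  # extra archetypes get independent draws
            anchor = anchor * rng.uniform(0.5, 2.0, size=N_NUTRIENTS)
        anchors.append(anchor)
    return np.asarray(anchors)


def generate_recipes(cfg: SyntheticConfig) -> tuple:
    """Recipe table plus ground-truth archetype labels.

    Each recipe is its archetype anchor plus Gaussian noise with
    per-component sd ``nutrient_noise_sd * anchor``, clipped at 0.
    """
    anchors = archetype_anchors(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    labels = rng.integers(cfg.n_archetypes, size=cfg.n_recipes)
    # guarantee every archetype is represented
    labels[: cfg.n_archetypes] = np.arange(cfg.n_archetypes)
    sd = cfg.nutrient_noise_sd * anchors[labels]
    values = np.clip(anchors[labels] + rng.normal(0.0, 1.0, (cfg.n_recipes, N_NUTRIENTS)) * sd, 0.0, None)
    ids = [f"r{i}" for i in range(cfg.n_recipes)]
    table = pd.DataFrame(values, index=pd.Index(ids, name="recipe_id"),
                         columns=list(NUTRIENT_COLUMNS))
    truth = dict(zip(ids, (int(x) for x in labels)))
    return RecipeTable(table), truth


def generate_interactions(
    recipes: RecipeTable, truth: dict, cfg: SyntheticConfig
) -> tuple:
    """Interaction table plus ground-truth user archetypes.

    Each user draws ``interactions_per_user`` distinct recipes, preferring
    their own archetype with probability ``interact_match_prob`` (uniform
    among the rest otherwise); ratings follow the match/mismatch 5-star
    probabilities, non-5 ratings uniform on 1..4.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    ids = np.asarray(recipes.recipe_ids, dtype=object)
    labels = np.array([truth[r] for r in ids])
    by_arch = [ids[labels == k] for k in range(cfg.n_archetypes)]

    rows = []
    user_truth = {}
    for u in range(cfg.n_users):
        user = f"u{u}"
        arch = int(rng.integers(cfg.n_archetypes))
        user_truth[user] = arch
        own = set(by_arch[arch])
        chosen: list = []
        seen: set = set()
        while len(chosen) < cfg.interactions_per_user:
            use_own = rng.random() < cfg.interact_match_prob and not own <= seen
            pool = by_arch[arch] if use_own else ids
            r = pool[int(rng.integers(len(pool)))]
            if r in seen:
                continue
            seen.add(r)
            chosen.append(r)
        for order, r in enumerate(chosen):
            p5 = cfg.rating5_prob_match if truth[r] == arch else cfg.rating5_prob_mismatch
            rating = 5 if rng.random() < p5 else int(rng.integers(1, 5))
            rows.append((user, r, rating, order))
    df = pd.DataFrame(rows, columns=["user_id", "recipe_id", "rating", "order_index"])
    return InteractionTable(df), user_truth


def generate_dataset(cfg: SyntheticConfig | None = None) -> dict:
    """Full synthetic dataset: recipes, interactions and ground truth."""
    cfg = cfg or SyntheticConfig()
    recipes, recipe_truth = generate_recipes(cfg)
    interactions, user_truth = generate_interactions(recipes, recipe_truth, cfg)
    return {
        "config": cfg,
        "recipes": recipes,
        "recipe_archetypes": recipe_truth,
        "interactions": interactions,
        "user_archetypes": user_truth,
        "anchors": archetype_anchors(cfg),
    }
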