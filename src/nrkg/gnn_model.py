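"""Heterogeneous graph convolution, link scoring, and the training loop.

The node update is ``x'_i = W1 x_i + sum_t W2_t sum_{j in N_t(i)} e_{j,i} x_j``
with one self weight ``W1`` and one neighbor weight ``W2_t`` per edge type
(rated user-recipe edges and nutrition-similarity recipe-recipe edges).
Link scores are the sigmoid of the dot product between the convolved user
and recipe embeddings, trained with binary cross-entropy against observed
interactions (label 1) and per-user uniformly sampled non-interactions
(label 0).

``NRKGRecommender`` is the scikit-learn-style entry point: ``fit`` on an
interaction table plus a recipe table runs graph construction, preference
profiling, attention fusion and the convolutional training loop end to
end; ``predict_proba`` scores arbitrary (user, recipe) pairs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .autodiff import Adam, Tensor, concat, glorot, _stable_sigmoid
from .data_io import (
    InteractionTable,
    RecipeTable,
    split_interactions,
)
from .evaluation import auc as _auc
from .fusion import (
    EmbeddingConfig,
    FusionParams,
    fuse_recipe,
    fuse_user,
    linear,
)
from .graph_construction import (
    HeteroGraph,
    NutrientMatrix,
    NutrientStandardizer,
    SimilarityGraph,
    assemble_hetero_graph,
    build_similarity_graph,
)
from .preferences import PreferenceProfiler

logger = logging.getLogger(__name__)

ABLATIONS = ("NRKG", "NRKG-G", "NRKG-U", "NRKG-R")
EDGE_TYPES = ("rated", "similar")
_CLAMP = 1e-7


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

@dataclass
class GraphConvParams:
    """Per-layer weights: one self map W1 and one neighbor map per edge type."""

    layers: list  # each: {"W1": Tensor, "W2": {edge_type: Tensor}}

    @classmethod
    def init(cls, rng: np.random.Generator, width: int, n_layers: int) -> "GraphConvParams":
        layers = [
            {
                "W1": glorot(rng, width, width),
                "W2": {t: glorot(rng, width, width) for t in EDGE_TYPES},
            }
            for _ in range(n_layers)
        ]
        # damp the output layer so initial link scores sit near 0 (loss ~ ln 2)
        for t in (layers[-1]["W1"], *layers[-1]["W2"].values()):
            t.data *= 0.1
        return cls(layers=layers)

    def tensors(self) -> list:
        out = []
        for layer in self.layers:
            out.append(layer["W1"])
            out.extend(layer["W2"].values())
        return out


def graph_conv_layer(x, adjacency: dict, W1, W2: dict):
    """One heterogeneous convolution: self term plus weighted neighbor sums.

    ``adjacency`` maps edge type to an (n, n) weighted matrix A with
    ``A[i, j] = e_{j, i}`` for each retained edge; a node with no
    neighbors keeps only its self term.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    out = linear(x, W1)
    for etype, A in adjacency.items():
        if etype not in W2:
            raise KeyError(f"no neighbor weights for edge type {etype!r}")
        msg = Tensor(A) @ x
        out = out + linear(msg, W2[etype])
    return out


def build_adjacency(graph: HeteroGraph) -> dict:
    """Dense symmetric weighted adjacency per edge type (undirected)."""
    index = graph.node_index()
    n = graph.n_nodes
    A = {t: np.zeros((n, n)) for t in EDGE_TYPES}
    for u, r, w in graph.rated_edges:
        i, j = index[("user", u)], index[("recipe", r)]
        A["rated"][i, j] = w
        A["rated"][j, i] = w
    for a, b, w in graph.similar_edges:
        i, j = index[("recipe", a)], index[("recipe", b)]
        A["similar"][i, j] = w
        A["similar"][j, i] = w
    return A


def row_normalize(adjacency: dict) -> dict:
    """Divide each row by its weighted degree (per edge type).

    Turns the neighbor sum of the convolution into a weighted mean, which
    keeps feature magnitudes bounded across layers; ratings still set the
    relative contribution of each neighbor.
    """
    out = {}
    for etype, A in adjacency.items():
        deg = A.sum(axis=1, keepdims=True)
        out[etype] = np.divide(A, deg, out=np.zeros_like(A), where=deg != 0)
    return out


def sample_neighbors(
    adjacency: dict,
    fanout: int,
    n_layers: int,
    rng: np.random.Generator,
    seeds=None,
) -> list:
    """Per-layer neighbor subsampling of the adjacency structure.

    For every node (optionally restricted to ``seeds``) and edge type,
    keep at most ``fanout`` incoming neighbors, sampled uniformly without
    replacement; nodes with fewer neighbors keep them all. Returns one
    sampled adjacency dict per layer, deterministic under the generator
    state.
    """
    if fanout < 1:
        raise ValueError("fanout must be >= 1")
    out = []
    some = next(iter(adjacency.values()))
    rows = range(some.shape[0]) if seeds is None else seeds
    for _ in range(n_layers):
        sampled = {}
        for etype, A in adjacency.items():
            S = np.zeros_like(A)
            for i in rows:
                nbrs = np.flatnonzero(A[i])
                if len(nbrs) > fanout:
                    nbrs = rng.choice(nbrs, size=fanout, replace=False)
                S[i, nbrs] = A[i, nbrs]
            sampled[etype] = S
        out.append(sampled)
    return out


# ---------------------------------------------------------------------------
# scoring and loss
# ---------------------------------------------------------------------------

def score(u_emb, r_emb) -> np.ndarray:
    """Sigmoid of the dot product of matching user/recipe embedding rows."""
    u_emb = np.atleast_2d(np.asarray(u_emb, dtype=float))
    r_emb = np.atleast_2d(np.asarray(r_emb, dtype=float))
    if u_emb.shape != r_emb.shape:
        raise ValueError(f"embedding width mismatch: {u_emb.shape} vs {r_emb.shape}")
    s = (u_emb * r_emb).sum(axis=1)
    return np.clip(_stable_sigmoid(s), _CLAMP, 1.0 - _CLAMP)


def bce_loss(y_true, y_pred) -> float:
    """Mean binary cross-entropy with natural log; predictions pre-clamped."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.clip(np.asarray(y_pred, dtype=float), _CLAMP, 1.0 - _CLAMP)
    if y_true.size == 0:
        raise ValueError("empty prediction batch")
    return float(-np.mean(y_true * np.log(y_pred) + (1 - y_true) * np.log(1 - y_pred)))


def sample_negatives(
    positives: pd.DataFrame,
    interacted: dict,
    recipe_universe: list,
    ratio: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniform per-user negatives: recipes the user never interacted with.

    ``interacted`` maps user -> set of recipe ids across ALL partitions, so
    no sampled negative is a held-out positive. Users who touched every
    recipe are skipped with a warning.
    """
    universe = np.asarray(recipe_universe, dtype=object)
    uni_index = {r: k for k, r in enumerate(universe)}
    users_out, recipes_out = [], []
    counts = positives["user_id"].value_counts()
    for user, n_pos in counts.items():
        seen = interacted.get(user, set())
        mask = np.ones(len(universe), dtype=bool)
        idx = [uni_index[r] for r in seen if r in uni_index]
        mask[idx] = False
        eligible = universe[mask]
        if len(eligible) == 0:
            logger.warning("user %r interacted with every recipe; no negatives", user)
            continue
        draws = rng.choice(eligible, size=ratio * int(n_pos), replace=True)
        users_out.extend([user] * len(draws))
        recipes_out.extend(draws.tolist())
    return pd.DataFrame({"user_id": users_out, "recipe_id": recipes_out})


# ---------------------------------------------------------------------------
# model parameters and forward pass
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Every trainable tensor of the recommender."""

    user_emb: Tensor  # (M, d_model)
    user_emb2: Tensor  # (M, d_model) second half when profiles are ablated
    recipe_emb: Tensor  # (N, d_model)
    recipe_emb2: Tensor  # (N, d_model) second half when nutrient fusion is ablated
    fusion: FusionParams
    conv: GraphConvParams

    def tensors(self) -> list:
        return [
            self.user_emb,
            self.user_emb2,
            self.recipe_emb,
            self.recipe_emb2,
            *self.fusion.tensors(),
            *self.conv.tensors(),
        ]

    def snapshot(self) -> list:
        return [t.data.copy() for t in self.tensors()]

    def restore(self, snap: list) -> None:
        for t, d in zip(self.tensors(), snap):
            t.data = d.copy()


def _forward(
    params: ModelParams,
    adjacency_layers: list,
    theta_std: np.ndarray,
    profiles_std: np.ndarray,
    ablation: str,
    cfg: EmbeddingConfig,
):
    """Node embedding matrix after fusion and stacked convolutions.

    Users occupy rows [0, M); recipes rows [M, M+N). Ablations swap the
    nutrition-derived embedding halves for plain learned ones:
    the base variant uses neither nutrition input, the user-only variant
    adds preference profiles, the recipe-only variant adds nutrient fusion.
    """
    use_recipe_nutrients = ablation in ("NRKG", "NRKG-R")
    use_user_profiles = ablation in ("NRKG", "NRKG-U")

    if use_recipe_nutrients:
        theta_proj = linear(theta_std, params.fusion.W_nutrient)
        r_tilde = fuse_recipe(
            params.recipe_emb, theta_proj, params.fusion.attention, mode=cfg.attention_mode
        )
    else:
        r_tilde = concat([params.recipe_emb, params.recipe_emb2], axis=1)

    if use_user_profiles:
        prof_proj = linear(profiles_std, params.fusion.W_profile)
        u_tilde = fuse_user(params.user_emb, prof_proj)
    else:
        u_tilde = concat([params.user_emb, params.user_emb2], axis=1)

    x = concat([u_tilde, r_tilde], axis=0)
    n_layers = len(params.conv.layers)
    for k, layer in enumerate(params.conv.layers):
        adj = adjacency_layers[min(k, len(adjacency_layers) - 1)]
        x = graph_conv_layer(x, adj, layer["W1"], layer["W2"])
        if k < n_layers - 1:
            x = x.relu()
    return x


def _pair_logits(x: Tensor, u_idx: np.ndarray, r_idx: np.ndarray) -> Tensor:
    xu = x.take_rows(u_idx)
    xr = x.take_rows(r_idx)
    return (xu * xr).sum(axis=1)


def _bce_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean BCE computed in logit space: softplus(s) - y*s.

    Identical to -[y log sigmoid(s) + (1-y) log(1-sigmoid(s))] but keeps
    gradients alive when the sigmoid saturates.
    """
    y = np.asarray(y, dtype=float)
    return (logits.softplus() - Tensor(y) * logits).mean()


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class NRKGRecommender(BaseEstimator):
    """Nutrition-aware heterogeneous-graph link predictor.

    Parameters
    ----------
    d_model : int
        Base embedding width; fused embeddings have width ``2 * d_model``.
    heads : int
        Attention heads in the recipe fusion block.
    n_layers : int
        Graph convolution layers.
    fanout : int
        Neighbors sampled per node, edge type and layer during training.
    sim_threshold : float
        Cosine threshold for the nutrition-similarity recipe graph.
    epochs, lr : int, float
        Training length and Adam learning rate.
    negative_ratio : int
        Sampled non-interactions per observed interaction.
    eval_threshold : float
        Score cut-off when converting probabilities to hard labels.
    ablation : str
        One of "NRKG" (full), "NRKG-G" (no nutrition input, bipartite
        graph), "NRKG-U" (user profiles only), "NRKG-R" (recipe nutrient
        fusion + similarity edges only).
    attention_mode : str
        "self" (3-token self-attention, mean-pooled) or "cross".
    split_ratios : tuple
        Train/validation/test fractions over interaction records.
    rating_weights : bool
        Weight rated edges by the 0-5 rating (else weight 1).
    cosine_weights : bool
        Weight similarity edges by the cosine score (else weight 1).
    random_state : int
        Master seed for splitting, initialization and all sampling.
    """

    def __init__(
        self,
        d_model: int = 16,
        heads: int = 2,
        n_layers: int = 2,
        fanout: int = 5,
        sim_threshold: float = 0.98,
        epochs: int = 60,
        lr: float = 1e-2,
        negative_ratio: int = 1,
        eval_threshold: float = 0.5,
        ablation: str = "NRKG",
        attention_mode: str = "self",
        split_ratios: tuple = (0.6, 0.2, 0.2),
        rating_weights: bool = True,
        cosine_weights: bool = False,
        normalize_adjacency: bool = True,
        random_state: int = 0,
    ):
        self.d_model = d_model
        self.heads = heads
        self.n_layers = n_layers
        self.fanout = fanout
        self.sim_threshold = sim_threshold
        self.epochs = epochs
        self.lr = lr
        self.negative_ratio = negative_ratio
        self.eval_threshold = eval_threshold
        self.ablation = ablation
        self.attention_mode = attention_mode
        self.split_ratios = split_ratios
        self.rating_weights = rating_weights
        self.cosine_weights = cosine_weights
        self.normalize_adjacency = normalize_adjacency
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, interactions: InteractionTable, recipes: RecipeTable):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if not (0.0 < self.eval_threshold < 1.0):
            raise ValueError("eval_threshold must lie in (0, 1)")
        if int(self.negative_ratio) < 1:
            raise ValueError("negative_ratio must be an integer >= 1")

        seeds = np.random.SeedSequence(self.random_state).spawn(4)
        rng_init, rng_sample, rng_negtrain, rng_negeval = (
            np.random.default_rng(s) for s in seeds
        )

        self.split_ = split_interactions(interactions, self.split_ratios, seed=self.random_state)
        train = self.split_.subset(interactions, "train")
        val = self.split_.subset(interactions, "val")
        test = self.split_.subset(interactions, "test")

        # nutrient standardization over the whole recipe corpus
        self.scaler_ = NutrientStandardizer().fit(recipes.matrix())
        theta_std = NutrientMatrix(
            recipe_ids=recipes.recipe_ids,
            values=self.scaler_.transform(recipes.matrix()),
            standardized=True,
        )

        # nutrition-similarity edges only where nutrition enters the model
        if self.ablation in ("NRKG", "NRKG-R"):
            self.similarity_ = build_similarity_graph(theta_std, self.sim_threshold)
        else:
            self.similarity_ = SimilarityGraph([], [], self.sim_threshold)

        self.graph_ = assemble_hetero_graph(
            train,
            theta_std,
            self.similarity_,
            rating_weights=self.rating_weights,
            cosine_weights=self.cosine_weights,
        )
        # the node universe covers every user/recipe, not only those in train
        all_users = list(dict.fromkeys(interactions.records["user_id"]))
        self.graph_.user_nodes = all_users
        self.graph_.__post_init__()

        self.profiler_ = PreferenceProfiler().fit(train, recipes, scaler=self.scaler_)

        self.user_index_ = {u: i for i, u in enumerate(self.graph_.user_nodes)}
        self.recipe_index_ = {r: i for i, r in enumerate(self.graph_.recipe_nodes)}
        M, N = len(self.user_index_), len(self.recipe_index_)
        offset = M

        cfg = EmbeddingConfig(
            d_model=self.d_model,
            heads=self.heads,
            seed=self.random_state,
            attention_mode=self.attention_mode,
        )
        self._cfg = cfg
        self.params_ = ModelParams(
            user_emb=Tensor(rng_init.normal(0, 0.1, (M, cfg.d_model)), requires_grad=True),
            user_emb2=Tensor(rng_init.normal(0, 0.1, (M, cfg.d_model)), requires_grad=True),
            recipe_emb=Tensor(rng_init.normal(0, 0.1, (N, cfg.d_model)), requires_grad=True),
            recipe_emb2=Tensor(rng_init.normal(0, 0.1, (N, cfg.d_model)), requires_grad=True),
            fusion=FusionParams.init(cfg, rng_init),
            conv=GraphConvParams.init(rng_init, cfg.width, self.n_layers),
        )

        self._theta_std = theta_std.values
        self._profiles_std = self.profiler_.lookup(self.graph_.user_nodes, standardized=True)
        self._adjacency = build_adjacency(self.graph_)

        interacted: dict = {}
        for u, r in zip(interactions.records["user_id"], interactions.records["recipe_id"]):
            interacted.setdefault(u, set()).add(r)
        universe = self.graph_.recipe_nodes

        def frozen_eval(part: pd.DataFrame) -> tuple:
            neg = sample_negatives(
                part, interacted, universe, int(self.negative_ratio), rng_negeval
            )
            u = np.array(
                [self.user_index_[x] for x in list(part["user_id"]) + list(neg["user_id"])]
            )
            r = np.array(
                [
                    offset + self.recipe_index_[x]
                    for x in list(part["recipe_id"]) + list(neg["recipe_id"])
                ]
            )
            y = np.concatenate([np.ones(len(part)), np.zeros(len(neg))])
            return u, r, y

        self._val_batch = frozen_eval(val.records)
        self._test_batch = frozen_eval(test.records)

        optimizer = Adam(self.params_.tensors(), lr=self.lr)
        pos_u = np.array([self.user_index_[x] for x in train.records["user_id"]])
        pos_r = np.array([offset + self.recipe_index_[x] for x in train.records["recipe_id"]])

        self.loss_curve_ = []
        self.val_auc_curve_ = []
        best = (-np.inf, None, -1)
        for epoch in range(int(self.epochs)):
            neg = sample_negatives(
                train.records, interacted, universe, int(self.negative_ratio), rng_negtrain
            )
            neg_u = np.array([self.user_index_[x] for x in neg["user_id"]])
            neg_r = np.array([offset + self.recipe_index_[x] for x in neg["recipe_id"]])
            u_idx = np.concatenate([pos_u, neg_u])
            r_idx = np.concatenate([pos_r, neg_r])
            y = np.concatenate([np.ones(len(pos_u)), np.zeros(len(neg_u))])

            adj_layers = sample_neighbors(
                self._adjacency, self.fanout, self.n_layers, rng_sample
            )
            if self.normalize_adjacency:
                adj_layers = [row_normalize(a) for a in adj_layers]
            x = _forward(
                self.params_, adj_layers, self._theta_std, self._profiles_std,
                self.ablation, cfg,
            )
            logits = _pair_logits(x, u_idx, r_idx)
            loss = _bce_logits(logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            self.loss_curve_.append(float(loss.data))

            val_auc = self._evaluate_auc(self._val_batch)
            self.val_auc_curve_.append(val_auc)
            if val_auc > best[0]:
                best = (val_auc, self.params_.snapshot(), epoch)

        if best[1] is not None:
            self.params_.restore(best[1])
        self.best_epoch_ = best[2]
        self.best_val_auc_ = best[0]
        self.node_embeddings_ = self._full_forward()
        return self

    # -- inference ----------------------------------------------------------

    def _full_forward(self) -> np.ndarray:
        adj = row_normalize(self._adjacency) if self.normalize_adjacency else self._adjacency
        x = _forward(
            self.params_,
            [adj],
            self._theta_std,
            self._profiles_std,
            self.ablation,
            self._cfg,
        )
        return x.data

    def _evaluate_auc(self, batch) -> float:
        u, r, y = batch
        x = self._full_forward()
        s = score(x[u], x[r])
        return _auc(s, y)

    def predict_proba(self, pairs) -> np.ndarray:
        """Interaction probability for (user_id, recipe_id) pairs."""
        x = self.node_embeddings_
        offset = len(self.user_index_)
        try:
            u = np.array([self.user_index_[p[0]] for p in pairs])
            r = np.array([offset + self.recipe_index_[p[1]] for p in pairs])
        except KeyError as e:
            raise KeyError(f"unknown user or recipe id: {e.args[0]!r}") from None
        return score(x[u], x[r])

    def predict(self, pairs) -> np.ndarray:
        return (self.predict_proba(pairs) >= self.eval_threshold).astype(int)

    def evaluate(self, part: str = "test"):
        """Metric report on the frozen held-out batch ('val' or 'test')."""
        from .evaluation import confusion_metrics

        batch = {"val": self._val_batch, "test": self._test_batch}[part]
        u, r, y = batch
        x = self.node_embeddings_
        s = score(x[u], x[r])
        report = confusion_metrics(s, y, threshold=self.eval_threshold)
        report.auc = _auc(s, y)
        return report


def train(
    interactions: InteractionTable,
    recipes: RecipeTable,
    config: dict | None = None,
) -> NRKGRecommender:
    """Functional wrapper: fit an ``NRKGRecommender`` with config overrides."""
    model = NRKGRecommender(**(config or {}))
    return model.fit(interactions, recipes)
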