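import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from nrkg.autodiff import Tensor, glorot
from nrkg.gnn_model import (
    NRKGRecommender,
    _bce_logits,
    _pair_logits,
    bce_loss,
    build_adjacency,
    graph_conv_layer,
    row_normalize,
    sample_negatives,
    sample_neighbors,
    score,
)
from nrkg.synthetic_data import SyntheticConfig, generate_dataset


def brute_force_conv(x, adjacency, W1, W2):
    """Double-loop oracle for the heterogeneous node update."""
    n, w = x.shape
    out = np.zeros((n, W1.shape[0]))
    for i in range(n):
        out[i] = W1 @ x[i]
        for etype, A in adjacency.items():
            acc = np.zeros(w)
            for j in range(n):
                if A[i, j] != 0:
                    acc += A[i, j] * x[j]
            out[i] += W2[etype] @ acc
    return out


class TestGraphConvLayer:
    def test_isolated_node_keeps_self_term_only(self):
        rng = np.random.default_rng(0)
        W1 = Tensor(rng.normal(size=(4, 4)))
        W2 = {"rated": Tensor(rng.normal(size=(4, 4)))}
        x = rng.normal(size=(1, 4))
        out = graph_conv_layer(x, {"rated": np.zeros((1, 1))}, W1, W2)
        np.testing.assert_allclose(out.data, x @ W1.data.T)

    def test_identity_weights_add_neighbor(self):
        eye = Tensor(np.eye(3))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        x = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        out = graph_conv_layer(x, {"rated": A}, eye, {"rated": eye})
        np.testing.assert_allclose(out.data, x + x[::-1])

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            w = int(rng.integers(2, 6))
            x = rng.normal(size=(n, w))
            adjacency = {
                t: rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.4)
                for t in ("rated", "similar")
            }
            W1 = Tensor(rng.normal(size=(w, w)))
            W2 = {t: Tensor(rng.normal(size=(w, w))) for t in adjacency}
            out = graph_conv_layer(x, adjacency, W1, W2)
            ref = brute_force_conv(x, adjacency, W1.data, {t: W.data for t, W in W2.items()})
            assert np.abs(out.data - ref).max() < 1e-9


class TestNeighborSampling:
    def _adj(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        A = (rng.random((n, n)) < 0.6).astype(float)
        np.fill_diagonal(A, 0)
        return {"rated": A}

    def test_undersized_neighborhood_kept_whole(self):
        A = np.zeros((4, 4))
        A[0, 1:] = 1.0
        out = sample_neighbors({"rated": A}, fanout=5, n_layers=1,
                               rng=np.random.default_rng(0))
        np.testing.assert_allclose(out[0]["rated"], A)

    def test_fanout_cardinality_and_subset(self):
        adj = self._adj()
        out = sample_neighbors(adj, fanout=3, n_layers=2, rng=np.random.default_rng(1))
        for layer in out:
            S = layer["rated"]
            for i in range(S.shape[0]):
                kept = np.flatnonzero(S[i])
                true = np.flatnonzero(adj["rated"][i])
                assert len(kept) == min(3, len(true))
                assert set(kept) <= set(true)

    def test_deterministic_under_seed(self):
        adj = self._adj()
        a = sample_neighbors(adj, 3, 2, np.random.default_rng(9))
        b = sample_neighbors(adj, 3, 2, np.random.default_rng(9))
        for la, lb in zip(a, b):
            np.testing.assert_allclose(la["rated"], lb["rated"])

    def test_row_normalize_rows_sum_to_one(self):
        adj = self._adj()
        out = row_normalize(adj)["rated"]
        sums = out.sum(axis=1)
        nz = adj["rated"].sum(axis=1) > 0
        np.testing.assert_allclose(sums[nz], 1.0)
        assert (sums[~nz] == 0).all()


class TestScoreAndLoss:
    def test_zero_embedding_scores_half(self):
        assert score(np.zeros((1, 4)), np.ones((1, 4)))[0] == pytest.approx(0.5)

    def test_known_sigmoid_value(self):
        # (1,2).(3,-1) = 1 -> sigmoid(1)
        assert score([[1.0, 2.0]], [[3.0, -1.0]])[0] == pytest.approx(0.73106, abs=1e-5)

    def test_score_monotone_to_one(self):
        r = np.ones((1, 4))
        vals = [score(c * r, r)[0] for c in (1, 10, 100, 1000)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, abs=1e-6)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score(np.ones((1, 3)), np.ones((1, 4)))

    def test_bce_at_half_is_ln2(self):
        assert bce_loss([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(np.log(2))

    def test_bce_hand_computed(self):
        expected = -0.5 * (np.log(0.9) + np.log(0.8))
        assert bce_loss([1, 0], [0.9, 0.2]) == pytest.approx(expected, abs=1e-5)
        assert expected == pytest.approx(0.16425, abs=1e-5)

    def test_bce_perfect_predictions_near_zero(self):
        assert bce_loss([1, 0], [1.0, 0.0]) <= 1e-6

    def test_bce_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([], [])

    def test_loss_invariant_to_batch_shuffle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert bce_loss(y, p) == pytest.approx(bce_loss(y[perm], p[perm]))

    def test_gradient_matches_finite_difference(self):
        """Analytic gradient of bce(score(...)) vs central differences."""
        rng = np.random.default_rng(3)
        x0 = rng.normal(size=(6, 4)) * 0.5
        u_idx = np.array([0, 1, 2])
        r_idx = np.array([3, 4, 5])
        y = np.array([1.0, 0.0, 1.0])

        def loss_at(xd):
            t = Tensor(xd, requires_grad=True)
            return _bce_logits(_pair_logits(t, u_idx, r_idx), y), t

        loss, t = loss_at(x0)
        loss.backward()
        num = np.zeros_like(x0)
        eps = 1e-6
        for i in range(x0.shape[0]):
            for j in range(x0.shape[1]):
                xp, xm = x0.copy(), x0.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                num[i, j] = (loss_at(xp)[0].data - loss_at(xm)[0].data) / (2 * eps)
        assert np.abs(num - t.grad).max() < 1e-4


class TestNegativeSampling:
    def _setup(self):
        pos = pd.DataFrame({"user_id": ["u"], "recipe_id": ["r0"]})
        interacted = {"u": {"r0", "r1"}}
        universe = [f"r{i}" for i in range(10)]
        return pos, interacted, universe

    def test_negatives_avoid_all_interactions(self):
        pos, interacted, universe = self._setup()
        neg = sample_negatives(pos, interacted, universe, ratio=1,
                               rng=np.random.default_rng(0))
        assert len(neg) == 1
        assert neg["recipe_id"].iloc[0] not in interacted["u"]

    def test_frozen_under_seed(self):
        pos, interacted, universe = self._setup()
        a = sample_negatives(pos, interacted, universe, 3, np.random.default_rng(5))
        b = sample_negatives(pos, interacted, universe, 3, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_saturated_user_skipped(self):
        pos = pd.DataFrame({"user_id": ["u"], "recipe_id": ["r0"]})
        neg = sample_negatives(pos, {"u": {"r0", "r1"}}, ["r0", "r1"], 1,
                               np.random.default_rng(0))
        assert len(neg) == 0

    def test_draws_uniform_over_eligible(self):
        pos = pd.DataFrame({"user_id": ["u"] * 1000, "recipe_id": ["r0"] * 1000})
        interacted = {"u": {"r0", "r1"}}
        universe = [f"r{i}" for i in range(10)]
        neg = sample_negatives(pos, interacted, universe, 1, np.random.default_rng(7))
        counts = neg["recipe_id"].value_counts()
        assert set(counts.index) <= set(universe) - interacted["u"]
        observed = [counts.get(r, 0) for r in sorted(set(universe) - interacted["u"])]
        assert chisquare(observed).pvalue > 0.01


class TestTraining:
    def test_initial_loss_near_ln2(self, small_dataset):
        m = NRKGRecommender(random_state=0, epochs=1).fit(
            small_dataset["interactions"], small_dataset["recipes"]
        )
        assert abs(m.loss_curve_[0] - np.log(2)) < 0.15

    def test_identical_seeds_identical_curves(self, small_dataset):
        kw = dict(random_state=4, epochs=8)
        a = NRKGRecommender(**kw).fit(small_dataset["interactions"], small_dataset["recipes"])
        b = NRKGRecommender(**kw).fit(small_dataset["interactions"], small_dataset["recipes"])
        np.testing.assert_allclose(a.loss_curve_, b.loss_curve_)
        np.testing.assert_allclose(a.val_auc_curve_, b.val_auc_curve_)

    def test_loss_descends(self, small_dataset):
        m = NRKGRecommender(random_state=0, epochs=15).fit(
            small_dataset["interactions"], small_dataset["recipes"]
        )
        assert m.loss_curve_[-1] < m.loss_curve_[0]

    def test_predict_proba_bounds_and_errors(self, small_dataset):
        m = NRKGRecommender(random_state=0, epochs=3).fit(
            small_dataset["interactions"], small_dataset["recipes"]
        )
        pairs = [("u0", "r0"), ("u1", "r5")]
        p = m.predict_proba(pairs)
        assert ((p > 0) & (p < 1)).all()
        assert set(m.predict(pairs)) <= {0, 1}
        with pytest.raises(KeyError):
            m.predict_proba([("ghost", "r0")])

    def test_invalid_ablation_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="ablation"):
            NRKGRecommender(ablation="bogus").fit(
                small_dataset["interactions"], small_dataset["recipes"]
            )

    def test_sklearn_param_interface(self):
        m = NRKGRecommender()
        params = m.get_params()
        assert params["d_model"] == 16 and params["fanout"] == 5 and params["n_layers"] == 2
        m.set_params(epochs=3)
        assert m.epochs == 3

    def test_base_variant_ignores_nutrition_edges(self, small_dataset):
        m = NRKGRecommender(random_state=0, epochs=2, ablation="NRKG-G").fit(
            small_dataset["interactions"], small_dataset["recipes"]
        )
        assert len(m.similarity_) == 0
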