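"""GCN forward pass, readout, training loop and gradients."""

import numpy as np
import pytest

from bfngcn import (
    AdjacencyMatrix,
    GCNParams,
    GraphSample,
    TrainConfig,
    gcn_forward,
    normalize_adjacency,
    predict_proba,
    readout,
    train,
)
from bfngcn.features import NodeFeatureMatrix
from bfngcn.gcn import batch_loss_and_grads, init_params


def make_sample(a_raw, x, label=0, normalized=None):
    adj = AdjacencyMatrix(raw=np.asarray(a_raw, dtype=float), estimator="pc")
    if normalized is not None:
        adj.normalized = np.asarray(normalized, dtype=float)
    else:
        normalize_adjacency(adj)
    feats = NodeFeatureMatrix(values=np.asarray(x, dtype=float), feature_set=("CV",))
    return GraphSample(adjacency=adj, features=feats, label=label)


def sym(a):
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def identity_params(d):
    return GCNParams(
        W0=np.eye(d), W1=np.eye(d), head_W=np.zeros((2 * d, 2)), head_b=np.zeros(2)
    )


class TestForward:
    def test_identity_collapse(self):
        # Â = I, W0 = W1 = I, X >= 0  =>  F = X
        x = np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        s = make_sample(np.zeros((4, 4)), x, normalized=np.eye(4))
        np.testing.assert_allclose(gcn_forward(s, identity_params(4)), x)

    def test_zero_features_zero_embedding(self):
        s = make_sample(np.ones((3, 3)) - np.eye(3), np.zeros((3, 3)))
        np.testing.assert_array_equal(gcn_forward(s, identity_params(3)), 0.0)

    def test_matches_naive_loop_oracle(self):
        r = np.random.default_rng(5)
        a_raw = np.abs(r.standard_normal((3, 3)))
        a_raw = (a_raw + a_raw.T) / 2
        np.fill_diagonal(a_raw, 0.0)
        x = r.standard_normal((3, 4))
        s = make_sample(a_raw, x)
        p = GCNParams(
            W0=r.standard_normal((4, 2)),
            W1=r.standard_normal((2, 2)),
            head_W=np.zeros((4, 2)),
            head_b=np.zeros(2),
        )
        a = s.adjacency.normalized

        def relu(z):
            return np.where(z > 0, z, 0.0)

        def matmul_loops(u, v):
            out = np.zeros((u.shape[0], v.shape[1]))
            for i in range(u.shape[0]):
                for j in range(v.shape[1]):
                    for k in range(u.shape[1]):
                        out[i, j] += u[i, k] * v[k, j]
            return out

        expected = relu(
            matmul_loops(a, matmul_loops(relu(matmul_loops(a, matmul_loops(x, p.W0))), p.W1))
        )
        np.testing.assert_allclose(gcn_forward(s, p), expected, atol=1e-6)

    def test_relu_nonnegativity(self):
        r = np.random.default_rng(9)
        s = make_sample(sym(np.abs(r.standard_normal((5, 5)))), r.standard_normal((5, 6)))
        p = init_params(6, TrainConfig(embedding_dim=4, seed=1))
        assert (gcn_forward(s, p) >= 0).all()


class TestReadout:
    def test_single_node(self):
        f = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(readout(f), [1, 2, 3, 1, 2, 3])

    def test_constant_rows_halves_equal(self):
        f = np.tile([2.0, 5.0], (4, 1))
        h = readout(f)
        np.testing.assert_array_equal(h[:2], h[2:])

    def test_hand_mean_max(self):
        h = readout(np.array([[1.0, 0.0], [0.0, 2.0]]))
        np.testing.assert_allclose(h, [0.5, 1.0, 1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            readout(np.zeros((0, 3)))


class TestGradients:
    def test_finite_difference_check(self):
        # analytic gradients agree with central differences on a 3-node toy
        r = np.random.default_rng(3)
        samples = [
            make_sample(
                sym(np.abs(r.standard_normal((3, 3)))),
                r.standard_normal((3, 2)),
                label=lab,
            )
            for lab in (0, 1, 1)
        ]
        a = np.stack([s.adjacency.normalized for s in samples])
        x = np.stack([s.features.values for s in samples])
        y = np.array([s.label for s in samples])
        p = init_params(2, TrainConfig(embedding_dim=3, seed=4))
        _, grads = batch_loss_and_grads(a, x, y, p)
        eps = 1e-6
        for w, g in zip(p.as_list(), grads):
            flat = w.ravel()
            idxs = range(0, flat.size, max(1, flat.size // 5))
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = batch_loss_and_grads(a, x, y, p)
                flat[i] = orig - eps
                lm, _ = batch_loss_and_grads(a, x, y, p)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(fd, abs=1e-4)


@pytest.fixture(scope="module")
def separable():
    # class 1 has uniformly larger features on a shared ring graph
    r = np.random.default_rng(11)
    ring = np.zeros((6, 6))
    for i in range(6):
        ring[i, (i + 1) % 6] = ring[(i + 1) % 6, i] = 1.0
    out = []
    for k in range(20):
        lab = k % 2
        x = r.standard_normal((6, 4)) + (3.0 if lab else -3.0)
        out.append(make_sample(ring, x, label=lab))
    return out


class TestTraining:
    def test_separable_set_fit_to_perfection(self, separable):
        params, losses = train(separable, TrainConfig(embedding_dim=8, seed=0))
        probs = predict_proba(separable, params)
        acc = (probs.argmax(axis=1) == [s.label for s in separable]).mean()
        assert acc == 1.0
        assert losses[-1] < losses[0]

    def test_deterministic_given_seed(self, separable):
        cfg = TrainConfig(embedding_dim=4, epochs=20, seed=7)
        _, l1 = train(separable, cfg)
        _, l2 = train(separable, cfg)
        assert l1 == l2

    def test_single_class_rejected(self, separable):
        ones = [s for s in separable if s.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            train(ones, TrainConfig())

    def test_heavy_weight_decay_shrinks_parameters(self, separable):
        # in the decay-dominated regime the weight norm keeps decreasing
        # as training continues
        norms = []
        for epochs in (25, 50, 100):
            cfg = TrainConfig(embedding_dim=4, epochs=epochs, weight_decay=5.0, seed=0)
            params, _ = train(separable, cfg)
            norms.append(np.linalg.norm(params.W0))
        fresh = np.linalg.norm(init_params(4, cfg).W0)
        assert norms[0] < fresh and norms == sorted(norms, reverse=True)


class TestPredict:
    def test_probabilities_normalized(self, separable_samples=None):
        r = np.random.default_rng(2)
        samples = [
            make_sample(
                sym(np.abs(r.standard_normal((4, 4)))),
                r.standard_normal((4, 3)),
                label=k % 2,
            )
            for k in range(6)
        ]
        p = init_params(3, TrainConfig(embedding_dim=5, seed=0))
        probs = predict_proba(samples, p)
        assert ((probs >= 0) & (probs <= 1)).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_head_gives_coin_flip(self):
        r = np.random.default_rng(4)
        s = make_sample(sym(np.abs(r.standard_normal((4, 4)))), r.standard_normal((4, 3)))
        p = init_params(3, TrainConfig(embedding_dim=5, seed=0))
        p.head_W[:] = 0.0
        p.head_b[:] = 0.0
        np.testing.assert_allclose(predict_proba([s], p), 0.5)

    def test_duplicate_sample_same_probability(self):
        r = np.random.default_rng(6)
        s = make_sample(sym(np.abs(r.standard_normal((4, 4)))), r.standard_normal((4, 3)))
        p = init_params(3, TrainConfig(embedding_dim=5, seed=0))
        probs = predict_proba([s, s], p)
        np.testing.assert_array_equal(probs[0], probs[1])


class TestPermutationInvariance:
    @pytest.mark.parametrize("feature_kind", ["cv", "ns", "os"])
    def test_prediction_invariant_under_node_relabeling(self, feature_kind):
        # CV/NS/OS features permute with the nodes; the readout is
        # node-order free, so predictions must not change
        from bfngcn import TimeSeriesMatrix, estimate_pc
        from bfngcn.features import build_feature_matrix

        r = np.random.default_rng(8)
        ts = TimeSeriesMatrix(values=r.standard_normal((10, 40)))
        adj = estimate_pc(ts)
        x = build_feature_matrix([feature_kind], ts=ts, adj=adj, adj_pc=adj)
        sample = GraphSample(adjacency=adj, features=x, label=0)
        p = init_params(x.d, TrainConfig(embedding_dim=6, seed=0))
        base = predict_proba([sample], p)[0]
        for k in range(10):
            perm = np.random.default_rng(100 + k).permutation(10)
            pa = AdjacencyMatrix(
                raw=adj.raw[np.ix_(perm, perm)], estimator="pc"
            )
            normalize_adjacency(pa)
            # rows of X travel with their nodes; columns keep their meaning
            px = NodeFeatureMatrix(
                values=x.values[perm], feature_set=x.feature_set,
                column_names=list(x.column_names),
            )
            ps = GraphSample(adjacency=pa, features=px, label=0)
            got = predict_proba([ps], p)[0]
            np.testing.assert_allclose(got, base, atol=1e-8)
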