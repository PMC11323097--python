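import numpy as np
import pytest
from scipy.special import expit

from pidap import AssociationMatrix, GraphVAE, GvaeConfig, multi_channel_embed
from pidap.gvae import (
    GcnParams,
    decode,
    encode,
    gcn_layer,
    gvae_loss,
    normalize_adjacency,
    reparameterize,
    train_channel,
)
from pidap.similarity import SimilarityNetwork, build_all_networks


def make_net(S, channel="pirna_seq"):
    return SimilarityNetwork(
        S=np.asarray(S, float), node_ids=[f"n{i}" for i in range(len(S))], channel=channel
    )


class TestNormalizeAdjacency:
    def test_identity_network_is_fixed_point(self):
        adj = normalize_adjacency(make_net(np.eye(2)))
        assert np.array_equal(adj.a_hat, np.eye(2))

    def test_complete_graph_two_nodes(self):
        adj = normalize_adjacency(make_net(np.ones((2, 2))))
        assert np.allclose(adj.a_hat, 0.5, atol=1e-15)

    def test_symmetry_preserved(self, two_block_network):
        net, _ = two_block_network
        adj = normalize_adjacency(net)
        assert np.array_equal(adj.a_hat, adj.a_hat.T)
        assert np.abs(adj.a_hat - adj.a_hat.T).max() < 1e-12


class TestGcnLayer:
    def test_identity_propagation(self):
        adj = normalize_adjacency(make_net(np.eye(3)))
        H = np.abs(np.random.default_rng(0).normal(size=(3, 4)))
        out = gcn_layer(H, adj, np.eye(4), activation="relu")
        assert np.allclose(out, H)

    def test_relu_zeroes_negatives(self):
        adj = normalize_adjacency(make_net(np.eye(2)))
        H = np.array([[-1.0, 2.0], [3.0, -4.0]])
        out = gcn_layer(H, adj, np.eye(2), activation="relu")
        assert np.array_equal(out, np.array([[0.0, 2.0], [3.0, 0.0]]))

    def test_matches_triple_product_oracle(self):
        rng = np.random.default_rng(5)
        S = rng.uniform(0, 1, (4, 4))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        adj = normalize_adjacency(make_net(S))
        H, W = rng.normal(size=(4, 6)), rng.normal(size=(6, 2))
        expected = np.maximum(adj.a_hat @ (H @ W), 0)  # associativity: same product
        assert np.allclose(gcn_layer(H, adj, W), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        adj = normalize_adjacency(make_net(np.eye(2)))
        with pytest.raises(ValueError):
            gcn_layer(np.ones((2, 3)), adj, np.ones((4, 2)))


class TestEncode:
    def test_zero_weights_give_prior(self):
        adj = normalize_adjacency(make_net(np.eye(3)))
        params = GcnParams(np.zeros((5, 4)), np.zeros((4, 2)), np.zeros((4, 2)))
        mu, log_sigma = encode(np.ones((3, 5)), adj, params)
        assert np.all(mu == 0) and np.all(log_sigma == 0)

    def test_default_output_shapes(self, two_block_network):
        net, _ = two_block_network
        X = np.random.default_rng(1).normal(size=(net.n_nodes, 7))
        model = GraphVAE(epochs=2, random_state=0).fit(net, X)
        emb = model.embeddings_[0]
        assert emb.mu.shape == (net.n_nodes, 16)
        assert emb.log_sigma.shape == (net.n_nodes, 16)

    def test_first_layer_shared_between_heads(self):
        rng = np.random.default_rng(2)
        adj = normalize_adjacency(make_net(np.eye(3)))
        X = rng.normal(size=(3, 5))
        params = GcnParams(
            rng.normal(size=(5, 4)), rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        )
        mu0, ls0 = encode(X, adj, params)
        params.w0 = params.w0 + 0.1
        mu1, ls1 = encode(X, adj, params)
        assert not np.allclose(mu0, mu1)
        assert not np.allclose(ls0, ls1)


class TestReparameterize:
    def test_zero_sigma_returns_mu(self):
        mu = np.ones((3, 2))
        z = reparameterize(mu, np.full((3, 2), -745.0), np.random.default_rng(0))
        assert np.allclose(z, mu)

    def test_deterministic_under_seed(self):
        mu, ls = np.zeros((4, 3)), np.zeros((4, 3))
        z1 = reparameterize(mu, ls, np.random.default_rng(9))
        z2 = reparameterize(mu, ls, np.random.default_rng(9))
        assert np.array_equal(z1, z2)

    def test_monte_carlo_mean_is_mu(self):
        mu = np.array([[1.5]])
        draws = np.array(
            [
                reparameterize(mu, np.zeros((1, 1)), rng)[0, 0]
                for rng in [np.random.default_rng(s) for s in range(100_000)]
            ]
        )
        assert abs(draws.mean() - 1.5) < 3.0 / np.sqrt(100_000)


class TestDecode:
    def test_zero_latents_give_half(self):
        assert np.allclose(decode(np.zeros((3, 2))), 0.5)

    def test_scaled_orthogonal_rows(self):
        Z = 50.0 * np.eye(2)
        probs = decode(Z)
        assert np.allclose(np.diag(probs), 1.0)
        assert np.allclose(probs[0, 1], 0.5)

    def test_symmetric_for_random_latents(self):
        Z = np.random.default_rng(3).normal(size=(6, 4))
        probs = decode(Z)
        assert np.abs(probs - probs.T).max() < 1e-12


class TestGvaeLoss:
    def test_kl_zero_at_prior(self):
        report = gvae_loss(
            np.full((2, 2), 0.5), np.eye(2), np.zeros((2, 3)), np.zeros((2, 3))
        )
        assert report.kl == 0.0

    def test_kl_positive_off_prior(self):
        report = gvae_loss(
            np.full((2, 2), 0.5), np.eye(2), np.ones((2, 3)), np.zeros((2, 3))
        )
        assert report.kl > 0.0

    def test_kl_closed_form_single_unit(self):
        report = gvae_loss(
            np.array([[0.5]]), np.array([[1.0]]), np.array([[1.0]]), np.array([[0.0]])
        )
        assert report.kl == pytest.approx(0.5, abs=1e-15)

    def test_total_combines_beta(self):
        probs, S = np.full((2, 2), 0.5), np.eye(2)
        mu, ls = np.ones((2, 2)), np.zeros((2, 2))
        r1 = gvae_loss(probs, S, mu, ls, beta=1.0)
        r2 = gvae_loss(probs, S, mu, ls, beta=2.0)
        assert r2.total == pytest.approx(r1.reconstruction + 2.0 * r1.kl)


class TestTrainingGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """The backprop oracle: central finite differences on a tiny channel."""
        rng = np.random.default_rng(11)
        p, f, h1, h2 = 5, 4, 3, 2
        S = rng.uniform(0, 1, (p, p))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        net = make_net(S)
        X = rng.normal(size=(p, f))
        model = GraphVAE(hidden1=h1, hidden2=h2, beta=0.7, random_state=0)
        adj = normalize_adjacency(net)
        params = GcnParams(
            rng.normal(size=(f, h1)), rng.normal(size=(h1, h2)), rng.normal(size=(h1, h2))
        )

        def loss_at(params, eps_rng_seed=123):
            grads = [np.zeros_like(w) for w in params.as_list()]
            report = model._channel_grads(
                X, adj, S, params, grads, np.random.default_rng(eps_rng_seed), 0
            )
            return report.total, grads

        _, analytic = loss_at(params)
        h = 1e-6
        for wi, w in enumerate(params.as_list()):
            flat_idx = [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]
            for i, j in flat_idx:
                plus = params.copy()
                plus.as_list()[wi][i, j] += h
                minus = params.copy()
                minus.as_list()[wi][i, j] -= h
                fd = (loss_at(plus)[0] - loss_at(minus)[0]) / (2 * h)
                assert analytic[wi][i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def recovery_score(z, block):
    """Mean within-block minus mean between-block cosine similarity."""
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    u = z / np.where(norms == 0, 1.0, norms)
    cos = u @ u.T
    same = block[:, None] == block[None, :]
    np.fill_diagonal(same, False)
    off = ~np.eye(len(block), dtype=bool)
    return cos[same].mean() - cos[~same & off].mean()


class TestTrainChannel:
    def test_loss_decreases_over_training(self, two_block_network):
        net, _ = two_block_network
        X = np.random.default_rng(0).normal(size=(net.n_nodes, 8))
        model = GraphVAE(random_state=0).fit(net, X)
        history = model.loss_history_[0]
        assert len(history) == 50
        assert history[-1].total < history[0].total

    def test_same_seed_reproducible_bitwise(self, two_block_network):
        net, _ = two_block_network
        X = np.random.default_rng(0).normal(size=(net.n_nodes, 8))
        emb1 = train_channel(net, X, GvaeConfig(seed=5))
        emb2 = train_channel(net, X, GvaeConfig(seed=5))
        assert np.array_equal(emb1.mu, emb2.mu)
        assert np.array_equal(emb1.log_sigma, emb2.log_sigma)

    def test_planted_blocks_recovered(self, two_block_network):
        net, block = two_block_network
        X = np.random.default_rng(7).normal(size=(net.n_nodes, 8))
        scores = [
            recovery_score(train_channel(net, X, GvaeConfig(seed=s)).z, block)
            for s in range(5)
        ]
        assert sum(s > 0 for s in scores) >= 4
        assert np.mean(scores) > 0

    def test_graph_free_baseline_degrades_recovery(self, two_block_network):
        """With the adjacency replaced by identity the encoder cannot exploit
        the planted graph structure, so recovery drops on average."""
        net, block = two_block_network
        X = np.random.default_rng(7).normal(size=(net.n_nodes, 8))
        gcn, plain = [], []
        for s in range(5):
            gcn.append(recovery_score(train_channel(net, X, GvaeConfig(seed=s)).z, block))
            plain.append(
                recovery_score(
                    train_channel(net, X, GvaeConfig(seed=s, encoder="identity")).z, block
                )
            )
        assert np.mean(gcn) > np.mean(plain)


class TestMultiChannel:
    def test_shared_weights_within_node_class(self, fixture_data):
        seqs, assoc, dag, _ = fixture_data
        nets = build_all_networks(seqs, assoc, dag)
        result = multi_channel_embed(nets, assoc, GvaeConfig(epochs=5, seed=0))
        assert result.models["pirna_seq"] is result.models["pirna_gip"]
        assert result.models["disease_sem"] is result.models["disease_gip"]
        w_seq = result.models["pirna_seq"].params_.w0
        w_gip = result.models["pirna_gip"].params_.w0
        assert np.array_equal(w_seq, w_gip)

    def test_embedding_shapes(self, fixture_data):
        seqs, assoc, dag, _ = fixture_data
        m, n = assoc.shape
        nets = build_all_networks(seqs, assoc, dag)
        result = multi_channel_embed(nets, assoc, GvaeConfig(epochs=5, seed=0))
        assert result.embeddings["pirna_seq"].z.shape == (m, 16)
        assert result.embeddings["pirna_gip"].z.shape == (m, 16)
        assert result.embeddings["disease_sem"].z.shape == (n, 16)
        assert result.embeddings["disease_gip"].z.shape == (n, 16)

    def test_sharing_can_be_disabled(self, fixture_data):
        seqs, assoc, dag, _ = fixture_data
        nets = build_all_networks(seqs, assoc, dag)
        result = multi_channel_embed(
            nets, assoc, GvaeConfig(epochs=5, seed=0, share_params=False)
        )
        assert result.models["pirna_seq"] is not result.models["pirna_gip"]
        assert not np.array_equal(
            result.models["pirna_seq"].params_.w0,
            result.models["pirna_gip"].params_.w0,
        )
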