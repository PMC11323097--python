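"""Variational graph autoencoder over similarity networks.

Each channel is one similarity network.  The encoder is a two-layer graph
convolution: a shared first layer H1 = ReLU(A_hat X W0) followed by separate
linear heads mu = A_hat H1 W_mu and log_sigma = A_hat H1 W_sigma, where
A_hat = D^{-1/2} (S) D^{-1/2} is the symmetrically normalized adjacency (the
unit diagonal of S serves as the self-loop).  Latents are sampled with the
reparameterization trick Z = mu + sigma * eps, and the decoder reconstructs
the similarity matrix as sigmoid(Z Z^T).  The loss is a positively-reweighted
binary cross-entropy between the reconstruction and the similarity entries
(used as soft labels) plus a per-node-averaged Gaussian KL term against the
standard-normal prior.

Channels of the same node class (the two piRNA channels, the two disease
channels) can be trained with one shared parameter set: per epoch, gradients
from every channel accumulate into the same weights before a single Adam step.

Everything runs full-batch in numpy with analytic gradients; graphs of the
sizes handled here fit comfortably in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .io import AssociationMatrix
from .similarity import SimilarityNetwork

__all__ = [
    "GcnParams",
    "NormalizedAdjacency",
    "ChannelEmbedding",
    "GvaeLossReport",
    "GvaeConfig",
    "GraphVAE",
    "normalize_adjacency",
    "gcn_layer",
    "encode",
    "reparameterize",
    "decode",
    "gvae_loss",
    "train_channel",
    "multi_channel_embed",
    "MultiChannelResult",
]


@dataclass
class GcnParams:
    """Weights of the two-layer encoder: shared W0 and the mu/log-sigma heads."""

    w0: np.ndarray
    w_mu: np.ndarray
    w_sigma: np.ndarray

    def as_list(self) -> list[np.ndarray]:
        return [self.w0, self.w_mu, self.w_sigma]

    def copy(self) -> "GcnParams":
        return GcnParams(self.w0.copy(), self.w_mu.copy(), self.w_sigma.copy())


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically normalized adjacency A_hat = D^{-1/2} A_tilde D^{-1/2}."""

    a_tilde: np.ndarray
    degrees: np.ndarray
    a_hat: np.ndarray


@dataclass(frozen=True)
class ChannelEmbedding:
    """Latent mean, log-std and sampled vectors for one channel's nodes."""

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray
    channel: str
    node_ids: tuple[str, ...]


@dataclass(frozen=True)
class GvaeLossReport:
    reconstruction: float
    kl: float
    total: float
    epoch: int


@dataclass(frozen=True)
class GvaeConfig:
    """Training configuration for the graph VAE.

    hidden1/hidden2 are the encoder layer widths (defaults 48 and 16), trained
    with Adam at learning rate 0.001 for 50 epochs; beta weights the KL term.
    """

    hidden1: int = 48
    hidden2: int = 16
    learning_rate: float = 1e-3
    epochs: int = 50
    beta: float = 1.0
    encoder: str = "gcn"  # 'gcn' or 'identity' (plain-VAE baseline)
    share_params: bool = True
    seed: int = 0


def normalize_adjacency(net: SimilarityNetwork) -> NormalizedAdjacency:
    """Symmetric GCN normalization of a similarity network.

    The network's unit diagonal provides the self-loop, so A_tilde = S.
    """
    s = np.asarray(net.S, dtype=float)
    deg = s.sum(axis=1)
    assert (deg > 0).all(), "zero-degree node despite unit diagonal"
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    a_hat = d_inv_sqrt[:, None] * s * d_inv_sqrt[None, :]
    a_hat = (a_hat + a_hat.T) / 2.0
    return NormalizedAdjacency(a_tilde=s, degrees=deg, a_hat=a_hat)


def gcn_layer(
    H: np.ndarray,
    adj: NormalizedAdjacency,
    W: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph convolution: activation(A_hat H W)."""
    H = np.asarray(H, dtype=float)
    if H.shape[0] != adj.a_hat.shape[0]:
        raise ValueError("feature rows do not match adjacency size")
    if H.shape[1] != W.shape[0]:
        raise ValueError("feature width does not match weight rows")
    out = adj.a_hat @ H @ W
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "none":
        return out
    raise ValueError("activation must be 'relu' or 'none'")


def encode(
    X: np.ndarray, adj: NormalizedAdjacency, params: GcnParams
) -> tuple[np.ndarray, np.ndarray]:
    """Two-layer encoding: shared ReLU layer, then linear mu/log-sigma heads."""
    hidden = gcn_layer(X, adj, params.w0, activation="relu")
    mu = gcn_layer(hidden, adj, params.w_mu, activation="none")
    log_sigma = gcn_layer(hidden, adj, params.w_sigma, activation="none")
    return mu, log_sigma


def reparameterize(
    mu: np.ndarray, log_sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Z = mu + exp(log_sigma) * eps with eps ~ N(0, 1) i.i.d."""
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma must have equal shapes")
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(log_sigma) * eps


def decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: elementwise logistic of Z Z^T."""
    logits = Z @ Z.T
    logits = (logits + logits.T) / 2.0
    return expit(logits)


def _positive_weight(S: np.ndarray) -> float:
    total = float(S.sum())
    if total <= 0.0:
        return 1.0
    p2 = S.size
    return (p2 - total) / total


def gvae_loss(
    probabilities: np.ndarray,
    target: SimilarityNetwork | np.ndarray,
    mu: np.ndarray,
    log_sigma: np.ndarray,
    beta: float = 1.0,
    epoch: int = 0,
) -> GvaeLossReport:
    """Reweighted soft-label BCE reconstruction plus per-node Gaussian KL.

    reconstruction = mean_ij [ -w S_ij log p_ij - (1 - S_ij) log(1 - p_ij) ]
    with positive reweighting w = (p^2 - sum S) / sum S, and
    kl = (1/p) sum_nodes 1/2 sum_dims (exp(2 log_sigma) + mu^2 - 1 - 2 log_sigma).
    """
    S = target.S if isinstance(target, SimilarityNetwork) else np.asarray(target)
    p = np.clip(probabilities, 1e-7, 1.0 - 1e-7)
    w = _positive_weight(S)
    recon = float(np.mean(-w * S * np.log(p) - (1.0 - S) * np.log1p(-p)))
    n_nodes = mu.shape[0]
    kl = float(
        0.5 * np.sum(np.exp(2.0 * log_sigma) + mu**2 - 1.0 - 2.0 * log_sigma) / n_nodes
    )
    return GvaeLossReport(
        reconstruction=recon, kl=kl, total=recon + beta * kl, epoch=epoch
    )


class _Adam:
    """Adam with bias-corrected first/second moments (betas 0.9 / 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GraphVAE(BaseEstimator):
    """Graph variational autoencoder trained on one or more similarity networks.

    All networks passed to :meth:`fit` must share one node set and one feature
    matrix; their gradients accumulate into a single shared parameter set
    (multi-channel weight sharing).  With ``encoder='identity'`` the adjacency
    is replaced by the identity matrix, which turns the model into a plain VAE
    on the node features — the graph-free baseline.

    Parameters
    ----------
    hidden1, hidden2 : int
        Encoder layer widths; the latent dimension is ``hidden2``.
    learning_rate : float
        Adam step size.
    epochs : int
        Full-batch training epochs.
    beta : float
        Weight of the KL term in the total loss.
    encoder : {'gcn', 'identity'}
        Graph convolution or the graph-free baseline.
    random_state : int or None
        Seed for weight initialization and latent sampling.

    Attributes
    ----------
    params_ : GcnParams
        Fitted encoder weights (shared across the fitted channels).
    embeddings_ : list of ChannelEmbedding
        Deterministic embeddings (Z = mu) of each fitted channel.
    loss_history_ : list of list of GvaeLossReport
        Per-channel loss trajectory, one report per epoch.
    """

    def __init__(
        self,
        hidden1: int = 48,
        hidden2: int = 16,
        learning_rate: float = 1e-3,
        epochs: int = 50,
        beta: float = 1.0,
        encoder: str = "gcn",
        random_state: int | None = None,
    ):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.beta = beta
        self.encoder = encoder
        self.random_state = random_state

    def _adjacencies(
        self, nets: list[SimilarityNetwork]
    ) -> list[NormalizedAdjacency]:
        if self.encoder == "gcn":
            return [normalize_adjacency(net) for net in nets]
        if self.encoder == "identity":
            out = []
            for net in nets:
                eye = np.eye(net.n_nodes)
                out.append(NormalizedAdjacency(eye, np.ones(net.n_nodes), eye))
            return out
        raise ValueError("encoder must be 'gcn' or 'identity'")

    def fit(
        self,
        networks: SimilarityNetwork | list[SimilarityNetwork],
        X: np.ndarray,
    ) -> "GraphVAE":
        nets = [networks] if isinstance(networks, SimilarityNetwork) else list(networks)
        X = np.asarray(X, dtype=float)
        p = X.shape[0]
        for net in nets:
            if net.n_nodes != p:
                raise ValueError("all channels must share one node set")
        rng = np.random.default_rng(self.random_state)
        params = GcnParams(
            w0=_glorot(rng, X.shape[1], self.hidden1),
            w_mu=_glorot(rng, self.hidden1, self.hidden2),
            w_sigma=_glorot(rng, self.hidden1, self.hidden2),
        )
        adjs = self._adjacencies(nets)
        opt = _Adam(params.as_list(), self.learning_rate)
        history: list[list[GvaeLossReport]] = [[] for _ in nets]
        for epoch in range(self.epochs):
            grads = [np.zeros_like(w) for w in params.as_list()]
            for ch, (net, adj) in enumerate(zip(nets, adjs)):
                report = self._channel_grads(X, adj, net.S, params, grads, rng, epoch)
                if not np.isfinite(report.total):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} on channel {net.channel}"
                    )
                history[ch].append(report)
            opt.step(grads)
        self.params_ = params
        self.loss_history_ = history
        self.n_features_in_ = X.shape[1]
        self.embeddings_ = [
            self._embed(X, adj, net) for net, adj in zip(nets, adjs)
        ]
        return self

    def _embed(
        self, X: np.ndarray, adj: NormalizedAdjacency, net: SimilarityNetwork
    ) -> ChannelEmbedding:
        mu, log_sigma = encode(X, adj, self.params_)
        return ChannelEmbedding(
            mu=mu,
            log_sigma=log_sigma,
            z=mu,  # deterministic inference mode
            channel=net.channel,
            node_ids=tuple(net.node_ids),
        )

    def transform(
        self,
        networks: SimilarityNetwork | list[SimilarityNetwork],
        X: np.ndarray,
    ) -> list[ChannelEmbedding]:
        """Deterministic embeddings (Z = mu) under the fitted weights."""
        nets = [networks] if isinstance(networks, SimilarityNetwork) else list(networks)
        X = np.asarray(X, dtype=float)
        adjs = self._adjacencies(nets)
        return [self._embed(X, adj, net) for net, adj in zip(nets, adjs)]

    def fit_transform(self, networks, X) -> list[ChannelEmbedding]:
        return self.fit(networks, X).embeddings_

    def _channel_grads(
        self,
        X: np.ndarray,
        adj: NormalizedAdjacency,
        S: np.ndarray,
        params: GcnParams,
        grads: list[np.ndarray],
        rng: np.random.Generator,
        epoch: int,
    ) -> GvaeLossReport:
        """Forward pass plus analytic backprop; accumulates into ``grads``."""
        A_hat = adj.a_hat
        p = X.shape[0]
        m0 = A_hat @ X
        h_pre = m0 @ params.w0
        h1 = np.maximum(h_pre, 0.0)
        hm = A_hat @ h1
        mu = hm @ params.w_mu
        log_sigma = hm @ params.w_sigma
        sigma = np.exp(log_sigma)
        eps = rng.standard_normal(mu.shape)
        Z = mu + sigma * eps
        logits = Z @ Z.T
        probs = expit(logits)
        w = _positive_weight(S)
        # numerically stable BCE-with-logits: w*S*softplus(-L) + (1-S)*softplus(L)
        softplus = np.logaddexp(0.0, logits)
        recon = float(np.mean(w * S * (softplus - logits) + (1.0 - S) * softplus))
        kl = float(
            0.5 * np.sum(np.exp(2.0 * log_sigma) + mu**2 - 1.0 - 2.0 * log_sigma) / p
        )
        total = recon + self.beta * kl

        n = S.size
        d_logits = (-w * S * (1.0 - probs) + (1.0 - S) * probs) / n
        dZ = (d_logits + d_logits.T) @ Z
        d_mu = dZ + self.beta * mu / p
        d_log_sigma = dZ * eps * sigma + self.beta * (np.exp(2.0 * log_sigma) - 1.0) / p
        grads[1] += hm.T @ d_mu
        grads[2] += hm.T @ d_log_sigma
        d_hm = d_mu @ params.w_mu.T + d_log_sigma @ params.w_sigma.T
        d_h1 = A_hat @ d_hm  # A_hat symmetric
        d_h_pre = d_h1 * (h_pre > 0.0)
        grads[0] += m0.T @ d_h_pre
        return GvaeLossReport(reconstruction=recon, kl=kl, total=total, epoch=epoch)


def train_channel(
    net: SimilarityNetwork,
    X: np.ndarray,
    cfg: GvaeConfig | None = None,
    seed: int | None = None,
) -> ChannelEmbedding:
    """Train a single-channel graph VAE and return its deterministic embedding."""
    cfg = cfg or GvaeConfig()
    model = GraphVAE(
        hidden1=cfg.hidden1,
        hidden2=cfg.hidden2,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        beta=cfg.beta,
        encoder=cfg.encoder,
        random_state=cfg.seed if seed is None else seed,
    )
    return model.fit_transform(net, X)[0]


@dataclass(frozen=True)
class MultiChannelResult:
    """Embeddings of all four channels plus the models that produced them."""

    embeddings: dict[str, ChannelEmbedding]
    models: dict[str, GraphVAE]


def multi_channel_embed(
    nets: dict[str, SimilarityNetwork],
    assoc: AssociationMatrix,
    cfg: GvaeConfig | None = None,
    seed: int | None = None,
) -> MultiChannelResult:
    """Train the four channels with within-class weight sharing.

    piRNA channels use the association-matrix rows as node features, disease
    channels the columns.  With ``cfg.share_params`` (default) the two piRNA
    channels are trained jointly under one parameter set, and likewise the two
    disease channels; disabling it trains four independent models.
    """
    cfg = cfg or GvaeConfig()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    X_p = assoc.A.astype(float)
    X_d = assoc.A.T.astype(float)

    def make(seed_i: int) -> GraphVAE:
        return GraphVAE(
            hidden1=cfg.hidden1,
            hidden2=cfg.hidden2,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            beta=cfg.beta,
            encoder=cfg.encoder,
            random_state=int(seed_i),
        )

    embeddings: dict[str, ChannelEmbedding] = {}
    models: dict[str, GraphVAE] = {}
    groups = [
        (("pirna_seq", "pirna_gip"), X_p, seeds[0]),
        (("disease_sem", "disease_gip"), X_d, seeds[1]),
    ]
    if cfg.share_params:
        for channels, X, s in groups:
            model = make(s)
            embs = model.fit_transform([nets[c] for c in channels], X)
            for c, e in zip(channels, embs):
                embeddings[c] = e
                models[c] = model
    else:
        extra = iter(seeds)
        for channels, X, _ in groups:
            for c in channels:
                model = make(next(extra))
                embeddings[c] = model.fit_transform(nets[c], X)[0]
                models[c] = model
    return MultiChannelResult(embeddings=embeddings, models=models)
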