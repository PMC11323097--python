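"""Scoring of piRNA-disease pairs from concatenated channel embeddings.

A pair (p, d) is represented by the concatenation (Z_PS[p] | Z_DS[d] |
Z_PG[p] | Z_dG[d]) of the four channel embeddings — 64 dimensions at the
default latent width of 16 — and scored by a three-layer fully connected
network (64 -> 48 -> 16 -> 1, ReLU hidden activations, logistic output)
trained with binary cross-entropy.  A pair is called positive iff its score
strictly exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .gvae import ChannelEmbedding
from .io import PairPrediction

__all__ = [
    "PairFeatures",
    "MlpParams",
    "PairMLPClassifier",
    "build_pair_features",
    "mlp_forward",
    "predict",
    "train_classifier",
]

BLOCK_ORDER = ("pirna_seq", "disease_sem", "pirna_gip", "disease_gip")


@dataclass(frozen=True)
class PairFeatures:
    """Concatenated features for a list of (piRNA, disease) pairs.

    ``labels`` uses -1 for pairs of unknown status.
    """

    pirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    X: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class MlpParams:
    """Weights and biases of the three-layer pair classifier."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or len(self.biases) != 3:
            raise ValueError("the pair classifier has exactly three layers")


def build_pair_features(
    embeddings: dict[str, ChannelEmbedding],
    pairs: list[tuple[str, str, int]],
) -> PairFeatures:
    """Concatenate Z_PS[p], Z_DS[d], Z_PG[p], Z_dG[d] for each (p, d, label).

    Labels may be 0, 1 or -1 (unknown).  Input order is preserved.
    """
    for name in BLOCK_ORDER:
        if name not in embeddings:
            raise KeyError(f"missing channel embedding {name!r}")
    p_index = {pid: i for i, pid in enumerate(embeddings["pirna_seq"].node_ids)}
    d_index = {did: i for i, did in enumerate(embeddings["disease_sem"].node_ids)}
    rows, p_ids, d_ids, labels = [], [], [], []
    for p, d, label in pairs:
        if p not in p_index:
            raise KeyError(f"unknown piRNA id {p!r}")
        if d not in d_index:
            raise KeyError(f"unknown disease id {d!r}")
        pi, di = p_index[p], d_index[d]
        rows.append(
            np.concatenate(
                [
                    embeddings["pirna_seq"].z[pi],
                    embeddings["disease_sem"].z[di],
                    embeddings["pirna_gip"].z[pi],
                    embeddings["disease_gip"].z[di],
                ]
            )
        )
        p_ids.append(p)
        d_ids.append(d)
        labels.append(label)
    return PairFeatures(
        pirna_ids=tuple(p_ids),
        disease_ids=tuple(d_ids),
        X=np.vstack(rows) if rows else np.empty((0, 0)),
        labels=np.asarray(labels, dtype=int),
    )


def mlp_forward(params: MlpParams, X: np.ndarray) -> np.ndarray:
    """Forward pass: two ReLU hidden layers, logistic output, scores in (0,1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match first layer "
            f"({params.weights[0].shape[0]})"
        )
    h = np.maximum(X @ params.weights[0] + params.biases[0], 0.0)
    h = np.maximum(h @ params.weights[1] + params.biases[1], 0.0)
    out = h @ params.weights[2] + params.biases[2]
    return expit(out).ravel()


def predict(params: MlpParams, features: PairFeatures) -> list[PairPrediction]:
    """Score pairs and call positives by the strict > 0.5 rule."""
    scores = mlp_forward(params, features.X)
    return [
        PairPrediction(p, d, float(s), int(s > 0.5))
        for p, d, s in zip(features.pirna_ids, features.disease_ids, scores)
    ]


class PairMLPClassifier(BaseEstimator, ClassifierMixin):
    """Three-layer fully connected pair scorer (sklearn-compatible).

    Fitting minimizes binary cross-entropy with Adam (learning rate 0.001 by
    default) and stops early once the training loss has not improved by more
    than ``tol`` for ``patience`` consecutive epochs.  Prediction applies the
    strict rule: call 1 iff score > 0.5 (a score of exactly 0.5 is negative).

    Attributes
    ----------
    params_ : MlpParams
        Fitted weight matrices and biases.
    loss_curve_ : list of float
        Training loss per epoch.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        hidden1: int = 48,
        hidden2: int = 16,
        learning_rate: float = 1e-3,
        epochs: int = 200,
        tol: float = 1e-5,
        patience: int = 10,
        random_state: int | None = None,
    ):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.tol = tol
        self.patience = patience
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PairMLPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        present = set(np.unique(y))
        if present != {0, 1}:
            raise ValueError(
                f"training set must contain both classes; found labels {sorted(present)}"
            )
        net = MLPClassifier(
            hidden_layer_sizes=(self.hidden1, self.hidden2),
            activation="relu",
            solver="adam",
            alpha=0.0,
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            tol=self.tol,
            n_iter_no_change=self.patience,
            shuffle=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(X, y)
        self.params_ = MlpParams(
            weights=[w.copy() for w in net.coefs_],
            biases=[b.copy().ravel() for b in net.intercepts_],
        )
        self.loss_curve_ = list(net.loss_curve_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return mlp_forward(self.params_, X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0.5).astype(int)


def train_classifier(
    features: PairFeatures,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    seed: int | None = None,
) -> PairMLPClassifier:
    """Fit the pair classifier on labeled features (labels must be 0/1)."""
    if (features.labels < 0).any():
        raise ValueError("training features contain unlabeled pairs")
    model = PairMLPClassifier(
        epochs=epochs, learning_rate=learning_rate, random_state=seed
    )
    return model.fit(features.X, features.labels)
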