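"""Negative sampling, five-fold cross-validation, metrics and ablations.

The experimental protocol: known associations are the positives; an equal
number of negatives is drawn uniformly without replacement from the unknown
(zero) cells of the association matrix.  The pooled pair list is split into
five stratified folds.  For each fold the test-fold positives are masked out
of the association matrix before the GIP kernels and the GVAE node features
are built (leakage-safe default; a full-matrix GIP mode is available),
embeddings are trained on the masked data, the pair classifier is fitted on
the training pairs and evaluated on the held-out fold.  Reported metrics:
AUC, AUPR, accuracy, precision, recall, F1 and MCC, per fold plus the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .classifier import build_pair_features, train_classifier
from .gvae import GvaeConfig, multi_channel_embed, train_channel
from .io import AssociationMatrix, DiseaseDAG, SequenceSet
from .similarity import SimilarityNetwork, build_all_networks
from scipy.special import expit

__all__ = [
    "FoldPlan",
    "PipelineConfig",
    "METRICS",
    "VARIANTS",
    "sample_negatives",
    "make_folds",
    "compute_metrics",
    "run_cv",
    "run_ablation",
]

METRICS = ("auc", "aupr", "accuracy", "precision", "recall", "f1", "mcc")
VARIANTS = ("full", "no_gvae", "no_nn", "association_only", "attribution_only")


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint test-index sets partitioning the sampled pair list."""

    seed: int
    folds: tuple[np.ndarray, ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration of the cross-validated pipeline.

    ``gip_from='train'`` (default) rebuilds the GIP kernels from the
    training-fold-masked association matrix; ``'full'`` uses the complete
    matrix for the kernels (test links then leak into the similarity graphs).
    """

    k: int = 3
    alpha: float = 0.5
    gip_bandwidth: str = "normalized"
    gip_from: str = "train"
    neg_ratio: float = 1.0
    n_folds: int = 5
    gvae: GvaeConfig = field(default_factory=GvaeConfig)
    classifier_epochs: int = 200
    classifier_lr: float = 1e-3


def sample_negatives(
    assoc: AssociationMatrix,
    ratio: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform sample without replacement from the zero cells of the matrix.

    Returns an array of (row, column) index pairs of size
    ``round(ratio * #positives)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    zeros = np.argwhere(assoc.A == 0)
    n_pos = int(assoc.A.sum())
    count = int(round(ratio * n_pos))
    if count > len(zeros):
        raise ValueError(
            f"requested {count} negatives but only {len(zeros)} unknown pairs exist"
        )
    chosen = rng.choice(len(zeros), size=count, replace=False)
    return zeros[np.sort(chosen)]


def make_folds(
    labels: np.ndarray, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified k-fold partition of the pair list, deterministic under seed."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"cannot split {len(labels)} pairs into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(test for _, test in skf.split(np.zeros(len(labels)), labels))
    return FoldPlan(seed=seed, folds=folds)


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC (rank statistic, ties averaged), AUPR (PR step integral) and the
    confusion-matrix metrics at the strict > threshold rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics need both classes present in the labels")
    preds = (scores > threshold).astype(int)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
        "mcc": float(matthews_corrcoef(labels, preds)),
    }


def _mask_cells(assoc: AssociationMatrix, cells: np.ndarray) -> AssociationMatrix:
    masked = assoc.copy()
    if len(cells):
        masked.A[cells[:, 0], cells[:, 1]] = 0
    return masked


def _variant_pair_features(
    variant: str,
    embeddings: dict | None,
    nets: dict[str, SimilarityNetwork],
    pairs: list[tuple[str, str, int]],
):
    """Pair feature matrix for the classifier-based variants."""
    if variant in ("full",):
        return build_pair_features(embeddings, pairs)
    if variant == "association_only":
        sub = {k: embeddings[k] for k in ("pirna_seq", "disease_sem")}
        return _concat_two_channels(sub, pairs, "pirna_seq", "disease_sem")
    if variant == "attribution_only":
        sub = {k: embeddings[k] for k in ("pirna_gip", "disease_gip")}
        return _concat_two_channels(sub, pairs, "pirna_gip", "disease_gip")
    if variant == "no_gvae":
        return _similarity_row_features(nets, pairs)
    raise ValueError(f"unknown feature variant {variant!r}")


def _concat_two_channels(embeddings, pairs, p_channel, d_channel):
    from .classifier import PairFeatures

    p_emb = embeddings[p_channel]
    d_emb = embeddings[d_channel]
    p_index = {pid: i for i, pid in enumerate(p_emb.node_ids)}
    d_index = {did: i for i, did in enumerate(d_emb.node_ids)}
    rows = [
        np.concatenate([p_emb.z[p_index[p]], d_emb.z[d_index[d]]])
        for p, d, _ in pairs
    ]
    return PairFeatures(
        pirna_ids=tuple(p for p, _, _ in pairs),
        disease_ids=tuple(d for _, d, _ in pairs),
        X=np.vstack(rows),
        labels=np.asarray([lbl for _, _, lbl in pairs], dtype=int),
    )


def _similarity_row_features(nets, pairs):
    from .classifier import PairFeatures

    p_index = {pid: i for i, pid in enumerate(nets["pirna_seq"].node_ids)}
    d_index = {did: i for i, did in enumerate(nets["disease_sem"].node_ids)}
    rows = [
        np.concatenate(
            [
                nets["pirna_seq"].S[p_index[p]],
                nets["disease_sem"].S[d_index[d]],
                nets["pirna_gip"].S[p_index[p]],
                nets["disease_gip"].S[d_index[d]],
            ]
        )
        for p, d, _ in pairs
    ]
    return PairFeatures(
        pirna_ids=tuple(p for p, _, _ in pairs),
        disease_ids=tuple(d for _, d, _ in pairs),
        X=np.vstack(rows),
        labels=np.asarray([lbl for _, _, lbl in pairs], dtype=int),
    )


def _train_variant_embeddings(
    variant: str,
    nets: dict[str, SimilarityNetwork],
    assoc_train: AssociationMatrix,
    cfg: PipelineConfig,
    seed: int,
):
    if variant == "no_gvae":
        return None
    if variant == "association_only":
        X_p = assoc_train.A.astype(float)
        X_d = assoc_train.A.T.astype(float)
        gcfg = cfg.gvae
        rng = np.random.default_rng(seed)
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        return {
            "pirna_seq": train_channel(nets["pirna_seq"], X_p, gcfg, seed=int(s1)),
            "disease_sem": train_channel(nets["disease_sem"], X_d, gcfg, seed=int(s2)),
        }
    if variant == "attribution_only":
        X_p = assoc_train.A.astype(float)
        X_d = assoc_train.A.T.astype(float)
        gcfg = cfg.gvae
        rng = np.random.default_rng(seed)
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        return {
            "pirna_gip": train_channel(nets["pirna_gip"], X_p, gcfg, seed=int(s1)),
            "disease_gip": train_channel(nets["disease_gip"], X_d, gcfg, seed=int(s2)),
        }
    # full and no_nn use all four channels with weight sharing
    return multi_channel_embed(nets, assoc_train, cfg.gvae, seed=seed).embeddings


def _inner_product_scores(embeddings, pairs):
    """Average of the two cross-class inner-product reconstructions."""
    p_idx = {pid: i for i, pid in enumerate(embeddings["pirna_seq"].node_ids)}
    d_idx = {did: i for i, did in enumerate(embeddings["disease_sem"].node_ids)}
    rec_sem = expit(embeddings["pirna_seq"].z @ embeddings["disease_sem"].z.T)
    rec_gip = expit(embeddings["pirna_gip"].z @ embeddings["disease_gip"].z.T)
    rec = (rec_sem + rec_gip) / 2.0
    return np.array([rec[p_idx[p], d_idx[d]] for p, d, _ in pairs])


def run_cv(
    seqs: SequenceSet,
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    variant: str = "full",
    shuffle_labels: bool = False,
) -> pd.DataFrame:
    """Five-fold cross-validated evaluation of one model variant.

    Returns a DataFrame with one row per fold plus an ``Average`` row and the
    seven metric columns.  ``shuffle_labels`` permutes the pair labels after
    sampling (the chance-level null).
    """
    cfg = cfg or PipelineConfig()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    rng = np.random.default_rng(seed)
    pos = np.argwhere(assoc.A == 1)
    neg = sample_negatives(assoc, cfg.neg_ratio, rng)
    pair_idx = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    if shuffle_labels:
        labels = rng.permutation(labels)
    plan = make_folds(labels, cfg.n_folds, seed=int(rng.integers(0, 2**31 - 1)))
    all_idx = np.arange(len(labels))
    rows = []
    for fold_no, test_idx in enumerate(plan.folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        scores, test_labels = _run_fold(
            seqs, assoc, dag, cfg, variant, pair_idx, labels, train_idx, test_idx,
            fold_seed,
        )
        rows.append(compute_metrics(scores, test_labels))
    report = pd.DataFrame(rows, index=[f"fold{i + 1}" for i in range(len(rows))])
    report = report[list(METRICS)]
    report.loc["Average"] = report.mean(axis=0)
    return report


def _run_fold(
    seqs, assoc, dag, cfg, variant, pair_idx, labels, train_idx, test_idx, seed
):
    # mask the test-fold true positives out of the training association matrix
    test_cells = pair_idx[test_idx]
    pos_cells = test_cells[assoc.A[test_cells[:, 0], test_cells[:, 1]] == 1]
    assoc_train = _mask_cells(assoc, pos_cells)
    assoc_gip = assoc if cfg.gip_from == "full" else assoc_train
    nets = build_all_networks(
        seqs, assoc_gip, dag, k=cfg.k, alpha=cfg.alpha, gip_bandwidth=cfg.gip_bandwidth
    )
    embeddings = _train_variant_embeddings(variant, nets, assoc_train, cfg, seed)

    def pairs_of(idx):
        return [
            (assoc.pirna_ids[i], assoc.disease_ids[j], int(lbl))
            for (i, j), lbl in zip(pair_idx[idx], labels[idx])
        ]

    test_pairs = pairs_of(test_idx)
    test_labels = labels[test_idx]
    if variant == "no_nn":
        scores = _inner_product_scores(embeddings, test_pairs)
        return scores, test_labels
    train_feats = _variant_pair_features(variant, embeddings, nets, pairs_of(train_idx))
    test_feats = _variant_pair_features(variant, embeddings, nets, test_pairs)
    clf_seed = seed % (2**31 - 1)
    model = train_classifier(
        train_feats,
        epochs=cfg.classifier_epochs,
        learning_rate=cfg.classifier_lr,
        seed=clf_seed,
    )
    return model.decision_scores(test_feats.X), test_labels


def run_ablation(
    variant: str,
    seqs: SequenceSet,
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated report for one ablation preset (see VARIANTS)."""
    return run_cv(seqs, assoc, dag, cfg, seed=seed, variant=variant)
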