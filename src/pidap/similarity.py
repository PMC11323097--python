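"""Construction of the four homogeneous similarity networks.

The link-prediction model consumes four weighted graphs: a piRNA sequence
similarity network (Pearson correlation of k-mer frequency profiles), a
disease semantic similarity network (hierarchy-based contributions decaying by
a factor alpha per level, in the style of Wang's MeSH similarity), and one
Gaussian Interaction Profile (GIP) kernel network per node class, computed
from the rows respectively columns of the binary association matrix.

Every network is symmetric, has unit diagonal, and entries in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import AssociationMatrix, DiseaseDAG, SequenceSet

__all__ = [
    "KmerFeatureTable",
    "SimilarityNetwork",
    "SemanticValueTable",
    "kmer_features",
    "pearson_correlation",
    "pearson_similarity",
    "semantic_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "gip_kernel",
    "build_all_networks",
]

CHANNELS = ("pirna_seq", "disease_sem", "pirna_gip", "disease_gip")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class KmerFeatureTable:
    """Relative k-mer frequencies, one row per sequence.

    Columns follow the lexicographic order of k-mers over (A, C, G, T); each
    row sums to 1 for sequences of length >= k.
    """

    k: int
    F: np.ndarray
    sequence_ids: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.F.shape[1]


@dataclass
class SimilarityNetwork:
    """A symmetric weighted graph over one homogeneous node set (one channel)."""

    S: np.ndarray
    node_ids: list[str]
    channel: str

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.shape != (p, p) or len(self.node_ids) != p:
            raise ValueError("similarity matrix and node labels disagree in size")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.array_equal(self.S, self.S.T):
            raise ValueError("similarity matrix must be exactly symmetric")
        if (self.S < 0).any() or (self.S > 1).any():
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.all(np.diag(self.S) == 1.0):
            raise ValueError("similarity diagonal must equal 1")

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class SemanticValueTable:
    """Per-disease ancestor contributions and semantic values.

    ``contributions[d]`` maps every term t in T(d) — the anchor term of d plus
    all its ancestors — to its contribution D_d(t); ``value(d)`` is the sum.
    """

    contributions: dict[str, dict[str, float]]

    def terms(self, disease: str) -> set[str]:
        return set(self.contributions[disease])

    def value(self, disease: str) -> float:
        return float(sum(self.contributions[disease].values()))


def kmer_features(seqs: SequenceSet, k: int) -> KmerFeatureTable:
    """Count overlapping k-mers and normalize by the number of windows.

    The feature space has 4**k columns in lexicographic k-mer order; entry
    (i, w) is the count of k-mer w in sequence i divided by len_i - k + 1.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    n_feat = 4**k
    F = np.zeros((len(seqs), n_feat))
    for row, (seq_id, seq) in enumerate(seqs.records):
        n_windows = len(seq) - k + 1
        if n_windows < 1:
            raise ValueError(
                f"sequence {seq_id!r} is shorter than k={k} (length {len(seq)})"
            )
        for start in range(n_windows):
            idx = 0
            for base in seq[start : start + k]:
                idx = idx * 4 + _BASE_INDEX[base]
            F[row, idx] += 1
        F[row] /= n_windows
    return KmerFeatureTable(k=k, F=F, sequence_ids=tuple(seqs.ids))


def pearson_correlation(F: KmerFeatureTable) -> np.ndarray:
    """Raw pairwise Pearson correlations of feature rows, in [-1, 1].

    A row with zero variance has undefined correlations; its off-diagonal
    entries are set to 0 with a warning naming the node.
    """
    X = np.asarray(F.F, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("Pearson similarity needs at least 2 feature columns")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    degenerate = norms == 0.0
    for node in np.asarray(F.sequence_ids)[degenerate]:
        warnings.warn(
            f"sequence {node!r} has constant k-mer features; "
            "its similarities are set to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, norms)
    U = Xc / safe[:, None]
    S = U @ U.T
    S[degenerate, :] = 0.0
    S[:, degenerate] = 0.0
    return S


def pearson_similarity(F: KmerFeatureTable) -> SimilarityNetwork:
    """Pearson correlation of feature rows, clamped into [0, 1].

    Negative correlations are truncated to 0 (the downstream GCN normalization
    needs non-negative edge weights) and the diagonal is forced to 1.
    """
    S = pearson_correlation(F)
    np.clip(S, 0.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(S=S, node_ids=list(F.sequence_ids), channel="pirna_seq")


def _ancestor_closure(dag: DiseaseDAG, anchor: str) -> set[str]:
    return {anchor} | nx.ancestors(dag.graph, anchor)


def semantic_contribution(
    dag: DiseaseDAG, disease: str, alpha: float = 0.5
) -> dict[str, float]:
    """Contribution D_d(t) of each hierarchy term t to disease d.

    The anchor term of d contributes 1; every other term t in the ancestor
    closure T(d) contributes the maximum over its children t' in T(d) of
    alpha * D_d(t'), which closes to alpha ** (shortest parent->child path
    length from t down to the anchor).
    """
    anchor = dag.anchor(disease)
    closure = _ancestor_closure(dag, anchor)
    # shortest downward distance from each ancestor to the anchor = shortest
    # path from the anchor in the reversed hierarchy
    dist = nx.single_source_shortest_path_length(dag.graph.reverse(copy=False), anchor)
    return {t: float(alpha ** dist[t]) for t in closure}


def semantic_table(
    dag: DiseaseDAG, diseases: list[str], alpha: float = 0.5
) -> SemanticValueTable:
    """Semantic contributions for every listed disease."""
    return SemanticValueTable(
        contributions={d: semantic_contribution(dag, d, alpha) for d in diseases}
    )


def semantic_value(table: SemanticValueTable, disease: str) -> float:
    """D(d): the sum of contributions over the ancestor closure T(d)."""
    return table.value(disease)


def disease_semantic_similarity(
    dag: DiseaseDAG, diseases: list[str], alpha: float = 0.5
) -> SimilarityNetwork:
    """Hierarchy-overlap similarity between diseases.

    Entry (i, j) sums D_{d_i}(t) + D_{d_j}(t) over the shared ancestor terms
    and divides by D(d_i) + D(d_j); an empty intersection gives 0.
    """
    table = semantic_table(dag, diseases, alpha)
    n = len(diseases)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        ci = table.contributions[diseases[i]]
        cj = table.contributions[diseases[j]]
        shared = ci.keys() & cj.keys()
        num = sum(ci[t] + cj[t] for t in shared)
        den = table.value(diseases[i]) + table.value(diseases[j])
        S[i, j] = S[j, i] = num / den
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(S=S, node_ids=list(diseases), channel="disease_sem")


def gip_kernel(
    assoc: AssociationMatrix,
    axis: str,
    bandwidth: str = "normalized",
) -> SimilarityNetwork:
    """Gaussian Interaction Profile kernel over association profiles.

    For ``axis='pirna'`` the profile of node i is row i of the association
    matrix; entry (i, j) is exp(-lambda * ||profile_i - profile_j||^2).  The
    default bandwidth is the normalized form lambda = N / sum_m ||profile_m||^2
    (one over the mean squared profile norm); ``bandwidth='as_printed'``
    selects the inverted form lambda = (1/N) * sum_m ||profile_m||^2.
    """
    if axis == "pirna":
        profiles = assoc.A.astype(float)
        ids = list(assoc.pirna_ids)
        channel = "pirna_gip"
    elif axis == "disease":
        profiles = assoc.A.T.astype(float)
        ids = list(assoc.disease_ids)
        channel = "disease_gip"
    else:
        raise ValueError("axis must be 'pirna' or 'disease'")
    sq = (profiles**2).sum(axis=1)
    total = float(sq.sum())
    if total == 0.0:
        raise ValueError("GIP bandwidth undefined: all association profiles are zero")
    n = profiles.shape[0]
    if bandwidth == "normalized":
        lam = n / total
    elif bandwidth == "as_printed":
        lam = total / n
    else:
        raise ValueError("bandwidth must be 'normalized' or 'as_printed'")
    sqdist = sq[:, None] + sq[None, :] - 2.0 * (profiles @ profiles.T)
    np.clip(sqdist, 0.0, None, out=sqdist)
    S = np.exp(-lam * sqdist)
    S = (S + S.T) / 2.0
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(S=S, node_ids=ids, channel=channel)


def build_all_networks(
    seqs: SequenceSet,
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    k: int = 3,
    alpha: float = 0.5,
    gip_bandwidth: str = "normalized",
) -> dict[str, SimilarityNetwork]:
    """Build the four channels: pirna_seq, disease_sem, pirna_gip, disease_gip.

    GIP networks are computed from the association matrix passed in; callers
    evaluating under cross-validation pass the training-fold-masked matrix.
    """
    if seqs.ids != list(assoc.pirna_ids):
        raise ValueError("sequence ids and association matrix piRNA ids disagree")
    return {
        "pirna_seq": pearson_similarity(kmer_features(seqs, k)),
        "disease_sem": disease_semantic_similarity(dag, list(assoc.disease_ids), alpha),
        "pirna_gip": gip_kernel(assoc, "pirna", gip_bandwidth),
        "disease_gip": gip_kernel(assoc, "disease", gip_bandwidth),
    }
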