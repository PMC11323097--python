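"""Self-contained synthetic fixtures with planted low-rank block structure.

The generator partitions piRNAs and diseases into ``r`` latent blocks and
plants recoverable signal in all three input modalities:

* associations — A[p, d] ~ Bernoulli(block_assoc_prob) when p and d share a
  block, else Bernoulli(background_prob), emulating the sparse bipartite
  structure where similar piRNAs show similar correlation patterns with
  diseases;
* sequences — uniform-random ACGT strings (default lengths 26-32 nt, the
  typical piRNA range) with a block-specific motif inserted so that k-mer
  similarity correlates with blocks;
* disease hierarchy — a tree whose per-block subtrees hold each block's
  disease anchor terms, so semantic similarity correlates with blocks.

Every draw comes from one seed; the same configuration always yields
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    AssociationMatrix,
    DiseaseDAG,
    SequenceSet,
    write_association_matrix,
)

__all__ = ["SyntheticConfig", "generate", "default_fixture", "write_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-block generator.

    The defaults (60 piRNAs, 12 diseases, 3 blocks, within-block association
    probability 0.6 against a 0.02 background) are small enough for an
    end-to-end cross-validated run in well under two minutes on one CPU while
    keeping the planted signal clearly recoverable.
    """

    m: int = 60
    n: int = 12
    r: int = 3
    block_assoc_prob: float = 0.6
    background_prob: float = 0.02
    seq_length: tuple[int, int] = (26, 32)
    motif_length: int = 8
    motif_copies: int = 2
    dag_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.block_assoc_prob <= 1.0):
            raise ValueError("block_assoc_prob must be in (0, 1]")
        if not (0.0 <= self.background_prob < 1.0):
            raise ValueError("background_prob must be in [0, 1)")
        if self.block_assoc_prob <= self.background_prob:
            raise ValueError("block_assoc_prob must exceed background_prob")
        if self.m < self.r or self.n < self.r:
            raise ValueError("need at least one piRNA and one disease per block")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be at least 2")
        if self.seq_length[0] > self.seq_length[1] or self.seq_length[0] < 1:
            raise ValueError("invalid sequence length range")


def _block_of(index: int, total: int, r: int) -> int:
    return min(index * r // total, r - 1)


def _random_sequence(rng: np.random.Generator, length: int, motif: str, copies: int) -> str:
    seq = rng.choice(_BASES, size=length)
    for _ in range(copies):
        start = int(rng.integers(0, length - len(motif) + 1))
        seq[start : start + len(motif)] = list(motif)
    return "".join(seq)


def generate(
    cfg: SyntheticConfig,
) -> tuple[SequenceSet, AssociationMatrix, DiseaseDAG, dict]:
    """Generate (sequences, associations, hierarchy, truth) from one seed.

    ``truth`` holds the planted block assignment of every piRNA and disease
    plus the per-block motifs.
    """
    rng = np.random.default_rng(cfg.seed)
    p_block = np.array([_block_of(i, cfg.m, cfg.r) for i in range(cfg.m)])
    d_block = np.array([_block_of(j, cfg.n, cfg.r) for j in range(cfg.n)])

    motifs = []
    while len(motifs) < cfg.r:
        motif = "".join(rng.choice(_BASES, size=cfg.motif_length))
        if motif not in motifs:
            motifs.append(motif)

    pirna_ids = [f"p{i:03d}" for i in range(cfg.m)]
    records = []
    lo, hi = cfg.seq_length
    for i in range(cfg.m):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            (pirna_ids[i], _random_sequence(rng, length, motifs[p_block[i]], cfg.motif_copies))
        )
    seqs = SequenceSet(tuple(records))

    disease_ids = [f"d{j:02d}" for j in range(cfg.n)]
    same = p_block[:, None] == d_block[None, :]
    probs = np.where(same, cfg.block_assoc_prob, cfg.background_prob)
    A = (rng.random((cfg.m, cfg.n)) < probs).astype(np.int8)
    assoc = AssociationMatrix(A, pirna_ids, disease_ids)

    # per-block chains under a common root; anchors attach at the bottom
    edges: set[tuple[str, str]] = set()
    bottoms = []
    for b in range(cfg.r):
        chain = [f"b{b}_l{lvl}" for lvl in range(1, cfg.dag_depth)]
        edges.add(("root", chain[0]))
        for parent, child in zip(chain, chain[1:]):
            edges.add((parent, child))
        bottoms.append(chain[-1])
    term_map = {}
    for j in range(cfg.n):
        term = f"t_{disease_ids[j]}"
        edges.add((bottoms[d_block[j]], term))
        term_map[disease_ids[j]] = term
    nodes = frozenset(t for e in edges for t in e)
    dag = DiseaseDAG(nodes=nodes, edges=frozenset(edges), term_map=term_map)

    truth = {
        "pirna_block": p_block,
        "disease_block": d_block,
        "motifs": tuple(motifs),
    }
    return seqs, assoc, dag, truth


def default_fixture() -> tuple[SequenceSet, AssociationMatrix, DiseaseDAG, dict]:
    """The documented small default: 60 piRNAs x 12 diseases, 3 blocks."""
    return generate(SyntheticConfig())


def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical input files plus the ground-truth blocks.

    Produces sequences.fasta, associations.tsv, dag_edges.tsv, dag_map.tsv and
    truth.tsv in ``out_dir`` and returns their paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs, assoc, dag, truth = generate(cfg)
    paths = {
        "fasta": out / "sequences.fasta",
        "assoc": out / "associations.tsv",
        "dag_edges": out / "dag_edges.tsv",
        "dag_map": out / "dag_map.tsv",
        "truth": out / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for rec_id, seq in seqs.records:
            fh.write(f">{rec_id}\n{seq}\n")
    write_association_matrix(assoc, paths["assoc"])
    with open(paths["dag_edges"], "w") as fh:
        for parent, child in sorted(dag.edges):
            fh.write(f"{parent}\t{child}\n")
    with open(paths["dag_map"], "w") as fh:
        for disease in assoc.disease_ids:
            fh.write(f"{disease}\t{dag.term_map[disease]}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("node\tkind\tblock\n")
        for pid, b in zip(assoc.pirna_ids, truth["pirna_block"]):
            fh.write(f"{pid}\tpirna\t{b}\n")
        for did, b in zip(assoc.disease_ids, truth["disease_block"]):
            fh.write(f"{did}\tdisease\t{b}\n")
    return paths
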