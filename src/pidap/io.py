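"""Readers and writers for the pipeline's external representations.

All inputs are plain text: FASTA for piRNA sequences, labeled TSV/CSV for the
binary association matrix, two-column edge lists for the disease-term hierarchy.
Matrices are always labeled, never positional-only.  Delimiters are
auto-detected among tab and comma; files written by this package use tab.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "AssociationMatrix",
    "DiseaseDAG",
    "PairPrediction",
    "read_fasta",
    "read_association_matrix",
    "write_association_matrix",
    "read_disease_dag",
    "write_predictions",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of named nucleotide sequences.

    Sequences are stored upper-case over the DNA alphabet {A,C,G,T}; uracil is
    normalized to thymine on construction so downstream k-mer indexing works
    over a single 4-letter alphabet.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec_id, seq in self.records:
            if not rec_id:
                raise ValueError("empty sequence id")
            if rec_id in seen:
                raise ValueError(f"duplicate id {rec_id}")
            seen.add(rec_id)
            if not seq:
                raise ValueError(f"empty sequence for id {rec_id}")
            for pos, base in enumerate(seq):
                if base not in _VALID_BASES:
                    raise ValueError(
                        f"invalid character {base!r} at position {pos} in sequence {rec_id}"
                    )

    @property
    def ids(self) -> list[str]:
        return [rec_id for rec_id, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)


def _normalize_sequence(raw: str) -> str:
    return "".join(raw.split()).upper().replace("U", "T")


@dataclass
class AssociationMatrix:
    """Binary m x n matrix of known piRNA-disease links, with row/col labels."""

    A: np.ndarray
    pirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        m, n = self.A.shape
        if m == 0:
            raise ValueError("no piRNAs")
        if n == 0:
            raise ValueError("no diseases")
        if len(self.pirna_ids) != m or len(self.disease_ids) != n:
            raise ValueError("label lists do not match matrix dimensions")
        if len(set(self.pirna_ids)) != m:
            raise ValueError("duplicate piRNA ids")
        if len(set(self.disease_ids)) != n:
            raise ValueError("duplicate disease ids")
        bad = ~np.isin(self.A, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary entry at row {self.pirna_ids[i]!r}, "
                f"column {self.disease_ids[j]!r}"
            )
        self.A = self.A.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.A.copy(), list(self.pirna_ids), list(self.disease_ids))


@dataclass
class DiseaseDAG:
    """Disease-term hierarchy (parent -> child edges) plus the anchor mapping.

    ``term_map`` sends each disease label of the association matrix to the DAG
    term that anchors it.  Acyclicity is verified on construction.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    term_map: dict[str, str]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")
        missing = {d: t for d, t in self.term_map.items() if t not in self.nodes}
        if missing:
            d, t = next(iter(missing.items()))
            raise ValueError(f"disease {d!r} mapped to absent term {t!r}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        """The hierarchy as a networkx DiGraph (parent -> child)."""
        return self._graph

    def anchor(self, disease: str) -> str:
        try:
            return self.term_map[disease]
        except KeyError:
            raise KeyError(f"disease {disease!r} has no mapped DAG term") from None


@dataclass(frozen=True)
class PairPrediction:
    """A scored (piRNA, disease) pair; call = 1 iff score strictly exceeds 0.5."""

    pirna_id: str
    disease_id: str
    score: float
    call: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"score {self.score} for ({self.pirna_id}, {self.disease_id}) "
                "outside [0, 1]"
            )
        if self.call != int(self.score > 0.5):
            raise ValueError("call inconsistent with the strict 0.5 rule")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (upper-cased, U -> T)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _normalize_sequence(str(rec.seq))))
    return SequenceSet(tuple(records))


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    # auto-detect tab vs comma; python engine required for sep=None
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_association_matrix(path: str | Path) -> AssociationMatrix:
    """Read a labeled delimited text matrix of {0,1} associations.

    Expects one header row of disease ids and one leading column of piRNA ids.
    """
    df = _read_delimited(path, index_col=0)
    if df.shape[0] == 0:
        raise ValueError("no piRNAs")
    return AssociationMatrix(
        df.to_numpy(),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_association_matrix(assoc: AssociationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(assoc.A, index=assoc.pirna_ids, columns=assoc.disease_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_disease_dag(edges_path: str | Path, map_path: str | Path) -> DiseaseDAG:
    """Read a parent,child edge list and a disease,term mapping into a DAG.

    Both files are two-column delimited text without a header row.  The edge
    list may be in any order; acyclicity is verified on construction.
    """
    edges_df = _read_delimited(edges_path, header=None, dtype=str)
    if edges_df.shape[1] != 2:
        raise ValueError("edge list must have exactly two columns: parent, child")
    edges = frozenset((str(p), str(c)) for p, c in edges_df.itertuples(index=False))
    nodes = frozenset(t for e in edges for t in e)
    map_df = _read_delimited(map_path, header=None, dtype=str)
    if map_df.shape[1] != 2:
        raise ValueError("disease map must have exactly two columns: disease, term")
    term_map = {str(d): str(t) for d, t in map_df.itertuples(index=False)}
    return DiseaseDAG(nodes=nodes, edges=edges, term_map=term_map)


def write_predictions(pairs: Sequence[PairPrediction], path: str | Path) -> None:
    """Write scored pairs as TSV (pirna_id, disease_id, score, call), input order."""
    for p in pairs:
        if not 0.0 <= p.score <= 1.0:  # re-check: PairPrediction may be subclassed
            raise ValueError(f"score {p.score} outside [0, 1]")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pirna_id", "disease_id", "score", "call"])
        for p in pairs:
            writer.writerow([p.pirna_id, p.disease_id, repr(float(p.score)), p.call])
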