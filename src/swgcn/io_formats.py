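"""Readers and writers for the formats the pipeline touches.

The on-disk exchange formats are deliberately plain text so every
intermediate stays human-diffable:

* piRNA sequences       — FASTA (RNA ``U`` is normalised to ``T`` at read
  time so one DNA alphabet serves the alignment scoring tables),
* associations / scores — long-form TSV with a header,
* disease ontology      — two-column ``child<TAB>parent`` edge list, or an
  OBO file restricted to its ``is_a`` relations,
* run configuration     — flat YAML mirroring :class:`RunConfig` fields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import yaml

__all__ = [
    "SequenceSet",
    "DiseaseDAG",
    "AssociationTable",
    "RunConfig",
    "read_fasta",
    "read_dag",
    "read_associations",
    "read_association_table",
    "write_associations",
    "write_scores",
    "read_scores",
    "read_config",
    "write_config",
]

_VALID_BASES = frozenset("ACGTUN")


@dataclass(frozen=True)
class SequenceSet:
    """Ordered piRNA identifiers and their nucleotide sequences.

    The order of ``ids`` fixes the row order of every piRNA-indexed matrix
    downstream (association matrix, sequence similarity, feature rows).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise ValueError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
        for sid, seq in zip(self.ids, self.seqs):
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}


@dataclass(frozen=True)
class DiseaseDAG:
    """A rooted directed acyclic graph over disease terms.

    ``edges`` point from child to parent.  ``theta`` is the per-hop semantic
    contribution factor used by the Wang-style similarity (default 0.5).
    Term order fixes the column order of all disease-indexed matrices.
    """

    terms: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    theta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        known = set(self.terms)
        if len(known) != len(self.terms):
            raise ValueError("duplicate disease terms")
        for child, parent in self.edges:
            if child not in known or parent not in known:
                raise ValueError(f"edge ({child!r}, {parent!r}) references unknown term")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")

    def __len__(self) -> int:
        return len(self.terms)

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph containing every term as a node."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def roots(self) -> tuple[str, ...]:
        g = self.graph()
        return tuple(t for t in self.terms if g.out_degree(t) == 0)

    def with_theta(self, theta: float) -> "DiseaseDAG":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class AssociationTable:
    """Flat list of (piRNA_id, disease_id) association records."""

    records: tuple[tuple[str, str], ...]

    def to_matrix(self, seqs: SequenceSet, dag: DiseaseDAG) -> np.ndarray:
        """Binary m x n matrix in SequenceSet row / DAG column order.

        Unknown ids raise; duplicate pairs collapse to a single 1.
        """
        ridx, cidx = seqs.index(), dag.index()
        a = np.zeros((len(seqs), len(dag)), dtype=np.float64)
        for pid, did in self.records:
            if pid not in ridx:
                raise KeyError(f"unknown piRNA id in associations: {pid!r}")
            if did not in cidx:
                raise KeyError(f"unknown disease id in associations: {did!r}")
            a[ridx[pid], cidx[did]] = 1.0
        return a


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of the full pipeline.

    Training defaults: 1000 epochs, learning rate 1e-3, weight-decay
    factor mu = 1.0 and a learning-rate decay factor of 0.2, applied at
    50% and 75% of the epoch budget.  The restart probability, alignment
    scoring scheme, layer sizes and beta are open choices documented in
    docs/methods.md.
    """

    rwr_restart: float = 0.5
    sw_match: float = 1.0
    sw_mismatch: float = -1.0
    sw_gap_open: float = -1.0
    sw_gap_extend: float = -1.0
    theta: float = 0.5
    gcn_layers: int = 1
    embed_dim: int = 64
    head_dims: tuple[int, ...] = (64, 32, 16)
    beta: float = 2.0
    mu: float = 1.0
    epochs: int = 1000
    learning_rate: float = 1e-3
    lr_decay: float = 0.2
    seed: int = 0
    weighting_mode: str = "weighted"  # weighted | boolean:<k> | none

    def __post_init__(self) -> None:
        if not (0.0 < self.rwr_restart <= 1.0):
            raise ValueError("rwr_restart must be in (0, 1]")
        if self.sw_match <= 0:
            raise ValueError("sw_match must be positive")
        if self.epochs < 0 or self.gcn_layers < 0:
            raise ValueError("epochs and gcn_layers must be non-negative")
        if self.embed_dim <= 0 or any(d <= 0 for d in self.head_dims):
            raise ValueError("embedding dimensions must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        mode = self.weighting_mode
        if mode not in ("weighted", "none") and not _parse_boolean_mode(mode):
            raise ValueError(f"unknown weighting_mode: {mode!r}")


def _parse_boolean_mode(mode: str) -> float | None:
    """Return k_percent for 'boolean:<k>' modes, else None."""
    m = re.fullmatch(r"boolean:(\d+(?:\.\d+)?)", mode)
    if not m:
        return None
    k = float(m.group(1))
    return k if 0.0 < k <= 100.0 else None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read piRNA sequences, normalising RNA ``U`` to ``T``."""
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None and not current:
                    raise ValueError(f"empty FASTA record {ids[-1]!r} in {path}")
                sid = line[1:].split()[0]
                if sid in ids:
                    raise ValueError(f"duplicate FASTA id {sid!r} in {path}")
                ids.append(sid)
                current = []
                seqs.append("")
            else:
                if current is None:
                    raise ValueError(f"sequence data before first header in {path}")
                current.append(line.upper().replace("U", "T"))
                seqs[-1] = "".join(current)
    if ids and not seqs[-1]:
        raise ValueError(f"empty FASTA record {ids[-1]!r} in {path}")
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceSet(tuple(ids), tuple(seqs))


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(seqs.ids, seqs.seqs):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Disease DAG


def read_dag(path: str | Path, theta: float = 0.5) -> DiseaseDAG:
    """Read a disease DAG from an edge list or an OBO file.

    Edge lists are two tab-separated columns, ``child<TAB>parent``; a line
    with a single token declares an isolated (root) term.  Files ending in
    ``.obo`` are parsed with obonet and restricted to ``is_a`` relations.
    Term order is first-appearance order, which downstream matrices follow.
    """
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return _read_obo(path, theta)
    terms: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str]] = []

    def _add(term: str) -> None:
        if term not in seen:
            seen.add(term)
            terms.append(term)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                _add(parts[0])
            elif len(parts) == 2:
                child, parent = parts
                _add(child)
                _add(parent)
                edges.append((child, parent))
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns")
    return DiseaseDAG(tuple(terms), tuple(edges), theta)


def _read_obo(path: Path, theta: float) -> DiseaseDAG:
    graph = obonet.read_obo(path)
    # obonet edges run child -> parent for is_a, keyed by relation.
    terms = tuple(sorted(graph.nodes()))
    edges = tuple(
        (c, p)
        for c, p, key in graph.edges(keys=True)
        if key == "is_a"
    )
    return DiseaseDAG(terms, edges, theta)


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    """Write the edge list, declaring isolated terms on their own line."""
    in_edge = {t for e in dag.edges for t in e}
    with open(path, "w") as fh:
        for term in dag.terms:
            if term not in in_edge:
                fh.write(f"{term}\n")
        for child, parent in dag.edges:
            fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------------
# Associations and score matrices (long-form TSV)


def read_association_table(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"piRNA_id", "disease_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: association TSV needs columns {sorted(required)}")
    records = tuple(zip(df["piRNA_id"], df["disease_id"]))
    return AssociationTable(records)


def read_associations(
    path: str | Path, seqs: SequenceSet, dag: DiseaseDAG
) -> np.ndarray:
    """Read the pair list and return the binary m x n association matrix."""
    return read_association_table(path).to_matrix(seqs, dag)


def write_associations(
    matrix: np.ndarray, pirna_ids: Sequence, disease_ids: Sequence, path: str | Path
) -> None:
    """Write the positive cells of a binary matrix as a pair list."""
    rows, cols = np.nonzero(np.asarray(matrix) != 0)
    with open(path, "w") as fh:
        fh.write("piRNA_id\tdisease_id\n")
        for i, j in zip(rows, cols):
            fh.write(f"{pirna_ids[i]}\t{disease_ids[j]}\n")


def write_scores(
    matrix: np.ndarray,
    pirna_ids,
    disease_ids,
    path: str | Path,
) -> None:
    """Serialize a dense score (or similarity) matrix as long-form TSV.

    Rows are ``(piRNA_id, disease_id, score)`` with 10 significant digits,
    enough for a lossless round trip at the precision the pipeline needs.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape != (len(pirna_ids), len(disease_ids)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match id lists "
            f"({len(pirna_ids)}, {len(disease_ids)})"
        )
    with open(path, "w") as fh:
        fh.write("piRNA_id\tdisease_id\tscore\n")
        for i, pid in enumerate(pirna_ids):
            for j, did in enumerate(disease_ids):
                fh.write(f"{pid}\t{did}\t{matrix[i, j]:.10g}\n")


def read_scores(path: str | Path):
    """Read a long-form score TSV back into (matrix, row_ids, col_ids).

    Row and column orders are first-appearance orders, so a write/read
    round trip preserves both the matrix and the id orders.
    """
    df = pd.read_csv(path, sep="\t", dtype={"piRNA_id": str, "disease_id": str})
    required = {"piRNA_id", "disease_id", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: score TSV needs columns {sorted(required)}")
    row_ids = list(dict.fromkeys(df["piRNA_id"]))
    col_ids = list(dict.fromkeys(df["disease_id"]))
    ridx = {r: i for i, r in enumerate(row_ids)}
    cidx = {c: j for j, c in enumerate(col_ids)}
    mat = np.zeros((len(row_ids), len(col_ids)), dtype=np.float64)
    mat[df["piRNA_id"].map(ridx), df["disease_id"].map(cidx)] = df["score"].to_numpy()
    return mat, row_ids, col_ids


# ---------------------------------------------------------------------------
# Run configuration


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    if "head_dims" in data:
        data["head_dims"] = tuple(data["head_dims"])
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)

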