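"""Homogeneous similarity matrices for the two node types.

piRNA-piRNA similarity is a self-normalised Smith-Waterman local alignment
score,

    P_seq(i, j) = SW(p_i, p_j) / sqrt(SW(p_i, p_i) * SW(p_j, p_j)),

so identical sequences score 1 and the scale of the scoring scheme cancels.
Disease-disease similarity is the Wang-style ontology measure: each disease
d contributes S_d(t) = 1 at itself and theta * max over the relevant
children at each ancestor t, and

    D_sem(i, j) = sum_{t in T_i & T_j} (S_i(t) + S_j(t))
                  / (sum_{t in T_i} S_i(t) + sum_{t in T_j} S_j(t)),

where T_i is the disease together with all of its ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import Align

from .io_formats import DiseaseDAG, SequenceSet

__all__ = [
    "ScoringScheme",
    "sw_raw_score",
    "sequence_similarity",
    "semantic_contributions",
    "semantic_similarity",
    "validate_similarity",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; gap penalties are negative. Linear gaps by default."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -1.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


def sw_raw_score(seq_a: str, seq_b: str, scoring: ScoringScheme | None = None) -> float:
    """Best local alignment score between two nucleotide sequences.

    Symmetric in its arguments and >= 0 (the empty alignment scores 0).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or ScoringScheme()
    return float(scoring.aligner().score(seq_a, seq_b))


def sequence_similarity(
    seqs: SequenceSet, scoring: ScoringScheme | None = None
) -> np.ndarray:
    """Self-normalised Smith-Waterman similarity matrix P_seq.

    P_seq(i, j) = SW(i, j) / sqrt(SW(i, i) * SW(j, j)); unit diagonal,
    symmetric, entries in [0, 1].
    """
    scoring = scoring or ScoringScheme()
    aligner = scoring.aligner()
    m = len(seqs)
    self_scores = np.array([aligner.score(s, s) for s in seqs.seqs])
    if np.any(self_scores <= 0):
        bad = seqs.ids[int(np.argmin(self_scores))]
        raise ValueError(f"self-alignment score is 0 for {bad!r}; cannot normalise")
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            raw = aligner.score(seqs.seqs[i], seqs.seqs[j])
            sim[i, j] = sim[j, i] = raw / np.sqrt(self_scores[i] * self_scores[j])
    return sim


def semantic_contributions(dag: DiseaseDAG, disease: str) -> dict[str, float]:
    """Semantic contribution S_d(t) of every ancestor t to ``disease``.

    The contribution is 1 at the disease itself and decays by theta per
    hop toward the root, taking at each ancestor the max over its children
    that lie on a path from the disease.
    """
    if disease not in dag.index():
        raise KeyError(f"disease {disease!r} not in DAG")
    g = dag.graph()
    # T_i: the disease plus everything reachable along child->parent edges.
    members = {disease} | nx.descendants(g, disease)
    contrib = {disease: 1.0}
    # Children of t within T_i are predecessors of t in the child->parent
    # digraph; process in topological order away from the disease.
    order = [t for t in nx.topological_sort(g.subgraph(members))]
    for t in order:
        if t == disease:
            continue
        children = [c for c in g.predecessors(t) if c in members]
        contrib[t] = dag.theta * max(contrib[c] for c in children)
    return contrib


def semantic_similarity(dag: DiseaseDAG) -> np.ndarray:
    """Wang-style disease semantic similarity matrix D_sem.

    Terms that share no ancestor (disjoint rooted components) score 0.
    """
    n = len(dag)
    tables = [semantic_contributions(dag, t) for t in dag.terms]
    totals = np.array([sum(tab.values()) for tab in tables])
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = tables[i].keys() & tables[j].keys()
            if shared:
                num = sum(tables[i][t] + tables[j][t] for t in shared)
                sim[i, j] = sim[j, i] = num / (totals[i] + totals[j])
    return sim


def validate_similarity(sim: np.ndarray, atol: float = 1e-9) -> None:
    """Assert the SimilarityMatrix contract: square, symmetric, unit
    diagonal, entries in [0, 1]."""
    sim = np.asarray(sim)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {sim.shape}")
    if not np.allclose(sim, sim.T, atol=atol):
        raise ValueError("similarity matrix is not symmetric")
    if not np.allclose(np.diag(sim), 1.0, atol=atol):
        raise ValueError("similarity diagonal must be 1")
    if sim.min() < -atol or sim.max() > 1 + atol:
        raise ValueError("similarity entries must lie in [0, 1]")
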