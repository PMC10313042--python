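"""Seeded generator of desk-scale piRNA-disease worlds.

The generator emulates the statistical shape of the curated association
resources the method targets: a tall-thin binary association matrix
(m piRNAs >> n diseases) at roughly 5-6% density, short piRNA sequences
(23-36 nt range; 28 nt consensus here) whose pairwise similarity
correlates with shared association structure, and a small rooted disease
ontology tree.  Associations come from a low-rank latent-factor model:

    P(A[i, j] = 1) = sigmoid(signal * <p_i, q_j> / sqrt(r) + b)

with the intercept b calibrated so the expected density matches the
target.  Sequences are built per latent cluster (the sign pattern of the
two leading piRNA factors) from a cluster consensus with 10% per-base
mutation, and the disease tree attaches each disease to its most similar
already-placed disease in latent space — so both similarity matrices
carry real signal about the association structure, as the method assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import DiseaseDAG, SequenceSet
from .weighting import SplitSpec

__all__ = ["SyntheticWorld", "generate", "heldout_truth"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticWorld:
    """A fully specified synthetic benchmark instance."""

    pirna_factors: np.ndarray  # (m, r)
    disease_factors: np.ndarray  # (n, r)
    probabilities: np.ndarray  # (m, n) true association probabilities
    a: np.ndarray  # (m, n) sampled binary associations
    clusters: np.ndarray  # (m,) latent sequence-cluster labels
    seqs: SequenceSet
    dag: DiseaseDAG
    seed: int
    density: float
    signal: float

    @property
    def latent_scores(self) -> np.ndarray:
        """True latent pair affinities — the AUC ceiling for any learner."""
        return self.pirna_factors @ self.disease_factors.T


def _calibrate_intercept(logits: np.ndarray, density: float) -> float:
    """Intercept b with mean sigmoid(logits + b) == density."""

    def gap(b: float) -> float:
        return float(expit(logits + b).mean() - density)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"cannot calibrate intercept for density {density}")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _mutate(consensus: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    seq = consensus.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != seq[pos]]
        seq[pos] = rng.choice(choices)
    return "".join(seq)


def _build_tree(
    disease_factors: np.ndarray, rng: np.random.Generator
) -> tuple[tuple[str, str], ...]:
    """Rooted tree over diseases, similar diseases attaching nearby."""
    n = disease_factors.shape[0]
    norm = disease_factors / np.linalg.norm(disease_factors, axis=1, keepdims=True)
    order = rng.permutation(n)
    placed = [int(order[0])]
    parent = {int(order[0]): None}
    for idx in order[1:]:
        idx = int(idx)
        sims = norm[idx] @ norm[placed].T
        parent[idx] = placed[int(np.argmax(sims))]
        placed.append(idx)

    def depth(i: int) -> int:
        d = 0
        while parent[i] is not None:
            i, d = parent[i], d + 1
        return d

    # Guarantee depth >= 2: a star tree carries no ancestor structure.
    if n >= 3 and max(depth(i) for i in parent) < 2:
        root = placed[0]
        children = [i for i, p in parent.items() if p == root]
        parent[children[1]] = children[0]
    return tuple(
        (f"d{child}", f"d{p}") for child, p in parent.items() if p is not None
    )


def generate(
    m: int = 300,
    n: int = 15,
    rank: int = 4,
    density: float = 0.06,
    seed: int = 0,
    signal: float = 3.0,
    seq_length: int = 28,
    mutation_rate: float = 0.10,
) -> SyntheticWorld:
    """Sample a synthetic world; bit-identical for identical arguments."""
    if not (0.0 < density < 1.0):
        raise ValueError(f"density must be in (0, 1), got {density}")
    if rank > min(m, n):
        raise ValueError(f"rank {rank} exceeds min(m, n) = {min(m, n)}")
    rng = np.random.default_rng(seed)

    p = rng.standard_normal((m, rank))
    q = rng.standard_normal((n, rank))
    logits = signal * (p @ q.T) / np.sqrt(rank)
    b = _calibrate_intercept(logits, density)
    probs = expit(logits + b)
    a = (rng.random((m, n)) < probs).astype(np.float64)
    # Every disease needs at least one positive for the splits to make sense.
    for j in np.nonzero(a.sum(axis=0) == 0)[0]:
        a[int(np.argmax(probs[:, j])), j] = 1.0

    # Sequence clusters from the sign pattern of the leading factors (up to
    # four, keeping clusters populated): sequence similarity then reflects
    # latent association structure, as real piRNA families do.
    lead = p[:, : min(4, rank)]
    clusters = ((lead > 0) * (2 ** np.arange(lead.shape[1]))).sum(axis=1)
    n_clusters = 2 ** lead.shape[1]
    consensi = [
        rng.choice(_BASES, size=seq_length) for _ in range(n_clusters)
    ]
    seqs = SequenceSet(
        ids=tuple(f"p{i}" for i in range(m)),
        seqs=tuple(
            _mutate(consensi[int(c)], mutation_rate, rng) for c in clusters
        ),
    )

    edges = _build_tree(q, rng)
    terms = tuple(f"d{j}" for j in range(n))
    dag = DiseaseDAG(terms=terms, edges=edges, theta=0.5)

    return SyntheticWorld(
        pirna_factors=p,
        disease_factors=q,
        probabilities=probs,
        a=a,
        clusters=clusters.astype(np.int64),
        seqs=seqs,
        dag=dag,
        seed=seed,
        density=density,
        signal=signal,
    )


def heldout_truth(world: SyntheticWorld, splits: SplitSpec) -> np.ndarray:
    """Ground-truth labels for the held-out pairs, positives first.

    Aligned with the concatenation (ind2_pos, ind2_neg) that
    ``evaluate_split`` scores; negatives are genuine zero cells of the
    sampled association matrix by construction.
    """
    pos, neg = splits.ind2_pos, splits.ind2_neg
    labels = np.concatenate(
        [world.a[pos[:, 0], pos[:, 1]], world.a[neg[:, 0], neg[:, 1]]]
    )
    return labels
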