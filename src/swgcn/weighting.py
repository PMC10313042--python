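"""Two-phase data splits and the supplementarily weighted adjacency matrix.

The association network is extremely sparse (about 5-6% of cells are
validated positives), so a graph convolution on the raw Boolean adjacency
aggregates almost nothing.  The remedy implemented here fills every
unknown cell with a confidence weight in [0, 1]: an ensemble of 15 basic
classifiers — Random Forest, SVM and gradient-boosted trees, each trained
five times against independently resampled negative sets — scores every
unknown pair, and the average score becomes the cell's weight.  Known
training positives stay at exactly 1.

Splits follow a two-phase protocol.  Phase 1 trains the basic classifiers:
a random 20% of positives is held out and the classifiers are trained on
the remaining 80% against five equal-size negative draws from the unknown
cells.  Phase 2 trains the graph model: 80% of positives (the same 80% —
sharing the draw is what guarantees the phase-1 training positives never
include the final evaluation pairs) with an equal-size held-out negative
sample for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "make_splits",
    "pair_feature",
    "BasicEnsemble",
    "train_basic_ensemble",
    "supplementary_weighted_adjacency",
    "boolean_topk_adjacency",
]

Pairs = np.ndarray  # (k, 2) int array of (piRNA_row, disease_col) indices


def _as_pairs(rows: np.ndarray, cols: np.ndarray) -> Pairs:
    return np.stack([rows, cols], axis=1).astype(np.int64)


def _pair_set(pairs: Pairs) -> set[tuple[int, int]]:
    return {(int(i), int(j)) for i, j in pairs}


@dataclass(frozen=True)
class SplitSpec:
    """Index bookkeeping for the two training phases.

    Positive sets are (k, 2) integer arrays of matrix indices.  The
    phase-1 and phase-2 positive splits share the same 20% hold-out, so
    the basic-classifier training positives (``ben1_pos``) are disjoint
    from the final evaluation pairs (``ind2_pos``) by construction.
    """

    shape: tuple[int, int]
    ben1_pos: Pairs
    ind1_pos: Pairs
    ben1_neg_sets: tuple[Pairs, ...]
    ben2_pos: Pairs
    ind2_pos: Pairs
    ind2_neg: Pairs
    seed: int

    @property
    def n_positive(self) -> int:
        return self.ben2_pos.shape[0] + self.ind2_pos.shape[0]

    @property
    def n_unknown(self) -> int:
        """Number of unknown (unvalidated) piRNA-disease cells."""
        m, n = self.shape
        return m * n - self.n_positive

    def validate(self) -> None:
        ben1, ind1 = _pair_set(self.ben1_pos), _pair_set(self.ind1_pos)
        ben2, ind2 = _pair_set(self.ben2_pos), _pair_set(self.ind2_pos)
        ind2_neg = _pair_set(self.ind2_neg)
        if ben1 & ind1:
            raise ValueError("phase-1 benchmark and independent positives overlap")
        if (ben2 | set()) & (ind2 | ind2_neg):
            raise ValueError("phase-2 benchmark and independent sets overlap")
        if ben1 & (ind2 | ind2_neg):
            raise ValueError("phase-1 benchmark positives leak into the evaluation set")
        for k, neg in enumerate(self.ben1_neg_sets):
            if len(neg) != len(self.ben1_pos):
                raise ValueError(f"phase-1 negative set {k} has the wrong size")
        if len(self.ind2_neg) != len(self.ind2_pos):
            raise ValueError("evaluation negatives must match positives in size")


def make_splits(
    a: np.ndarray,
    seed: int,
    holdout_frac: float = 0.2,
    n_neg_sets: int = 5,
) -> SplitSpec:
    """Draw the two-phase splits from a binary association matrix.

    ``holdout_frac`` of the positives (rounded down) become the held-out
    independent positives of both phases; the rest are the training
    positives.  Five negative sets of the training-positive size are
    sampled without replacement (within each set) from the unknown cells
    for the basic classifiers, and one more equal-to-hold-out-size draw
    becomes the evaluation negatives.  Fully deterministic given ``seed``.
    """
    a = np.asarray(a)
    m, n = a.shape
    pos_rows, pos_cols = np.nonzero(a == 1)
    positives = _as_pairs(pos_rows, pos_cols)
    n_pos = len(positives)
    if n_pos < 10:
        raise ValueError(f"need at least 10 positives to split, got {n_pos}")
    neg_rows, neg_cols = np.nonzero(a == 0)
    unknowns = _as_pairs(neg_rows, neg_cols)

    rng = np.random.default_rng(seed)
    n_hold = int(round(holdout_frac * n_pos))
    perm = rng.permutation(n_pos)
    ind_pos = positives[np.sort(perm[:n_hold])]
    ben_pos = positives[np.sort(perm[n_hold:])]

    n_ben = len(ben_pos)
    if len(unknowns) < max(n_ben, n_hold):
        raise ValueError("not enough unknown cells to sample negative sets")
    ben1_neg_sets = tuple(
        unknowns[np.sort(rng.choice(len(unknowns), size=n_ben, replace=False))]
        for _ in range(n_neg_sets)
    )
    ind2_neg = unknowns[np.sort(rng.choice(len(unknowns), size=n_hold, replace=False))]

    spec = SplitSpec(
        shape=(m, n),
        ben1_pos=ben_pos,
        ind1_pos=ind_pos,
        ben1_neg_sets=ben1_neg_sets,
        ben2_pos=ben_pos,
        ind2_pos=ind_pos,
        ind2_neg=ind2_neg,
        seed=seed,
    )
    spec.validate()
    return spec


def pair_feature(f_p: np.ndarray, f_d: np.ndarray) -> np.ndarray:
    """Feature vector of a (piRNA, disease) pair: the concatenated RWR rows."""
    return np.concatenate([np.asarray(f_p), np.asarray(f_d)])


def _pair_matrix(pairs: Pairs, fp: np.ndarray, fd: np.ndarray) -> np.ndarray:
    """Stack pair features for many pairs at once."""
    return np.concatenate([fp[pairs[:, 0]], fd[pairs[:, 1]]], axis=1)


@dataclass
class BasicEnsemble:
    """The 15 basic scorers: {RF, SVM, GBDT} x 5 negative resamples.

    Every member scores a pair-feature vector into [0, 1]; SVM members are
    probability-calibrated (Platt scaling as provided by the library) so
    the three families share a scale before averaging.
    """

    members: list[tuple[str, object]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def score_matrix(self, x: np.ndarray) -> np.ndarray:
        """Per-member positive-class scores, shape (len(self), len(x))."""
        scores = np.stack(
            [model.predict_proba(x)[:, 1] for _, model in self.members]
        )
        return np.clip(scores, 0.0, 1.0)

    def score(self, x: np.ndarray) -> np.ndarray:
        """Ensemble-averaged scores in [0, 1] for a batch of pair features."""
        return self.score_matrix(x).mean(axis=0)

    def score_pairs(self, pairs: Pairs, fp: np.ndarray, fd: np.ndarray) -> np.ndarray:
        return self.score(_pair_matrix(pairs, fp, fd))


_FAMILIES = ("rf", "svm", "gbdt")


def _make_learner(family: str, random_state: int):
    if family == "rf":
        return RandomForestClassifier(random_state=random_state)
    if family == "svm":
        # Platt sigmoid on cross-validated decision values, putting SVM
        # scores on the common [0, 1] scale of the other families.
        return CalibratedClassifierCV(
            SVC(random_state=random_state), method="sigmoid", ensemble=False
        )
    if family == "gbdt":
        return GradientBoostingClassifier(random_state=random_state)
    raise ValueError(f"unknown learner family {family!r}")


def train_basic_ensemble(
    splits: SplitSpec,
    fp: np.ndarray,
    fd: np.ndarray,
    seed: int | None = None,
    families: tuple[str, ...] = _FAMILIES,
) -> BasicEnsemble:
    """Fit the basic ensemble on the phase-1 splits.

    For each of the negative resamples k, each learner family is fit on
    ben1_pos (label 1) against ben1_neg_set_k (label 0).  Library-default
    hyperparameters, seeded for reproducibility.
    """
    seed = splits.seed if seed is None else seed
    x_pos = _pair_matrix(splits.ben1_pos, fp, fd)
    y = np.concatenate([np.ones(len(x_pos)), np.zeros(len(x_pos))])
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training set")
    ensemble = BasicEnsemble()
    for k, neg in enumerate(splits.ben1_neg_sets):
        x = np.concatenate([x_pos, _pair_matrix(neg, fp, fd)], axis=0)
        for f, family in enumerate(families):
            model = _make_learner(family, random_state=seed + 97 * k + f)
            model.fit(x, y)
            ensemble.members.append((f"{family}_{k}", model))
    return ensemble


def _score_all_cells(
    shape: tuple[int, int], ensemble: BasicEnsemble, fp: np.ndarray, fd: np.ndarray
) -> np.ndarray:
    m, n = shape
    rows, cols = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    pairs = _as_pairs(rows.ravel(), cols.ravel())
    return ensemble.score_pairs(pairs, fp, fd).reshape(m, n)


def supplementary_weighted_adjacency(
    a: np.ndarray,
    ensemble: BasicEnsemble,
    positive_train_pairs: Pairs,
    fp: np.ndarray,
    fd: np.ndarray,
) -> np.ndarray:
    """Build A' in [0, 1]: 1 on training positives, the 15-member average
    confidence everywhere else.

    ``positive_train_pairs`` are the cells pinned to 1 (the phase-2
    training positives when deployed in the pipeline, so held-out
    evaluation positives keep their ensemble weight and never leak).
    """
    a = np.asarray(a, dtype=np.float64)
    weighted = _score_all_cells(a.shape, ensemble, fp, fd)
    weighted[positive_train_pairs[:, 0], positive_train_pairs[:, 1]] = 1.0
    return weighted


def boolean_topk_adjacency(
    a: np.ndarray,
    ensemble: BasicEnsemble,
    k_percent: float,
    positive_train_pairs: Pairs,
    fp: np.ndarray,
    fd: np.ndarray,
) -> np.ndarray:
    """Ablation variant: promote the top k% highest-scoring unknown cells
    to Boolean 1 instead of keeping fractional weights.

    ``k_percent = 0`` reproduces the unweighted Boolean adjacency exactly.
    Ties at the cutoff break by (row, col) lexicographic order.
    """
    if not (0.0 <= k_percent <= 100.0):
        raise ValueError(f"k_percent must be in [0, 100], got {k_percent}")
    a = np.asarray(a, dtype=np.float64)
    m, n = a.shape
    out = np.zeros((m, n))
    out[positive_train_pairs[:, 0], positive_train_pairs[:, 1]] = 1.0
    if k_percent == 0.0:
        return out
    unknown_mask = out == 0
    rows, cols = np.nonzero(unknown_mask)
    pairs = _as_pairs(rows, cols)
    scores = ensemble.score_pairs(pairs, fp, fd)
    n_promote = int(np.floor(k_percent / 100.0 * len(pairs)))
    if n_promote > 0:
        # lexsort keys: last key is primary -> sort by -score, then row, col
        order = np.lexsort((pairs[:, 1], pairs[:, 0], -scores))
        chosen = pairs[order[:n_promote]]
        out[chosen[:, 0], chosen[:, 1]] = 1.0
    return out
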