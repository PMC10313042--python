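import numpy as np
import pytest

from swgcn.node_features import rwr_features
from swgcn.similarity import sequence_similarity, semantic_similarity
from swgcn.synthetic import generate
from swgcn.weighting import (
    boolean_topk_adjacency,
    make_splits,
    pair_feature,
    supplementary_weighted_adjacency,
    train_basic_ensemble,
)


class TestMakeSplits:
    def _matrix(self, n_pos=100, shape=(40, 10), seed=0):
        rng = np.random.default_rng(seed)
        a = np.zeros(shape)
        idx = rng.choice(shape[0] * shape[1], size=n_pos, replace=False)
        a.ravel()[idx] = 1
        return a

    def test_eighty_twenty_proportions(self):
        splits = make_splits(self._matrix(), seed=3)
        assert len(splits.ind2_pos) == 20
        assert len(splits.ben2_pos) == 80
        assert len(splits.ind1_pos) == 20
        assert len(splits.ben1_pos) == 80

    def test_five_negative_sets_of_benchmark_size(self):
        splits = make_splits(self._matrix(), seed=3)
        assert len(splits.ben1_neg_sets) == 5
        assert all(len(s) == 80 for s in splits.ben1_neg_sets)

    def test_evaluation_negatives_balance_positives(self):
        splits = make_splits(self._matrix(), seed=3)
        assert len(splits.ind2_neg) == len(splits.ind2_pos)

    def test_same_seed_identical_splits(self):
        a = self._matrix()
        s1, s2 = make_splits(a, seed=9), make_splits(a, seed=9)
        np.testing.assert_array_equal(s1.ben1_pos, s2.ben1_pos)
        np.testing.assert_array_equal(s1.ind2_neg, s2.ind2_neg)
        for n1, n2 in zip(s1.ben1_neg_sets, s2.ben1_neg_sets):
            np.testing.assert_array_equal(n1, n2)

    def test_unknown_cell_bookkeeping(self):
        a = self._matrix(n_pos=100, shape=(40, 10))
        splits = make_splits(a, seed=0)
        assert splits.n_positive == 100
        assert splits.n_unknown == 300

    def test_disjointness_validates(self):
        splits = make_splits(self._matrix(), seed=1)
        splits.validate()  # does not raise
        ind2 = {tuple(p) for p in splits.ind2_pos}
        ben1 = {tuple(p) for p in splits.ben1_pos}
        assert not ind2 & ben1

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.zeros((5, 5)), seed=0)


class TestPairFeature:
    def test_concatenation_length(self):
        v = pair_feature(np.zeros(5), np.ones(3))
        assert v.shape == (8,)

    def test_order_is_pirna_then_disease(self):
        v = pair_feature(np.array([1.0, 2.0]), np.array([3.0]))
        np.testing.assert_array_equal(v, [1.0, 2.0, 3.0])
        swapped = pair_feature(np.array([3.0]), np.array([1.0, 2.0]))
        assert not np.array_equal(v, swapped)


@pytest.fixture(scope="module")
def trained_world():
    world = generate(m=80, n=8, rank=3, density=0.15, seed=21)
    p_seq = sequence_similarity(world.seqs)
    d_sem = semantic_similarity(world.dag)
    fp, fd = rwr_features(p_seq), rwr_features(d_sem)
    splits = make_splits(world.a, seed=21)
    ensemble = train_basic_ensemble(splits, fp, fd)
    return world, splits, fp, fd, ensemble


class TestBasicEnsemble:
    def test_fifteen_members(self, trained_world):
        _, _, _, _, ensemble = trained_world
        assert len(ensemble) == 15
        families = {name.split("_")[0] for name, _ in ensemble.members}
        assert families == {"rf", "svm", "gbdt"}

    def test_scores_lie_in_unit_interval(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        scores = ensemble.score_pairs(splits.ind2_pos, fp, fd)
        assert scores.min() >= 0 and scores.max() <= 1

    def test_retraining_with_same_seed_reproduces_scores(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        again = train_basic_ensemble(splits, fp, fd)
        probe = splits.ind2_neg
        np.testing.assert_array_equal(
            ensemble.score_pairs(probe, fp, fd), again.score_pairs(probe, fp, fd)
        )

    def test_identical_features_give_identical_pair_scores(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        # Two pairs with bitwise-equal features must score identically.
        fp2 = fp.copy()
        fp2[1] = fp2[0]
        pairs = np.array([[0, 2], [1, 2]])
        s = ensemble.score_pairs(pairs, fp2, fd)
        assert s[0] == s[1]


class TestWeightedAdjacency:
    def test_training_positives_pinned_to_one(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        w = supplementary_weighted_adjacency(
            world.a, ensemble, splits.ben2_pos, fp, fd
        )
        assert np.all(w[splits.ben2_pos[:, 0], splits.ben2_pos[:, 1]] == 1.0)
        assert w.min() >= 0 and w.max() <= 1

    def test_never_erases_a_known_positive(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        all_pos = np.stack(np.nonzero(world.a == 1), axis=1)
        w = supplementary_weighted_adjacency(world.a, ensemble, all_pos, fp, fd)
        assert np.all(w >= world.a)

    def test_heldout_positives_outweigh_negatives(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        w = supplementary_weighted_adjacency(
            world.a, ensemble, splits.ben2_pos, fp, fd
        )
        pos, neg = splits.ind2_pos, splits.ind2_neg
        margin = (
            w[pos[:, 0], pos[:, 1]].mean() - w[neg[:, 0], neg[:, 1]].mean()
        )
        assert margin > 0


class TestBooleanTopK:
    def test_k_zero_reproduces_boolean_adjacency(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        w = boolean_topk_adjacency(world.a, ensemble, 0.0, splits.ben2_pos, fp, fd)
        expected = np.zeros_like(world.a)
        expected[splits.ben2_pos[:, 0], splits.ben2_pos[:, 1]] = 1.0
        np.testing.assert_array_equal(w, expected)

    def test_k_hundred_promotes_everything(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        w = boolean_topk_adjacency(world.a, ensemble, 100.0, splits.ben2_pos, fp, fd)
        assert np.all(w == 1.0)

    def test_promotion_count_is_floor_of_percentage(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        n_train = len(splits.ben2_pos)
        n_unknown = world.a.size - n_train
        w = boolean_topk_adjacency(world.a, ensemble, 20.0, splits.ben2_pos, fp, fd)
        assert w.sum() == n_train + int(np.floor(0.2 * n_unknown))

    def test_invalid_percentage_rejected(self, trained_world):
        world, splits, fp, fd, ensemble = trained_world
        with pytest.raises(ValueError):
            boolean_topk_adjacency(world.a, ensemble, 150.0, splits.ben2_pos, fp, fd)
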