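"""Subsample splits, grid-search tuning and the 15-classifier ensemble."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import synapred as sp
from synapred.training import ALGORITHMS, derive_seed, tune_and_train
from conftest import FAST_GRIDS


def _labeled(n_pos: int, n_neg: int) -> sp.LabeledGeneSet:
    return sp.LabeledGeneSet(
        frozenset(f"P{i}" for i in range(n_pos)),
        frozenset(f"N{i}" for i in range(n_neg)),
    )


class TestSubsampleSplits:
    def test_small_forced_partition(self):
        splits = sp.make_subsample_splits(_labeled(10, 10), k=5, seed=0)
        assert len(splits) == 5
        for s in splits:
            assert len(s.test.positives) == 2 and len(s.test.negatives) == 2
        union_pos = frozenset().union(*(s.test.positives for s in splits))
        assert union_pos == _labeled(10, 10).positives

    def test_92_positives_split_as_balanced_fifths(self):
        splits = sp.make_subsample_splits(_labeled(92, 397), k=5, seed=11)
        pos_sizes = sorted(len(s.test.positives) for s in splits)
        assert pos_sizes == [18, 18, 18, 19, 19]
        neg_sizes = sorted(len(s.test.negatives) for s in splits)
        assert max(neg_sizes) - min(neg_sizes) <= 1
        assert sum(neg_sizes) == 397

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_each_fold_partitions_both_classes(self, seed):
        labeled = _labeled(23, 57)
        splits = sp.make_subsample_splits(labeled, k=5, seed=seed)
        for s in splits:
            assert not (s.train.positives & s.test.positives)
            assert not (s.train.negatives & s.test.negatives)
            assert s.train.positives | s.test.positives == labeled.positives
            assert s.train.negatives | s.test.negatives == labeled.negatives
        # test sets tile each class without overlap
        all_test_pos = [g for s in splits for g in s.test.positives]
        assert len(all_test_pos) == len(set(all_test_pos)) == 23

    def test_train_class_ratio_matches_global_within_rounding(self):
        labeled = _labeled(92, 397)
        for s in sp.make_subsample_splits(labeled, k=5, seed=2):
            ratio = len(s.train.positives) / len(s.train.negatives)
            assert ratio == pytest.approx(92 / 397, abs=0.01)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="cannot be split"):
            sp.make_subsample_splits(_labeled(3, 50), k=5, seed=0)

    def test_seeded_and_reproducible(self):
        a = sp.make_subsample_splits(_labeled(20, 40), seed=5)
        b = sp.make_subsample_splits(_labeled(20, 40), seed=5)
        assert [s.test.positives for s in a] == [s.test.positives for s in b]
        c = sp.make_subsample_splits(_labeled(20, 40), seed=6)
        assert [s.test.positives for s in a] != [s.test.positives for s in c]


class TestTuneAndTrain:
    def test_separable_limit_scores_perfectly(self):
        """With an overwhelming wave signal every family reaches accuracy 1."""
        cfg = sp.SimulationConfig(n_genes=250, n_pos_labeled=20, n_neg_labeled=50,
                                  n_hidden_pos=0, wave_fold=12.0,
                                  noise_dispersion=0.25, seed=5)
        ds = sp.generate_dataset(cfg)
        retained, _ = sp.filter_adult_only(ds.matrix, cfg.adult_stage_indices)
        norm = sp.max_normalize(retained)
        present = frozenset(norm.index)
        labeled = sp.LabeledGeneSet(ds.positives & present, ds.negatives & present)
        splits = sp.make_subsample_splits(labeled, seed=1)
        for alg in ALGORITHMS:
            clf = tune_and_train(alg, splits[0], norm,
                                 grid=FAST_GRIDS[alg], cv_folds=4, seed=0)
            m = sp.evaluate_classifier(clf, splits[0], norm)
            assert m.accuracy == 1.0, (alg, m)
            assert m.auroc == 1.0

    def test_chosen_hyperparameters_come_from_the_grid(self, tiny_trained):
        classifiers, _ = tiny_trained
        for clf in classifiers:
            grid = FAST_GRIDS[clf.algorithm]
            for key, value in clf.hyperparameters.items():
                assert value in grid[key]

    def test_probabilities_bounded(self, tiny_table):
        vals = tiny_table.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert not np.isnan(vals).any()

    def test_degenerate_single_class_rejected(self, tiny_normalized):
        genes = list(tiny_normalized.index[:12])
        split = sp.SubsampleSplit(
            0,
            train=sp.LabeledGeneSet(frozenset(genes[:8]), frozenset()),
            test=sp.LabeledGeneSet(frozenset(genes[8:10]), frozenset(genes[10:])),
        )
        with pytest.raises(ValueError, match="both classes"):
            tune_and_train("kNN", split, tiny_normalized,
                           grid=FAST_GRIDS["kNN"], cv_folds=2, seed=0)

    def test_permuted_labels_give_chance_level_auroc(self, tiny_normalized,
                                                     tiny_labeled):
        """Null check: destroying the label-feature link drives AUROC to ~0.5."""
        ids = sorted(tiny_labeled.positives | tiny_labeled.negatives)
        n_pos = len(tiny_labeled.positives)
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(ids)
            labeled = sp.LabeledGeneSet(frozenset(shuffled[:n_pos]),
                                        frozenset(shuffled[n_pos:]))
            split = sp.make_subsample_splits(labeled, seed=seed)[0]
            clf = tune_and_train("kNN", split, tiny_normalized,
                                 grid={"n_neighbors": [5], "weights": ["uniform"]},
                                 cv_folds=3, seed=seed)
            aurocs.append(sp.evaluate_classifier(clf, split, tiny_normalized).auroc)
        assert 0.4 <= np.mean(aurocs) <= 0.6

    def test_no_leakage_from_test_rows(self, tiny_normalized, tiny_labeled):
        """Corrupting the held-out rows cannot change the fitted classifier."""
        split = sp.make_subsample_splits(tiny_labeled, seed=4)[0]
        corrupted = tiny_normalized.copy()
        test_ids = sorted(split.test.positives | split.test.negatives)
        corrupted.loc[test_ids] = np.random.default_rng(0).random(
            (len(test_ids), corrupted.shape[1]))
        clean = tune_and_train("kNN", split, tiny_normalized,
                               grid=FAST_GRIDS["kNN"], cv_folds=4, seed=9)
        dirty = tune_and_train("kNN", split, corrupted,
                               grid=FAST_GRIDS["kNN"], cv_folds=4, seed=9)
        probe = tiny_normalized.drop(index=test_ids)
        pd.testing.assert_series_equal(clean.predict_proba(probe),
                                       dirty.predict_proba(probe))


class TestTrainAll:
    def test_default_scheme_identity_grid(self, tiny_trained):
        classifiers, splits = tiny_trained
        assert len(classifiers) == 15
        assert len(splits) == 5
        identities = Counter((c.algorithm, c.fold_index) for c in classifiers)
        assert len(identities) == 15 and set(identities.values()) == {1}
        assert {a for a, _ in identities} == set(ALGORITHMS)

    def test_single_algorithm_gives_five(self, tiny_labeled, tiny_normalized):
        classifiers, _ = sp.train_all(tiny_labeled, tiny_normalized,
                                      grids=FAST_GRIDS, cv_folds=4, seed=3,
                                      algorithms=("kNN",))
        assert len(classifiers) == 5

    def test_full_reproducibility_under_fixed_seed(self, tiny_labeled,
                                                   tiny_normalized, tiny_trained,
                                                   tiny_table):
        classifiers, _ = sp.train_all(tiny_labeled, tiny_normalized,
                                      grids=FAST_GRIDS, cv_folds=4, seed=3)
        first, _ = tiny_trained
        assert [c.hyperparameters for c in classifiers] == [
            c.hyperparameters for c in first]
        table = sp.predict_all(classifiers, tiny_normalized,
                               exclude=tiny_labeled.positives | tiny_labeled.negatives)
        pd.testing.assert_frame_equal(table, tiny_table, check_exact=True)

    def test_missing_labeled_genes_rejected(self, tiny_normalized):
        labeled = sp.LabeledGeneSet(frozenset(["NOT_A_GENE"]),
                                    frozenset(tiny_normalized.index[:10]))
        with pytest.raises(ValueError, match="absent"):
            sp.train_all(labeled, tiny_normalized, grids=FAST_GRIDS, seed=0)


def test_derived_seeds_are_stable_and_distinct():
    assert derive_seed(1, 2, 3) == derive_seed(1, 2, 3)
    seeds = {derive_seed(0, a, f) for a in range(3) for f in range(5)}
    assert len(seeds) == 15
    assert all(0 <= s < 2**31 for s in seeds)
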