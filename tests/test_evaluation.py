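import itertools
import math

import numpy as np
import pytest

from ncdna import (
    ConfusionCounts,
    LabeledDataset,
    SVMConfig,
    compare_classifiers,
    confusion_counts,
    cross_validate,
    metrics,
    roc_auc,
)


def phi_coefficient(tp: int, tn: int, fp: int, fn: int) -> float | None:
    """Textbook Matthews correlation: (TP·TN − FP·FN) / sqrt(product of the
    four marginals); None where a marginal vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = [1] * 5 + [-1] * 5
        counts = confusion_counts(truth, truth)
        assert (counts.false_neg, counts.false_pos) == (0, 0)
        assert (counts.n_pos, counts.n_neg) == (5, 5)

    def test_fully_flipped_prediction(self):
        truth = np.array([1] * 4 + [-1] * 6)
        counts = confusion_counts(truth, -truth)
        assert counts.false_neg == 4
        assert counts.false_pos == 6

    def test_matches_brute_force_tally_on_random_labels(self, rng):
        truth = rng.choice([1, -1], size=200)
        pred = rng.choice([1, -1], size=200)
        counts = confusion_counts(truth, pred)
        assert counts.false_neg == sum(
            1 for t, p in zip(truth, pred) if t == 1 and p == -1)
        assert counts.false_pos == sum(
            1 for t, p in zip(truth, pred) if t == -1 and p == 1)

    @pytest.mark.parametrize("truth,pred", [
        ([1, 1], [1]), ([1, 0], [1, -1]), ([], []),
    ])
    def test_contract_violations_rejected(self, truth, pred):
        with pytest.raises(ValueError):
            confusion_counts(truth, pred)

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            ConfusionCounts(n_pos=3, n_neg=3, false_neg=4, false_pos=0)


class TestMetrics:
    def test_error_free_prediction_is_all_ones(self):
        m = metrics(ConfusionCounts(10, 10, 0, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_example(self):
        m = metrics(ConfusionCounts(100, 200, 5, 10))
        assert m.sn == pytest.approx(0.95)
        assert m.sp == pytest.approx(0.95)
        assert m.acc == pytest.approx(0.95)
        # cross-check against the phi coefficient with TP=95 TN=190 FP=10 FN=5
        assert m.mcc == pytest.approx(phi_coefficient(95, 190, 10, 5), abs=1e-12)
        assert m.mcc == pytest.approx(0.8895, abs=5e-5)

    def test_equivalence_with_phi_exhaustive_small_tables(self):
        """The class-total metric formulas coincide with the textbook
        TP/TN/FP/FN forms on every confusion table with class totals <= 12."""
        checked = 0
        for n_pos, n_neg in itertools.product(range(1, 13), repeat=2):
            for fn in range(n_pos + 1):
                for fp in range(n_neg + 1):
                    counts = ConfusionCounts(n_pos, n_neg, fn, fp)
                    tp, tn = n_pos - fn, n_neg - fp
                    with np.errstate(all="ignore"):
                        import warnings
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            m = metrics(counts)
                    assert m.sn == pytest.approx(tp / n_pos, abs=1e-12)
                    assert m.sp == pytest.approx(tn / n_neg, abs=1e-12)
                    assert m.acc == pytest.approx((tp + tn) / (n_pos + n_neg),
                                                  abs=1e-12)
                    phi = phi_coefficient(tp, tn, fp, fn)
                    if phi is not None:
                        assert m.mcc == pytest.approx(phi, abs=1e-12)
                        checked += 1
        assert checked > 5_000  # the sweep really covered the space

    def test_degenerate_mcc_is_zero_with_warning(self):
        # everything predicted positive: a predicted class is empty
        with pytest.warns(UserWarning, match="MCC"):
            m = metrics(ConfusionCounts(5, 5, 0, 5))
        assert m.mcc == 0.0

    def test_mcc_bounds(self, rng):
        import warnings
        for _ in range(200):
            n_pos = int(rng.integers(1, 30))
            n_neg = int(rng.integers(1, 30))
            counts = ConfusionCounts(n_pos, n_neg,
                                     int(rng.integers(0, n_pos + 1)),
                                     int(rng.integers(0, n_neg + 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(counts)
            assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12
            assert 0.0 <= m.acc <= 1.0


def auc_pair_counting(scores, truth) -> float:
    """Mann-Whitney oracle: fraction of (positive, negative) pairs where the
    positive outscores the negative, ties counted half."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        scores = [3.0, 2.0, 1.0, -1.0, -2.0]
        truth = [1, 1, 1, -1, -1]
        points, auc = roc_auc(scores, truth)
        assert auc == 1.0
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            truth = rng.choice([1, -1], size=n)
            if len(set(truth)) < 2:
                continue
            # coarse grid forces tied scores
            scores = rng.integers(0, 6, size=n).astype(float)
            _, auc = roc_auc(scores, truth)
            assert auc == pytest.approx(auc_pair_counting(scores, truth),
                                        abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score
        truth = rng.choice([1, -1], size=100)
        truth[:2] = [1, -1]
        scores = rng.standard_normal(100) + 0.4 * truth
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_label_independent_scores_near_half(self):
        gen = np.random.default_rng(77)
        truth = gen.choice([1, -1], size=2000)
        scores = gen.standard_normal(2000)
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


def _random_dataset(n_pos, n_neg, m, seed, shift=0.0):
    gen = np.random.default_rng(seed)
    pos = gen.random((n_pos, m)) + shift
    neg = gen.random((n_neg, m))
    return LabeledDataset(
        np.vstack([pos, neg]),
        np.r_[np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)],
        [f"x{j}" for j in range(m)], 1,
        [f"r{i}" for i in range(n_pos + n_neg)],
    )


class TestCrossValidate:
    def test_every_record_tested_once_per_repeat(self):
        ds = _random_dataset(10, 10, 3, seed=1)
        res = cross_validate(ds, "knn", folds=10, repeats=1, seed=0)
        assignment = res.fold_assignments[0]
        assert np.all(assignment >= 0)  # everyone got a fold
        tested = sum(fd.counts.n_pos + fd.counts.n_neg for fd in res.per_fold)
        assert tested == 20

    def test_folds_are_stratified_within_one_sample(self):
        ds = _random_dataset(30, 20, 3, seed=2)
        res = cross_validate(ds, "knn", folds=5, repeats=1, seed=3)
        assignment = res.fold_assignments[0]
        global_ratio = 30 / 50
        for fold in range(5):
            mask = assignment == fold
            n = mask.sum()
            n_pos_fold = int(np.sum(ds.labels[mask] == 1))
            assert abs(n_pos_fold - global_ratio * n) <= 1

    def test_null_data_accuracy_near_chance(self):
        ds = _random_dataset(40, 40, 5, seed=4)
        res = cross_validate(ds, "svm", SVMConfig(C=1.0, gamma=1.0),
                             folds=5, repeats=2, seed=5)
        assert res.metrics.acc == pytest.approx(0.5, abs=0.1)

    def test_separated_data_high_accuracy(self):
        ds = _random_dataset(30, 30, 4, seed=6, shift=2.0)
        res = cross_validate(ds, "svm", SVMConfig(C=8.0, gamma=0.5),
                             folds=5, repeats=1, seed=7)
        assert res.metrics.acc >= 0.95

    def test_same_seed_reproduces_everything(self):
        ds = _random_dataset(15, 15, 4, seed=8)
        r1 = cross_validate(ds, "svm", folds=5, repeats=2, seed=42)
        r2 = cross_validate(ds, "svm", folds=5, repeats=2, seed=42)
        for a, b in zip(r1.fold_assignments, r2.fold_assignments):
            np.testing.assert_array_equal(a, b)
        assert r1.metrics == r2.metrics
        assert [m for m in r1.per_repeat] == [m for m in r2.per_repeat]

    def test_different_repeats_use_different_partitions(self):
        ds = _random_dataset(15, 15, 4, seed=9)
        res = cross_validate(ds, "knn", folds=5, repeats=2, seed=1)
        assert not np.array_equal(res.fold_assignments[0],
                                  res.fold_assignments[1])

    def test_class_smaller_than_folds_is_protocol_error(self):
        ds = _random_dataset(5, 30, 3, seed=10)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ds, "svm", folds=10, repeats=1, seed=0)

    def test_pooled_accuracy_equals_total_correct_over_total(self):
        ds = _random_dataset(20, 20, 4, seed=11, shift=0.5)
        res = cross_validate(ds, "knn", folds=4, repeats=1, seed=12)
        errors = sum(fd.counts.false_neg + fd.counts.false_pos
                     for fd in res.per_fold)
        assert res.per_repeat[0].acc == pytest.approx(1 - errors / 40)

    def test_tuned_cv_runs_grid_search_per_fold(self):
        ds = _random_dataset(12, 12, 3, seed=13, shift=1.5)
        cfg = SVMConfig(C_grid=(1.0, 8.0), gamma_grid=(0.25, 1.0), inner_folds=2)
        res = cross_validate(ds, "svm", cfg, folds=3, repeats=1, seed=14,
                             tune=True)
        assert len(res.tuned_params) == 3
        assert res.metrics.acc >= 0.9

    def test_tuning_non_svm_rejected(self):
        ds = _random_dataset(12, 12, 3, seed=15)
        with pytest.raises(ValueError, match="SVM"):
            cross_validate(ds, "knn", folds=3, repeats=1, seed=0, tune=True)


class TestCompareClassifiers:
    def test_single_spec_equals_direct_cross_validate(self):
        ds = _random_dataset(15, 15, 4, seed=16, shift=1.0)
        from ncdna.evaluation import make_folds
        shared = [make_folds(ds.labels, 5, 0 + rep, True) for rep in range(2)]
        direct = cross_validate(ds, "knn", folds=5, repeats=2, seed=0,
                                shared_folds=shared)
        table = compare_classifiers(ds, ["knn"], folds=5, repeats=2, seed=0)
        assert len(table) == 1
        assert table.loc[0, "Acc"] == pytest.approx(direct.metrics.acc)

    def test_all_specs_exceed_point_nine_on_separated_data(self):
        ds = _random_dataset(25, 25, 4, seed=17, shift=2.0)
        table = compare_classifiers(
            ds, ["svm", "knn", "naive-bayes", "random-forest", "decision-tree"],
            config=SVMConfig(C=8.0, gamma=0.5), folds=5, repeats=1, seed=18)
        assert (table["Acc"] > 0.9).all()
        assert list(table["Acc"]) == sorted(table["Acc"], reverse=True)

    def test_empty_spec_list_rejected(self):
        ds = _random_dataset(10, 10, 3, seed=19)
        with pytest.raises(ValueError):
            compare_classifiers(ds, [], folds=5, repeats=1)
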