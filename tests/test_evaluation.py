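"""Accuracy, splitting, ROC/AUC, and jackknife machinery."""

import numpy as np
import pytest
from scipy.stats import norm

from rooibosml import (
    BASELINE,
    ConfusionCounts,
    FeatureSetSpec,
    SplitConfig,
    accuracy,
    confusion_from_labels,
    count_scheduled_optimizations,
    evaluate_once,
    jackknife_compare,
    jackknife_from_estimates,
    roc_curve,
    stratified_split,
)

from conftest import dataset_from_matrix, two_feature_dataset


def _single_feature_dataset(fr_values, ufr_values):
    vals = np.concatenate([fr_values, ufr_values]).astype(float)
    labels = ["FR"] * len(fr_values) + ["UFR"] * len(ufr_values)
    X = np.repeat(vals[:, None], 6, axis=1)  # same value in every assay column
    return dataset_from_matrix(X, labels)


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(3, 2, 1, 0), 5 / 6),
            (ConfusionCounts(4, 6, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 3, 2), 0.0),
        ],
    )
    def test_direct_formula(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected)

    def test_complement_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            assert accuracy(c) == pytest.approx(1 - (c.fp + c.fn) / c.total)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_confusion_from_labels_totals(self):
        true = np.array(["UFR", "UFR", "FR", "FR", "FR"])
        pred = np.array(["UFR", "FR", "FR", "UFR", "FR"])
        c = confusion_from_labels(true, pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 1, 1)
        assert c.total == 5


class TestStratifiedSplit:
    def test_half_split_counts_ceil_to_train(self, default_dataset):
        train, test = stratified_split(default_dataset, SplitConfig(seed=0))
        assert train.label_counts() == {"FR": 26, "UFR": 24}
        assert test.label_counts() == {"FR": 25, "UFR": 23}

    def test_partition_is_disjoint_and_exhaustive(self, default_dataset):
        train, test = stratified_split(default_dataset, SplitConfig(seed=5))
        ids = {s.sample_id for s in train.samples} | {s.sample_id for s in test.samples}
        assert len(ids) == 98
        assert not ({s.sample_id for s in train.samples}
                    & {s.sample_id for s in test.samples})

    def test_deterministic_given_seed(self, default_dataset):
        a = stratified_split(default_dataset, SplitConfig(seed=9))
        b = stratified_split(default_dataset, SplitConfig(seed=9))
        assert a[0].samples == b[0].samples and a[1].samples == b[1].samples

    def test_missing_label_rejected(self):
        ds = _single_feature_dataset(np.arange(5) + 1.0, [])
        with pytest.raises(ValueError, match="UFR"):
            stratified_split(ds, SplitConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.0)
        with pytest.raises(ValueError):
            SplitConfig(cv_folds=1)


class TestROC:
    def test_perfect_separation(self):
        ds = _single_feature_dataset([1, 2, 3], [10, 11, 12])
        assert roc_curve(ds, "TPC", "water").auc == pytest.approx(1.0)

    def test_uninformative_feature_near_half(self):
        rng = np.random.default_rng(3)
        fr = rng.uniform(10, 20, 300)
        ufr = rng.uniform(10, 20, 300)
        r = roc_curve(_single_feature_dataset(fr, ufr), "TPC", "water")
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_mann_whitney_pair_counting(self):
        fr = np.array([1.0, 2, 2, 3, 5, 7, 7, 8, 11, 13])
        ufr = np.array([2.0, 4, 4, 6, 7, 9, 10, 12, 12, 14])
        r = roc_curve(_single_feature_dataset(fr, ufr), "TEAC", "water")
        wins = sum(
            1.0 if u > f else (0.5 if u == f else 0.0) for u in ufr for f in fr
        )
        assert r.auc == pytest.approx(wins / (len(fr) * len(ufr)), abs=1e-12)
        assert r.orientation == "higher-is-UFR"

    def test_orientation_flip_keeps_auc_above_half(self):
        ds = _single_feature_dataset([10.0, 11, 12], [1.0, 2, 3])
        r = roc_curve(ds, "FRAP", "methanol")
        assert r.auc == pytest.approx(1.0)
        assert r.orientation == "lower-is-UFR"

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        fr = rng.normal(5, 1, 40) ** 2
        ufr = rng.normal(6, 1, 35) ** 2
        a = roc_curve(_single_feature_dataset(fr, ufr), "TPC", "water").auc
        b = roc_curve(_single_feature_dataset(np.exp(fr / 50), np.exp(ufr / 50)),
                      "TPC", "water").auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_feature_degenerate(self):
        ds = _single_feature_dataset([4.0, 4, 4], [4.0, 4, 4])
        r = roc_curve(ds, "TPC", "water")
        assert r.degenerate and r.auc == 0.5

    def test_rates_monotone_along_sweep(self, default_dataset):
        r = roc_curve(default_dataset, "TEAC", "methanol")
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    @pytest.mark.parametrize("delta", [0.0, 1.0, 2.0])
    def test_gaussian_auc_closed_form(self, delta):
        """Single-feature AUC for classes Delta apart -> Phi(Delta/sqrt(2))."""
        rng = np.random.default_rng(int(10 + delta))
        fr = rng.normal(100.0, 1.0, 10_000)
        ufr = rng.normal(100.0 + delta, 1.0, 10_000)
        r = roc_curve(_single_feature_dataset(fr, ufr), "TPC", "water")
        assert r.auc == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.01)


class TestJackknife:
    def test_se_of_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        loo_means = np.array([np.delete(x, i).mean() for i in range(x.size)])
        _, se = jackknife_from_estimates(loo_means)
        assert se == pytest.approx(x.std(ddof=1) / np.sqrt(x.size), abs=1e-12)

    def test_baseline_against_itself_is_null(self):
        rng = np.random.default_rng(2)
        fr = rng.normal(0, 1, (12, 2))
        ufr = rng.normal(6, 1, (11, 2))
        ds = two_feature_dataset(fr + 10, ufr + 10)
        spec = FeatureSetSpec(("TPC", "TEAC"), "water")
        res = jackknife_compare(ds, spec, BASELINE, SplitConfig(seed=0))
        assert res.accuracy_difference == 0.0
        assert res.jackknife_se == 0.0
        assert not res.significant
        assert res.n_replicates == 23

    def test_small_dataset_rejected(self):
        ds = two_feature_dataset(np.ones((4, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="n >= 10"):
            jackknife_compare(
                ds, FeatureSetSpec(("TPC",), "water"), BASELINE, SplitConfig(seed=0)
            )


class TestEvaluateOnce:
    def test_well_separated_classes_classified_accurately(self):
        rng = np.random.default_rng(3)
        fr = rng.normal(0, 1, (30, 2)) + 20
        ufr = rng.normal(8, 1, (28, 2)) + 20
        ds = two_feature_dataset(fr, ufr)
        spec = FeatureSetSpec(("TPC", "TEAC"), "water")
        acc = evaluate_once(ds, spec, BASELINE, SplitConfig(seed=0))
        assert acc >= 0.95

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(50, 5, (98, 2))
        labels = rng.permutation(["FR"] * 51 + ["UFR"] * 47)
        ds = two_feature_dataset(X[labels == "FR"], X[labels == "UFR"])
        spec = FeatureSetSpec(("TPC", "TEAC"), "water")
        accs = [evaluate_once(ds, spec, BASELINE, SplitConfig(seed=s)) for s in range(5)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.15)

    def test_deterministic_given_seed(self, default_dataset):
        spec = FeatureSetSpec(("TEAC",), "methanol")
        cfg = SplitConfig(seed=6)
        a = evaluate_once(default_dataset, spec, "KNN", cfg)
        b = evaluate_once(default_dataset, spec, "KNN", cfg)
        assert a == b

    def test_unknown_method_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="method"):
            evaluate_once(
                default_dataset, FeatureSetSpec(("TPC",), "water"), "MLP",
                SplitConfig(seed=0),
            )


def test_count_scheduled_optimizations():
    assert count_scheduled_optimizations(98, 21, 4) == 8232
    assert count_scheduled_optimizations(1, 1, 1) == 1
    assert count_scheduled_optimizations(0, 21, 4) == 0
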