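"""Evaluation protocol: folds, metrics, sweeps, permutation, t-tests."""

import numpy as np
import pytest
from sklearn.metrics import roc_curve

from fsinet import (
    BinaryProfileSet,
    compare_models,
    compute_metrics,
    confusion_metrics,
    cross_validate,
    decay_factor_sweep,
    make_folds,
    permute_profile_edges,
)
from fsinet.evaluation import MetricReport
import pandas as pd


class TestFolds:
    def test_even_positive_split(self):
        w = np.zeros((5, 4), dtype=int)
        w.ravel()[:10] = 1
        folds = make_folds(w, n_folds=5, seed=0)
        sizes = np.bincount(folds.pos_fold, minlength=5)
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_same_seed_reproduces_assignment(self):
        w = (np.random.default_rng(1).random((8, 9)) < 0.3).astype(int)
        a = make_folds(w, 4, seed=7)
        b = make_folds(w, 4, seed=7)
        assert np.array_equal(a.pos_fold, b.pos_fold)
        assert np.array_equal(a.neg_fold, b.neg_fold)

    def test_published_scale_fold_sizes(self):
        """3,583 positives split 10 ways gives folds of 358 or 359."""
        w = np.zeros((862, 1517), dtype=np.int8)
        flat = np.random.default_rng(3).choice(862 * 1517, size=3583, replace=False)
        w.ravel()[flat] = 1
        folds = make_folds(w, 10, seed=0)
        sizes = np.bincount(folds.pos_fold, minlength=10)
        assert set(sizes) <= {358, 359}
        assert sizes.sum() == 3583

    def test_folds_partition_all_pairs(self):
        w = (np.random.default_rng(4).random((6, 7)) < 0.3).astype(int)
        folds = make_folds(w, 3, seed=2)
        union = np.zeros(w.shape, dtype=int)
        for k in range(3):
            mask = folds.test_mask(k, w.shape)
            union += mask
        assert np.all(union == 1)  # disjoint and covering

    def test_too_few_positives_raise(self):
        w = np.zeros((3, 3), dtype=int)
        w[0, 0] = 1
        with pytest.raises(ValueError, match="positive"):
            make_folds(w, 5)


class TestMetrics:
    def test_hand_computed_confusion_row(self):
        row = confusion_metrics(tp=1, fp=1, fn=2, tn=6)
        assert row["PRE"] == pytest.approx(0.5)
        assert row["REC"] == pytest.approx(1 / 3)
        assert row["F1"] == pytest.approx(0.4)
        assert row["ACC"] == pytest.approx(0.7)
        assert row["MCC"] == pytest.approx(4 / np.sqrt(336))

    def test_mcc_zero_denominator_is_zero(self):
        assert confusion_metrics(0, 0, 2, 6)["MCC"] == 0.0

    def test_perfect_separation_scores_one_everywhere(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        row = compute_metrics(scores, labels)
        for key in ("AUC", "AUPR", "PRE", "REC", "F1", "ACC", "MCC"):
            assert row[key] == pytest.approx(1.0)

    def test_reversed_ranking_gives_auc_zero(self):
        row = compute_metrics(np.array([0.1, 0.9]), np.array([1, 0]))
        assert row["AUC"] == 0.0

    def test_single_class_labels_flagged(self):
        row = compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))
        assert np.isnan(row["AUC"]) and np.isnan(row["AUPR"])

    def test_fixed_threshold_rule(self):
        row = compute_metrics(np.array([0.9, 0.4, 0.6]), np.array([1, 0, 0]),
                              threshold_rule=0.5)
        assert row["threshold"] == 0.5
        assert row["PRE"] == pytest.approx(0.5)  # 0.9 and 0.6 predicted positive

    def test_rank_auc_equals_trapezoidal_roc_integration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = rng.random(50)
            labels = (rng.random(50) < 0.3).astype(int)
            if labels.min() == labels.max():
                continue
            row = compute_metrics(scores, labels)
            fpr, tpr, _ = roc_curve(labels, scores)
            assert row["AUC"] == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


class TestCrossValidate:
    def test_no_leakage_and_report_shape(self, small_bundle, small_catalog):
        folds = make_folds(small_bundle.dti, 5, seed=1)
        report = cross_validate(small_catalog["Structures"], small_catalog["PW_Jac"],
                                small_bundle.dti, folds)
        assert len(report.per_fold) == 5
        assert set(report.means) == {"AUPR", "AUC", "PRE", "REC", "F1", "ACC", "MCC"}
        assert 0 <= report.mean("AUC") <= 1

    def test_strong_signal_beats_prevalence(self, small_bundle, small_catalog):
        folds = make_folds(small_bundle.dti, 5, seed=1)
        report = cross_validate(small_catalog["Structures"], small_catalog["PW_Jac"],
                                small_bundle.dti, folds)
        prevalence = small_bundle.dti.mean()
        assert report.mean("AUPR") > 2 * prevalence

    def test_sparse_block_strong_signal_recovers_order_of_magnitude(self):
        """With rare compatible class blocks and near-noiseless profiles,
        10-fold CV AUPR exceeds the positive prevalence by >= 10x."""
        from fsinet import kernels
        from fsinet.synthetic import SyntheticSpec, generate

        hi = {k: 0.98 for k in
              ("Structures", "DDA", "DDI", "SE", "PW", "GO", "Seq", "PPI")}
        bundle = generate(SyntheticSpec(
            seed=17, informativeness=hi, flip_rate=0.01,
            n_drug_classes=10, n_target_classes=10,
            p_within=0.4, p_between=0.001,
        ))
        folds = make_folds(bundle.dti, 10, seed=3)
        report = cross_validate(
            kernels.tanimoto_similarity(bundle.profiles["Structures"],
                                        measure_name="S", dataset_tag="S"),
            kernels.jaccard_similarity(bundle.profiles["PW"], side="target",
                                       measure_name="P", dataset_tag="P"),
            bundle.dti, folds)
        assert report.mean("AUPR") >= 10 * bundle.dti.mean()


class TestDecaySweep:
    def test_counts_and_percentages_account_for_ties(self, small_bundle, small_catalog):
        folds = make_folds(small_bundle.dti, 3, seed=2)
        models = {
            "a": (small_catalog["Structures"], small_catalog["PW_Jac"]),
            "b": (small_catalog["DDA_Jac"], small_catalog["GO_A"]),
        }
        table = decay_factor_sweep(models, small_bundle.dti, folds,
                                   alphas=(0.1, 0.5, 0.9), metrics=("AUC",))
        assert table["AUC"].sum() >= len(models)  # ties credit every tied alpha
        assert table["AUC_pct"].sum() >= 100.0 - 1e-9

    def test_single_model_credits_its_argmax_fully(self, small_bundle, small_catalog):
        folds = make_folds(small_bundle.dti, 3, seed=2)
        table = decay_factor_sweep(
            {"m": (small_catalog["Structures"], small_catalog["PW_Jac"])},
            small_bundle.dti, folds, alphas=(0.1, 0.9), metrics=("AUC",))
        assert table["AUC_pct"].max() == pytest.approx(100.0)


class TestPermutation:
    def _profiles(self, matrix):
        m, f = matrix.shape
        return BinaryProfileSet([f"e{i}" for i in range(m)],
                                [f"f{j}" for j in range(f)], matrix)

    def test_all_zero_matrix_unchanged(self):
        prof = self._profiles(np.zeros((3, 4), dtype=int))
        out = permute_profile_edges(prof, seed=1)
        assert out.matrix.sum() == 0

    def test_edge_count_conserved_and_deterministic(self):
        rng = np.random.default_rng(9)
        prof = self._profiles((rng.random((6, 8)) < 0.3).astype(int))
        a = permute_profile_edges(prof, seed=3)
        b = permute_profile_edges(prof, seed=3)
        assert a.matrix.sum() == prof.matrix.sum()
        assert np.array_equal(a.matrix, b.matrix)

    def test_different_seed_moves_edges(self):
        rng = np.random.default_rng(10)
        prof = self._profiles((rng.random((10, 12)) < 0.3).astype(int))
        out = permute_profile_edges(prof, seed=4)
        assert not np.array_equal(out.matrix, prof.matrix)


def report_from(values):
    return MetricReport(per_fold=pd.DataFrame({"AUPR": values}))


class TestCompareModels:
    def test_identical_reports_not_significant(self):
        r = report_from([0.5, 0.6, 0.7])
        out = compare_models(r, r)
        assert out.mean_difference == 0.0
        assert not out.significant_05

    def test_constant_shift_with_tiny_noise_is_significant(self):
        rng = np.random.default_rng(11)
        base = 0.5 + 0.001 * rng.random(10)
        out = compare_models(report_from(base + 0.1), report_from(base))
        assert out.significant_01

    def test_paired_t_matches_hand_computation(self):
        # textbook paired sample: differences d = [2, 4, 6], t = mean/sem = 2*sqrt(3)
        a = report_from([12.0, 14.0, 16.0])
        b = report_from([10.0, 10.0, 10.0])
        out = compare_models(a, b, sided="two-sided")
        assert out.t_statistic == pytest.approx(2 * np.sqrt(3))

    def test_unequal_folds_raise_when_paired(self):
        with pytest.raises(ValueError, match="equal fold counts"):
            compare_models(report_from([1, 2]), report_from([1, 2, 3]))
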