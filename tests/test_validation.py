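"""Cross-validation, transfer, threshold search, permutation and sign tests."""

import numpy as np
import pytest
from scipy.special import comb

from cpmsvm import (
    CohortDataset,
    EffectPlan,
    confusion_and_accuracy,
    cross_dataset_predict,
    fit_cpm,
    generate_cohort,
    generate_two_sites,
    kfold_cv,
    loocv,
    permutation_test,
    predict_cpm,
    sign_test,
    threshold_search,
)
from cpmsvm.simulate import SiteDesign, sample_effect_plan
from cpmsvm.validation import permutation_pvalue


class TestConfusion:
    def test_perfect(self):
        labels = np.array([0, 1, 0, 1])
        c, a = confusion_and_accuracy(labels, labels)
        assert a == 1.0
        assert c[0, 1] == 0 and c[1, 0] == 0

    def test_inverted(self):
        labels = np.array([0, 1, 0, 1])
        c, a = confusion_and_accuracy(1 - labels, labels)
        assert a == 0.0
        assert c[0, 0] == 0 and c[1, 1] == 0

    def test_hand_count(self):
        labels = np.array([0, 0, 1, 1])
        preds = np.array([0, 1, 1, 1])
        c, a = confusion_and_accuracy(preds, labels)
        np.testing.assert_array_equal(c, [[1, 1], [0, 2]])
        assert a == 0.75

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(37) < 0.5).astype(int)
        preds = (rng.random(37) < 0.5).astype(int)
        c, a = confusion_and_accuracy(preds, labels)
        assert c.sum() == 37
        assert a == np.trace(c) / 37


class TestSignTest:
    def test_eight_of_ten(self):
        preds = np.array([1] * 8 + [0] * 2)
        labels = np.ones(10, dtype=int)
        assert sign_test(preds, labels) == pytest.approx(56 / 1024, abs=1e-12)

    def test_five_of_ten(self):
        preds = np.array([1] * 5 + [0] * 5)
        labels = np.ones(10, dtype=int)
        assert sign_test(preds, labels) == pytest.approx(638 / 1024, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 12])
    def test_all_correct_closed_form(self, n):
        v = np.ones(n, dtype=int)
        assert sign_test(v, v) == pytest.approx(2.0**-n, abs=1e-15)

    @pytest.mark.parametrize("n,k", [(6, 3), (11, 8), (20, 13), (20, 20)])
    def test_matches_binomial_tail_enumeration(self, n, k):
        preds = np.concatenate([np.ones(k, int), np.zeros(n - k, int)])
        labels = np.ones(n, dtype=int)
        expected = sum(comb(n, j, exact=True) for j in range(k, n + 1)) / 2**n
        assert sign_test(preds, labels) == pytest.approx(expected, abs=1e-12)


class TestLoocv:
    def test_separable_high_accuracy(self):
        plan = sample_effect_plan(20, 25, 25, seed=11, delta=0.6, noise_sd=0.2)
        data = generate_cohort(plan, 50, 50, seed=12)
        out = loocv(data, "both", 0.01)
        assert out.accuracy > 0.9

    def test_matches_per_fold_fit_cpm(self, small_random_cohort):
        """The downdated fast path equals refitting each fold from scratch."""
        d = small_random_cohort
        out = loocv(d, "both", 0.2)
        all_idx = np.arange(d.n_subjects)
        for s in range(d.n_subjects):
            fold = d.subset(all_idx[all_idx != s])
            model = fit_cpm(fold, "both", 0.2)
            np.testing.assert_array_equal(
                model.selection.increased_mask, out.fold_selections[s].increased_mask
            )
            np.testing.assert_array_equal(
                model.selection.decreased_mask, out.fold_selections[s].decreased_mask
            )
            assert predict_cpm(model, d.edges[s])[0] == out.predictions[s]

    def test_confusion_consistent(self, small_random_cohort):
        out = loocv(small_random_cohort, "both", 0.1)
        assert out.confusion.sum() == out.n
        assert out.accuracy == np.trace(out.confusion) / out.n

    def test_fold_model_independent_of_heldout_subject(self, small_random_cohort):
        """Perturbing a held-out subject never changes that fold's model."""
        d = small_random_cohort
        out1 = loocv(d, "both", 0.2)
        edges = d.edges.copy()
        edges[3] += 100.0  # wreck subject 3's data
        d2 = CohortDataset(d.subject_ids, edges, d.labels, n_nodes=d.n_nodes)
        out2 = loocv(d2, "both", 0.2)
        np.testing.assert_array_equal(
            out1.fold_selections[3].increased_mask,
            out2.fold_selections[3].increased_mask,
        )
        np.testing.assert_array_equal(
            out1.fold_selections[3].decreased_mask,
            out2.fold_selections[3].decreased_mask,
        )

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortDataset(["a", "b"], np.zeros((2, 3)), np.array([0, 1]))


class TestKfold:
    def test_k_equals_n_is_loocv(self, small_random_cohort):
        d = small_random_cohort
        out_k = kfold_cv(d, "both", 0.2, k=d.n_subjects, seed=0)
        out_l = loocv(d, "both", 0.2)
        np.testing.assert_array_equal(out_k.predictions, out_l.predictions)

    def test_seeded_determinism(self, planted_cohort):
        o1 = kfold_cv(planted_cohort, "both", 0.05, k=5, seed=42)
        o2 = kfold_cv(planted_cohort, "both", 0.05, k=5, seed=42)
        np.testing.assert_array_equal(o1.predictions, o2.predictions)
        assert o1.accuracy == o2.accuracy

    def test_class_smaller_than_k(self):
        plan = EffectPlan(n_nodes=8, delta=0.0)
        data = generate_cohort(plan, 3, 10, seed=0)
        with pytest.raises(ValueError, match="stratified"):
            kfold_cv(data, "both", 0.05, k=5)

    def test_close_to_loocv_on_planted_data(self):
        plan = sample_effect_plan(15, 15, 15, seed=21, delta=0.5, noise_sd=0.2)
        diffs = []
        for rep in range(10):
            data = generate_cohort(plan, 25, 25, seed=100 + rep)
            a_k = kfold_cv(data, "both", 0.05, k=10, seed=rep).accuracy
            a_l = loocv(data, "both", 0.05).accuracy
            diffs.append(abs(a_k - a_l))
        assert np.mean(diffs) < 0.1


class TestCrossDataset:
    def test_resubstitution_when_test_is_train(self, planted_cohort):
        out = cross_dataset_predict(planted_cohort, planted_cohort, "both", 0.05)
        model = fit_cpm(planted_cohort, "both", 0.05)
        preds = predict_cpm(model, planted_cohort.edges)
        np.testing.assert_array_equal(out.predictions, preds)

    def test_flipped_test_labels_complement_accuracy(self, planted_cohort, small_random_cohort):
        plan = sample_effect_plan(15, 8, 8, seed=7, delta=0.6, noise_sd=0.2)
        test = generate_cohort(plan, 12, 12, seed=55)
        out = cross_dataset_predict(planted_cohort, test, "both", 0.05)
        flipped = CohortDataset(
            test.subject_ids, test.edges, 1 - test.labels, n_nodes=test.n_nodes
        )
        out_f = cross_dataset_predict(planted_cohort, flipped, "both", 0.05)
        assert out_f.accuracy == pytest.approx(1.0 - out.accuracy, abs=1e-12)

    def test_edge_dimension_mismatch(self, planted_cohort, small_random_cohort):
        with pytest.raises(ValueError, match="mismatch"):
            cross_dataset_predict(planted_cohort, small_random_cohort, "both", 0.05)

    def test_decreased_transfers_increased_does_not(self):
        """Shared decreased vs site-specific increased effects (overlap 0)."""
        wins = 0
        for rep in range(20):
            s1, s2 = generate_two_sites(
                SiteDesign(), EffectPlan(n_nodes=60, delta=0.2), seed=700 + rep
            )
            acc_dec = cross_dataset_predict(s1, s2, "decreased", 0.05).accuracy
            acc_inc = cross_dataset_predict(s1, s2, "increased", 0.05).accuracy
            wins += acc_dec > acc_inc
        assert wins >= 18


class TestThresholdSearch:
    def test_best_is_max_of_table(self, planted_cohort):
        best, table = threshold_search(planted_cohort, "both")
        best_acc = table[best].accuracy
        assert best_acc == max(o.accuracy for o in table.values())
        assert best in table

    def test_tie_broken_to_smallest(self):
        # strong effects: accuracy saturates at every threshold
        plan = sample_effect_plan(12, 10, 10, seed=31, delta=2.0, noise_sd=0.1)
        data = generate_cohort(plan, 10, 10, seed=32)
        best, table = threshold_search(data, "both")
        accs = {t: o.accuracy for t, o in table.items()}
        tied = [t for t, a in accs.items() if a == max(accs.values())]
        assert best == min(tied)

    def test_empty_thresholds_rejected(self, planted_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            threshold_search(planted_cohort, "both", thresholds=())


class TestPermutation:
    def test_pvalue_floor_and_ceiling(self):
        nulls = np.linspace(0.3, 0.7, 1000)
        assert permutation_pvalue(0.9, nulls) == pytest.approx(1 / 1001)
        assert permutation_pvalue(0.1, nulls) == 1.0

    def test_add_one_formula(self):
        nulls = np.array([0.5, 0.6, 0.7, 0.8])
        assert permutation_pvalue(0.7, nulls) == pytest.approx(3 / 5)  # ties count

    def test_significant_on_planted_data(self, planted_cohort):
        res = permutation_test(planted_cohort, "both", 0.01, B=99, seed=5)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.observed_accuracy > max(res.null_accuracies)

    def test_seeded_determinism_bit_identical(self, small_random_cohort):
        r1 = permutation_test(small_random_cohort, "both", 0.1, B=30, seed=9)
        r2 = permutation_test(small_random_cohort, "both", 0.1, B=30, seed=9)
        assert np.array_equal(r1.null_accuracies, r2.null_accuracies)
        assert r1.p_value == r2.p_value
        assert r1.observed_accuracy == r2.observed_accuracy

    def test_null_mean_near_chance(self, small_random_cohort):
        res = permutation_test(small_random_cohort, "both", 0.1, B=100, seed=13)
        assert 0.35 < res.null_accuracies.mean() < 0.65

    def test_invalid_b(self, small_random_cohort):
        with pytest.raises(ValueError, match="B"):
            permutation_test(small_random_cohort, "both", 0.1, B=0, seed=1)

    def test_cross_dataset_evaluator_requires_test(self, small_random_cohort):
        with pytest.raises(ValueError, match="test"):
            permutation_test(
                small_random_cohort, "both", 0.1, B=5, seed=1, evaluator="cross_dataset"
            )
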