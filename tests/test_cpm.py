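"""Edge-label correlation, directional selection, summation and model fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpmsvm import (
    CohortDataset,
    CpmModel,
    edgewise_label_correlation,
    fit_cpm,
    predict_cpm,
    select_directional_features,
    summarize_features,
)
from cpmsvm.simulate import sample_effect_plan, generate_cohort


class TestEdgewiseCorrelation:
    def test_hand_computed_example(self):
        edges = np.array([[1.0], [2.0], [3.0], [4.0]])
        labels = np.array([0, 0, 1, 1])
        r, p = edgewise_label_correlation(edges, labels)
        assert r[0] == pytest.approx(2.0 / np.sqrt(5.0), abs=1e-12)  # 0.894427
        assert p[0] == pytest.approx(0.1056, abs=1e-4)

    def test_constant_edge_convention(self):
        edges = np.column_stack([np.full(6, 2.5), np.arange(6.0)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        r, p = edgewise_label_correlation(edges, labels)
        assert r[0] == 0.0
        assert p[0] == 1.0

    def test_label_flip_negates_r_keeps_p(self, small_random_cohort):
        d = small_random_cohort
        r1, p1 = edgewise_label_correlation(d.edges, d.labels)
        r2, p2 = edgewise_label_correlation(d.edges, 1 - d.labels)
        np.testing.assert_allclose(r2, -r1, atol=1e-12)
        np.testing.assert_allclose(p2, p1, atol=1e-12)

    def test_matches_two_sample_t_test(self, small_random_cohort):
        """Point-biserial p identical to the equal-variance two-sample t p."""
        d = small_random_cohort
        _, p = edgewise_label_correlation(d.edges, d.labels)
        g0 = d.edges[d.labels == 0]
        g1 = d.edges[d.labels == 1]
        p_t = stats.ttest_ind(g0, g1, equal_var=True).pvalue
        np.testing.assert_allclose(p, p_t, atol=1e-10)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="n >= 4"):
            edgewise_label_correlation(np.zeros((3, 2)), np.array([0, 1, 1]))

    def test_single_class_labels(self):
        with pytest.raises(ValueError, match="single class"):
            edgewise_label_correlation(np.zeros((5, 2)), np.ones(5))


class TestSelection:
    def test_example_masks(self):
        r = np.array([0.5, -0.5, 0.0])
        p = np.array([0.01, 0.01, 1.0])
        sel = select_directional_features(r, p, 0.05)
        np.testing.assert_array_equal(sel.increased_mask, [True, False, False])
        np.testing.assert_array_equal(sel.decreased_mask, [False, True, False])

    def test_all_above_threshold_empty(self):
        sel = select_directional_features(
            np.array([0.9, -0.9]), np.array([0.002, 0.5]), 0.001
        )
        assert sel.n_increased == 0 and sel.n_decreased == 0

    def test_zero_r_never_selected(self):
        sel = select_directional_features(np.array([0.0]), np.array([1e-9]), 0.05)
        assert sel.n_increased == 0 and sel.n_decreased == 0

    @given(st.integers(0, 2**31))
    @settings(max_examples=25, deadline=None)
    def test_masks_disjoint_and_union(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, 50)
        p = rng.uniform(0, 1, 50)
        sel = select_directional_features(r, p, 0.2)
        assert not np.any(sel.increased_mask & sel.decreased_mask)
        union = sel.increased_mask | sel.decreased_mask
        np.testing.assert_array_equal(union, (p < 0.2) & (r != 0))

    @given(st.integers(0, 2**31))
    @settings(max_examples=25, deadline=None)
    def test_mask_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, 50)
        p = rng.uniform(0, 1, 50)
        s_small = select_directional_features(r, p, 0.01)
        s_large = select_directional_features(r, p, 0.2)
        assert np.all(s_large.increased_mask[s_small.increased_mask])
        assert np.all(s_large.decreased_mask[s_small.decreased_mask])

    def test_label_flip_swaps_masks(self, small_random_cohort):
        d = small_random_cohort
        r1, p1 = edgewise_label_correlation(d.edges, d.labels)
        r2, p2 = edgewise_label_correlation(d.edges, 1 - d.labels)
        s1 = select_directional_features(r1, p1, 0.1)
        s2 = select_directional_features(r2, p2, 0.1)
        np.testing.assert_array_equal(s1.increased_mask, s2.decreased_mask)
        np.testing.assert_array_equal(s1.decreased_mask, s2.increased_mask)


class TestSummarize:
    def test_row_sum_example(self):
        edges = np.array([[1.0, 2.0, 3.0]])
        sel = select_directional_features(
            np.array([0.5, 0.5, 0.5]), np.array([0.01, 0.9, 0.01]), 0.05
        )
        feats, empty = summarize_features(edges, sel, "increased")
        assert feats[0, 0] == 4.0
        assert not empty[0]

    def test_empty_masks_flagged_zero(self):
        sel = select_directional_features(
            np.array([0.5, -0.5]), np.array([0.9, 0.9]), 0.05
        )
        feats, empty = summarize_features(np.random.default_rng(0).normal(size=(3, 2)), sel, "both")
        np.testing.assert_array_equal(feats, 0.0)
        assert empty.all()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        edges = rng.normal(size=(7, 30))
        r = rng.uniform(-1, 1, 30)
        p = rng.uniform(0, 1, 30)
        sel = select_directional_features(r, p, 0.3)
        feats, _ = summarize_features(edges, sel, "both")
        for s in range(7):
            inc = sum(edges[s, e] for e in range(30) if sel.increased_mask[e])
            dec = sum(edges[s, e] for e in range(30) if sel.decreased_mask[e])
            assert feats[s, 0] == pytest.approx(inc, rel=1e-12)
            assert feats[s, 1] == pytest.approx(dec, rel=1e-12)


class TestFitPredict:
    def test_separable_training_accuracy(self, planted_cohort):
        model = fit_cpm(planted_cohort, "both", 0.01)
        preds = predict_cpm(model, planted_cohort.edges)
        assert (preds == planted_cohort.labels).mean() >= 0.95

    def test_wrong_direction_gives_fallback(self):
        # only decreased effects planted; increased mode at strict threshold
        plan = sample_effect_plan(12, 0, 10, seed=3, delta=1.0, noise_sd=0.1)
        data = generate_cohort(plan, 15, 15, seed=4)
        model = fit_cpm(data, "increased", 1e-6)
        assert model.is_fallback
        preds = predict_cpm(model, data.edges)
        assert np.all(preds == model.fallback_label)

    def test_predictions_ignore_unselected_edges(self, planted_cohort):
        model = fit_cpm(planted_cohort, "both", 0.01)
        rng = np.random.default_rng(9)
        test = planted_cohort.edges[:5].copy()
        base = predict_cpm(model, test)
        unselected = ~(model.selection.increased_mask | model.selection.decreased_mask)
        test[:, unselected] += rng.normal(scale=50.0, size=(5, int(unselected.sum())))
        np.testing.assert_array_equal(predict_cpm(model, test), base)

    def test_dimension_mismatch(self, planted_cohort):
        model = fit_cpm(planted_cohort, "both", 0.01)
        with pytest.raises(ValueError, match="columns"):
            predict_cpm(model, np.zeros((2, 10)))

    def test_selection_inside_training_only(self, planted_cohort):
        """The fitted model is identical whatever test data will follow."""
        m1 = fit_cpm(planted_cohort, "both", 0.05)
        m2 = fit_cpm(planted_cohort, "both", 0.05)
        np.testing.assert_array_equal(
            m1.selection.increased_mask, m2.selection.increased_mask
        )
        np.testing.assert_array_equal(m1.classifier.coef_, m2.classifier.coef_)

    def test_json_round_trip(self, planted_cohort):
        model = fit_cpm(planted_cohort, "both", 0.05)
        restored = CpmModel.from_dict(model.to_dict())
        test = planted_cohort.edges[:8]
        np.testing.assert_array_equal(
            predict_cpm(restored, test), predict_cpm(model, test)
        )

    def test_invalid_threshold(self, planted_cohort):
        with pytest.raises(ValueError, match="threshold"):
            fit_cpm(planted_cohort, "both", 1.5)

    def test_invalid_mode(self, planted_cohort):
        with pytest.raises(ValueError, match="mode"):
            fit_cpm(planted_cohort, "sideways", 0.05)
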