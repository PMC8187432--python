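import numpy as np
import pytest

import mogonet as mg
from mogonet.preprocess import apply_preprocess, fit_preprocess


def make_view(values, name="v"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return mg.OmicsView(name, [f"s{i}" for i in range(n)],
                        [f"f{j}" for j in range(d)], values)


class TestVarianceFilter:
    def test_constant_nonzero_column_dropped(self):
        view = make_view([[1, 5], [2, 5], [3, 5]])
        out = mg.variance_filter(view, 0.1)
        assert out.feature_names == ["f0"]

    def test_binary_column_kept_at_threshold(self):
        # var of {0,1} over two samples is 0.25 (population) >= 0.1
        view = make_view([[0, 1], [1, 2]])
        out = mg.variance_filter(view, 0.1)
        assert "f0" in out.feature_names

    def test_zero_mean_dropped(self):
        view = make_view([[-1, 1], [1, 2], [0, 3]])  # f0 mean 0
        out = mg.variance_filter(view, 0.0)
        assert out.feature_names == ["f1"]

    def test_all_dropped_raises_with_hint(self):
        view = make_view([[5, 5], [5, 5]])
        with pytest.raises(ValueError, match="lower the threshold"):
            mg.variance_filter(view, 0.1)

    @pytest.mark.parametrize("threshold", [0.1, 0.001])
    def test_standard_thresholds_accepted(self, threshold):
        rng = np.random.default_rng(0)
        view = make_view(rng.normal(size=(10, 5)))
        out = mg.variance_filter(view, threshold)
        assert out.n_features > 0


def brute_force_f(values, labels):
    """One-way ANOVA F from between/within mean squares, feature by feature."""
    classes = np.unique(labels)
    n, d = values.shape
    F = np.zeros(d)
    for j in range(d):
        x = values[:, j]
        grand = x.mean()
        ss_between = sum(
            (labels == c).sum() * (x[labels == c].mean() - grand) ** 2 for c in classes
        )
        ss_within = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in classes)
        df_b, df_w = len(classes) - 1, n - len(classes)
        if ss_within > 0:
            F[j] = (ss_between / df_b) / (ss_within / df_w)
        else:
            # 0/0 for a constant feature (no signal); inf for a perfect separator
            F[j] = np.inf if ss_between > 0 else 0.0
    return F


class TestAnovaPreselect:
    def setup_method(self):
        # 4 features, 2 classes, 6 samples: f0 strong, f1 weak, f2 none, f3 constant
        self.values = np.array(
            [
                [5.0, 1.1, 0.3, 2.0],
                [5.1, 0.9, 0.1, 2.0],
                [4.9, 1.3, 0.2, 2.0],
                [1.0, 1.6, 0.25, 2.0],
                [1.1, 1.4, 0.15, 2.0],
                [0.9, 1.8, 0.05, 2.0],
            ]
        )
        self.view = make_view(self.values)
        self.labels = mg.LabelVector([f"s{i}" for i in range(6)], [0, 0, 0, 1, 1, 1], 2)

    def test_f_ranking_matches_brute_force(self):
        _, F, _ = mg.anova_preselect(self.view, self.labels, n_keep=1)
        expected = brute_force_f(self.values, self.labels.labels)
        np.testing.assert_allclose(F, expected, rtol=1e-10)
        assert np.argmax(F) == 0

    def test_constant_feature_never_selected(self):
        selected, F, p_adj = mg.anova_preselect(self.view, self.labels, n_keep=2)
        assert "f3" not in selected.feature_names
        assert F[3] == 0.0 and p_adj[3] == 1.0

    def test_perfect_separator_selected_first(self):
        vals = self.values.copy()
        vals[:, 2] = [1, 1, 1, 0, 0, 0]  # zero within-class variance
        view = make_view(vals)
        selected, F, _ = mg.anova_preselect(view, self.labels, n_keep=1)
        assert selected.feature_names == ["f2"]
        assert F[2] > F[0]

    def test_warns_when_few_pass_fdr(self):
        rng = np.random.default_rng(0)
        noise = make_view(rng.normal(size=(10, 20)))
        labels = mg.LabelVector([f"s{i}" for i in range(10)], [0] * 5 + [1] * 5, 2)
        with pytest.warns(UserWarning, match="pass"):
            try:
                mg.anova_preselect(noise, labels, n_keep=15)
            except ValueError:
                pass  # zero survivors is also acceptable for pure noise

    def test_degenerate_class_errors(self):
        labels = mg.LabelVector([f"s{i}" for i in range(6)], [0, 0, 0, 0, 0, 1], 2)
        with pytest.raises(ValueError, match="at least 2 samples"):
            mg.anova_preselect(self.view, labels, n_keep=1)


class TestChooseFeatureCount:
    def test_duplicated_column_needs_largest(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 1)) + np.array([0.0] * 15 + [3.0] * 15)[:, None]
        view = make_view(np.repeat(base, 10, axis=1))
        labels = mg.LabelVector([f"s{i}" for i in range(30)], [0] * 15 + [1] * 15, 2)
        with pytest.warns(UserWarning, match="PC1"):
            count = mg.choose_feature_count(view, labels, [2, 5, 10])
        assert count == 10

    def test_isotropic_noise_takes_smallest(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(60, 40))
        values[:, :40] += np.array([0.0] * 30 + [0.5] * 30)[:, None]  # mild signal
        view = make_view(values)
        labels = mg.LabelVector([f"s{i}" for i in range(60)], [0] * 30 + [1] * 30, 2)
        count = mg.choose_feature_count(view, labels, [10, 20], fdr_alpha=0.9)
        assert count == 10

    def test_empty_candidates_error(self, trio_small):
        data, _ = trio_small
        with pytest.raises(ValueError, match="empty"):
            mg.choose_feature_count(data.views[0], data.labels, [])


class TestMinmaxScale:
    def test_basic_arithmetic(self):
        view = make_view([[2.0], [4.0], [6.0]])
        scaled, _ = mg.minmax_scale(view)
        np.testing.assert_allclose(scaled.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_maps_to_zero(self):
        view = make_view([[3.0], [3.0]])
        scaled, _ = mg.minmax_scale(view)
        np.testing.assert_array_equal(scaled.values, 0.0)

    def test_test_values_clipped(self):
        train = make_view([[2.0], [4.0]])
        _, spec = mg.minmax_scale(train)
        test = make_view([[10.0], [-5.0]])
        scaled, _ = mg.minmax_scale(test, spec)
        np.testing.assert_array_equal(scaled.values[:, 0], [1.0, 0.0])

    def test_feature_mismatch_errors(self):
        _, spec = mg.minmax_scale(make_view([[1.0], [2.0]]))
        other = make_view([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="feature set"):
            mg.minmax_scale(other, spec)


class TestFittedPipeline:
    def test_training_output_in_unit_interval(self, trio_small):
        data, _ = trio_small
        out, spec = fit_preprocess(data.views[0], data.labels)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert spec.n_preselected == out.n_features

    def test_statistics_come_from_training_rows_only(self, trio_small):
        data, _ = trio_small
        train_ids = data.sample_ids[:80]
        test_ids = data.sample_ids[80:]
        view_tr = data.views[0].subset_samples(train_ids)
        labels_tr = data.labels.subset(train_ids)
        _, spec = fit_preprocess(view_tr, labels_tr)
        test_view = data.views[0].subset_samples(test_ids)
        out = apply_preprocess(test_view, spec)
        # test rows are transformed with the training map, then clipped
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert out.feature_names == spec.feature_names

    def test_deterministic(self, trio_small):
        data, _ = trio_small
        a, _ = fit_preprocess(data.views[1], data.labels, n_keep=10, fdr_alpha=0.5)
        b, _ = fit_preprocess(data.views[1], data.labels, n_keep=10, fdr_alpha=0.5)
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.values, b.values)

    def test_whitelist_restricts_panel(self, trio_small):
        data, _ = trio_small
        keep = set(data.views[0].feature_names[:10])
        out, _ = fit_preprocess(data.views[0], data.labels, whitelist=keep)
        assert set(out.feature_names) <= keep
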