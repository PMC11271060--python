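"""Cross-tissue correlation filter, t-test filter, standardizer, LASSO."""

import numpy as np
import pandas as pd
import pytest

from plnm_radiomics.selection import (
    cross_correlation_filter,
    fit_standardizer,
    lasso_select,
    pair_key,
    select_features,
    ttest_filter,
)
from plnm_radiomics.synthetic_cohort import SimConfig, simulate_feature_tables


def frame(arr, cols=None, index=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols, index=index)


class TestCrossCorrelationFilter:
    def test_identical_column_retained_noise_dropped(self, rng):
        x = rng.normal(size=200)
        lesion = frame(np.column_stack([x, rng.normal(size=200)]), ["a", "b"])
        node = frame(np.column_stack([x, rng.normal(size=200)]), ["a", "b"])
        assert cross_correlation_filter(lesion, node) == ["a"]

    def test_hand_computed_pearson(self):
        # r((1,2,3,4),(1,2,3,5)) = 6.5 / sqrt(5 * 8.75) = 0.98270
        lesion = frame(np.array([[1], [2], [3], [4]]), ["f"])
        node = frame(np.array([[1], [2], [3], [5]]), ["f"])
        assert cross_correlation_filter(lesion, node, threshold=0.9) == ["f"]
        assert cross_correlation_filter(lesion, node, threshold=0.983) == []

    def test_anticorrelation_retained_with_abs(self, rng):
        x = rng.normal(size=50)
        lesion = frame(x[:, None], ["f"])
        node = frame(-x[:, None], ["f"])
        assert cross_correlation_filter(lesion, node) == ["f"]
        assert cross_correlation_filter(lesion, node, use_abs=False) == []

    def test_tissue_names_pair_across_tables(self, rng):
        x = rng.normal(size=30)
        lesion = frame(x[:, None], ["T2_tumor_original_glcm_Contrast"])
        node = frame(x[:, None], ["T2_node_original_glcm_Contrast"])
        assert cross_correlation_filter(lesion, node) == ["T2_tumor_original_glcm_Contrast"]
        assert pair_key("T2_tumor_x") == pair_key("T2_node_x")

    def test_any_mode_uses_best_partner(self, rng):
        x = rng.normal(size=100)
        lesion = frame(x[:, None], ["lesion_feat"])
        node = frame(np.column_stack([rng.normal(size=100), x]), ["n1", "n2"])
        assert cross_correlation_filter(lesion, node, mode="paired") == []
        assert cross_correlation_filter(lesion, node, mode="any") == ["lesion_feat"]

    def test_input_validation(self, rng):
        lesion = frame(rng.normal(size=(5, 2)))
        node = frame(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            cross_correlation_filter(lesion, node)
        with pytest.raises(ValueError):
            cross_correlation_filter(lesion.iloc[:2], lesion.iloc[:2])  # < 3 cases
        with pytest.raises(ValueError):
            cross_correlation_filter(lesion, lesion, threshold=0.0)

    def test_recovery_of_planted_signature(self):
        """Informative features pass the 0.9 filter; noise features do not."""
        recalls, false_rates = [], []
        for seed in range(10):
            cfg = SimConfig(
                n_train_pos=200, n_train_neg=10, n_internal=6, n_external=6,
                prevalence_internal=0.34, prevalence_external=0.34,
                n_features=200, n_informative=20, cross_tissue_rho=0.95, seed=seed,
            )
            tabs = simulate_feature_tables(cfg)
            pos = tabs.node.index
            kept = set(
                cross_correlation_filter(tabs.lesion.loc[pos], tabs.node, threshold=0.9)
            )
            inf = set(tabs.informative)
            recalls.append(len(kept & inf) / len(inf))
            false_rates.append(len(kept - inf) / (cfg.n_features - len(inf)))
        assert np.mean(recalls) >= 0.9
        assert np.mean(false_rates) < 0.05


class TestTtestFilter:
    def test_separating_feature_retained_constant_dropped(self, rng):
        y = np.repeat([0, 1], 50)
        X = frame(
            np.column_stack([
                y + rng.normal(0, 0.05, 100),  # separates
                np.full(100, 3.0),             # constant -> undefined t
                rng.normal(size=100),          # noise
            ]),
            ["signal", "flat", "noise"],
        )
        kept = ttest_filter(X, y)
        assert "signal" in kept and "flat" not in kept

    def test_hand_computed_t(self):
        # {1,2,3} vs {4,5,6}: t = -3.674, p = 0.0214 (equal variance)
        X = frame(np.array([1, 2, 3, 4, 5, 6.0])[:, None], ["f"])
        y = np.array([1, 1, 1, 0, 0, 0])
        assert ttest_filter(X, y, alpha=0.05, equal_var=True) == ["f"]
        assert ttest_filter(X, y, alpha=0.02, equal_var=True) == []
        from scipy import stats
        t, p = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        np.testing.assert_allclose(t, -3.6742346, rtol=1e-6)
        np.testing.assert_allclose(p, 0.021312, rtol=1e-4)

    def test_single_class_errors(self, rng):
        X = frame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            ttest_filter(X, np.ones(5))


class TestStandardizer:
    def test_train_columns_zero_mean_unit_sd(self, rng):
        X = frame(rng.normal(5, 3, size=(50, 4)))
        std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(ddof=0), 1.0, atol=1e-12)

    def test_validation_rows_use_training_parameters(self, rng):
        X = frame(rng.normal(size=(50, 3)))
        std = fit_standardizer(X)
        Z_shifted = std.transform(X + 5.0)
        assert (Z_shifted.mean() > 1.0).all()  # no refit

    def test_round_trip(self, rng):
        X = frame(rng.normal(size=(20, 3)))
        std = fit_standardizer(X)
        back = std.inverse_transform(std.transform(X))
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-12)

    def test_zero_variance_dropped_with_warning(self, rng):
        X = frame(np.column_stack([rng.normal(size=10), np.full(10, 2.0)]), ["a", "flat"])
        with pytest.warns(UserWarning):
            std = fit_standardizer(X)
        assert std.features == ["a"]


class TestLasso:
    def test_huge_penalty_empty_set(self, rng):
        X = frame(rng.normal(size=(60, 5)))
        y = rng.integers(0, 2, 60)
        kept, w = lasso_select(X, y, Cs=[1e-6], n_repeats=1, seed=0)
        assert kept == [] and w == {}

    def test_single_feature_matches_soft_threshold_oracle(self, rng):
        # orthonormal design, linear variant: beta = sign(c) max(|c| - alpha, 0)
        # with c = cov(x, y) for standardized x
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 0.5 * x + rng.normal(0, 0.3, n)
        y = y - y.mean()
        c = float(x @ y) / n
        for alpha in (0.05, 0.2, abs(c) + 0.1):
            kept, w = lasso_select(frame(x[:, None], ["f"]), y, model="linear", alpha=alpha)
            expect = np.sign(c) * max(abs(c) - alpha, 0.0)
            got = w.get("f", 0.0)
            np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_retained_set_shrinks_with_penalty(self, rng):
        cfg = SimConfig(n_train_pos=40, n_train_neg=60, n_internal=6, n_external=6,
                        prevalence_internal=0.3, prevalence_external=0.3,
                        n_features=30, n_informative=5, seed=3)
        tabs = simulate_feature_tables(cfg)
        tr = tabs.splits == "train"
        X, y = tabs.lesion[tr], tabs.labels[tr].to_numpy()
        sizes = []
        for C in (10.0, 0.1, 0.01):  # decreasing C = increasing penalty
            kept, _ = lasso_select(X, y, Cs=[C], n_repeats=1, seed=0)
            sizes.append(len(kept))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_degenerate_labels_error(self, rng):
        X = frame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            lasso_select(X, np.zeros(10))


class TestPathway:
    def test_stage_nesting_and_determinism(self):
        cfg = SimConfig(n_train_pos=60, n_train_neg=90, n_internal=6, n_external=6,
                        prevalence_internal=0.3, prevalence_external=0.3,
                        n_features=120, n_informative=15, seed=9)
        tabs = simulate_feature_tables(cfg)
        tr = tabs.splits == "train"
        X, y = tabs.lesion[tr], tabs.labels[tr].to_numpy()
        pos = tabs.node.index.intersection(X.index)
        trace, _ = select_features(
            X, y, node_train_pos=tabs.node.loc[pos], use_correlation_filter=True, seed=1
        )
        corr, tt, lasso = trace.stages["correlation"], trace.stages["ttest"], trace.stages["lasso"]
        assert set(lasso) <= set(tt) <= set(corr)
        assert set(trace.weights) == set(lasso)
        trace2, _ = select_features(
            X, y, node_train_pos=tabs.node.loc[pos], use_correlation_filter=True, seed=1
        )
        assert trace.stages == trace2.stages and trace.weights == trace2.weights
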