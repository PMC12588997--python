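"""Screening selections vs brute force; augmentation statistics; split rule."""

import numpy as np
import pandas as pd
import pytest

from leafchem.screenaug import (
    AugmentConfig,
    augment,
    elasticnet_screen,
    lasso_screen,
    pearson_screen,
    split_7_2_1,
    variance_screen,
)


class TestPearson:
    def test_perfectly_correlated_feature_retained(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        X = pd.DataFrame({"same": y, "anti": -y, "noise": rng.normal(size=50)})
        res = pearson_screen(X, y, threshold=0.6)
        assert "same" in res.selected_names
        assert "anti" in res.selected_names  # absolute-value rule
        assert res.scores["same"] == pytest.approx(1.0)
        assert res.scores["anti"] == pytest.approx(1.0)

    def test_independent_noise_dropped_at_point_three(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=1000)
        X = pd.DataFrame({"noise": rng.normal(size=1000)})
        res = pearson_screen(X, y, threshold=0.3)
        assert res.selected_names == []

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 8)),
                         columns=[f"c{i}" for i in range(8)])
        y = rng.normal(size=40)
        res = pearson_screen(X, y, threshold=0.1)
        for col in X.columns:
            r = np.corrcoef(X[col], y)[0, 1]
            assert res.scores[col] == pytest.approx(abs(r), abs=1e-12)
            assert (col in res.selected_names) == (abs(r) > 0.1)

    def test_zero_variance_feature_scores_zero(self):
        y = np.arange(10.0)
        X = pd.DataFrame({"flat": np.ones(10), "good": y})
        res = pearson_screen(X, y, threshold=0.3)
        assert res.scores["flat"] == 0.0
        assert "flat" not in res.selected_names

    def test_constant_target_raises(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError, match="constant"):
            pearson_screen(X, np.ones(5), 0.3)


class TestVariance:
    def test_selection_equals_brute_force(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(scale=rng.uniform(0.1, 3, 6), size=(30, 6)),
                         columns=[f"c{i}" for i in range(6)])
        res = variance_screen(X, threshold=1.0)
        for col in X.columns:
            v = float(np.var(X[col], ddof=1))
            assert res.scores[col] == pytest.approx(v)
            assert (col in res.selected_names) == (v > 1.0)

    def test_constant_dropped_and_high_variance_kept(self):
        X = pd.DataFrame({"flat": np.ones(20),
                          "wide": np.sqrt(2.0) * np.random.default_rng(4).normal(size=20)})
        res = variance_screen(X, threshold=0.01)
        assert "flat" not in res.selected_names
        assert "wide" in res.selected_names


class TestLassoElasticNet:
    def test_lasso_recovers_single_informative_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(100, 21))
            y = 3.0 * X[:, 0] + rng.normal(0, 0.5, 100)
            res = lasso_screen(X, y, strength=0.2, seed=seed)
            hits += "f0" in res.selected_names
        assert hits >= 19

    def test_huge_strength_empties_selection(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 50)
        assert lasso_screen(X, y, strength=1e6).selected_names == []

    def test_zero_strength_is_least_squares(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.1, 50)
        res = lasso_screen(X, y, strength=0)
        assert len(res.selected_names) == 5

    def test_grouping_effect_on_duplicated_columns(self):
        en_both, lasso_single = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 10))
            X[:, 1] = X[:, 0]
            y = 2.0 * X[:, 0] + rng.normal(0, 0.3, 80)
            en = elasticnet_screen(X, y, l1_strength=0.05, l2_strength=0.5, seed=seed)
            las = lasso_screen(X, y, strength=0.1, seed=seed)
            en_both += {"f0", "f1"} <= set(en.selected_names)
            lasso_single += len({"f0", "f1"} & set(las.selected_names)) <= 1
        assert en_both >= 15
        assert lasso_single >= 15

    def test_ridge_limit_keeps_everything(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 50)
        res = elasticnet_screen(X, y, l1_strength=0.0, l2_strength=1.0)
        assert len(res.selected_names) == 6

    def test_l2_zero_equals_lasso(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 8))
        y = X[:, 2] - 0.5 * X[:, 5] + rng.normal(0, 0.2, 60)
        en = elasticnet_screen(X, y, l1_strength=0.1, l2_strength=0.0, seed=3)
        las = lasso_screen(X, y, strength=0.1, seed=3)
        assert en.selected_names == las.selected_names
        np.testing.assert_allclose(en.scores, las.scores, atol=1e-8)

    def test_monotonicity_of_selection_size(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 15))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.3, 80)
        sizes = [len(lasso_screen(X, y, strength=s).selected_names)
                 for s in (0.01, 0.1, 0.5, 2.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestAugment:
    def test_gaussian_statistics(self):
        cfg = AugmentConfig(scale_range=(1.0, 1.0), offset_range=(0.0, 0.0), seed=0)
        base = np.zeros((1, 100_000))
        out = augment(base, cfg)[1]
        assert abs(out.mean()) < 0.005
        assert out.var() == pytest.approx(0.01, abs=0.001)

    def test_offsets_confined_to_range(self):
        cfg = AugmentConfig(gaussian_variance=0.0, scale_range=(1.0, 1.0), seed=1)
        base = np.zeros((100_000, 1))
        offsets = augment(base, cfg)[100_000:]
        assert offsets.min() > -0.01 and offsets.max() < 0.01

    def test_degenerate_config_is_identity(self):
        cfg = AugmentConfig(gaussian_variance=0.0, scale_range=(1.0, 1.0),
                            offset_range=(0.0, 0.0))
        x = np.random.default_rng(2).normal(size=(5, 4))
        out = augment(x, cfg)
        np.testing.assert_array_equal(out[5:], x)
        np.testing.assert_array_equal(out[:5], x)

    def test_non_training_partition_rejected(self):
        with pytest.raises(ValueError, match="training"):
            augment(np.zeros((3, 2)), AugmentConfig(), partition="val")

    def test_reproducible_from_seed(self):
        x = np.random.default_rng(3).normal(size=(4, 6))
        a = augment(x, AugmentConfig(seed=7))
        b = augment(x, AugmentConfig(seed=7))
        np.testing.assert_array_equal(a, b)


class TestSplit:
    def test_ten_records_give_7_2_1(self):
        parts = split_7_2_1(10, seed=0)
        assert (len(parts.train), len(parts.val), len(parts.test)) == (7, 2, 1)

    def test_315_records_follow_floor_rule(self):
        parts = split_7_2_1(315, seed=0)
        assert (len(parts.train), len(parts.val), len(parts.test)) == (220, 63, 32)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property_random_sizes(self, seed):
        rng = np.random.default_rng(seed)
        for n in rng.integers(10, 400, size=10):
            n = int(n)
            parts = split_7_2_1(n, seed=seed)
            union = np.concatenate([parts.train, parts.val, parts.test])
            assert len(union) == n
            assert len(np.unique(union)) == n

    def test_grouping_keeps_plants_together(self):
        groups = np.repeat(np.arange(12), 5)  # 12 plants x 5 leaves
        parts = split_7_2_1(len(groups), seed=1, group_by=groups)
        for part in (parts.train, parts.val, parts.test):
            for g in np.unique(groups[part]):
                assert np.all(np.isin(np.flatnonzero(groups == g), part))

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_7_2_1(9)
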