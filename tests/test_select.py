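"""ANOVA screening and SVM/AUC channel selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from asft.io import FeatureTable, all_feature_keys
from asft.select import (SelectionConfig, anova_screen, apply_selection,
                         channel_band_auc, fit_selection, select_channels,
                         svm_auc)


def pairwise_auc(scores, labels):
    """Brute-force oracle: P(s⁺ > s⁻) + ½ P(s⁺ == s⁻) over all pairs."""
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_table(rng, n_per_state=40, channels=("FP1", "O1", "O2", "C3"),
               shift_channels=(), shift=0.0):
    """Random-feature table with an optional mean shift planted per channel."""
    keys = all_feature_keys(channels=channels)
    n = 2 * n_per_state
    X = rng.standard_normal((n, len(keys)))
    states = ["alert"] * n_per_state + ["fatigue"] * n_per_state
    for j, k in enumerate(keys):
        if k.channel in shift_channels:
            X[n_per_state:, j] += shift
    meta = pd.DataFrame({
        "subject_id": [f"S{i % 4}" for i in range(n)],
        "session": ["pre"] * n_per_state + ["post"] * n_per_state,
        "state": states,
        "segment_index": list(range(n_per_state)) * 2,
    })
    return FeatureTable(X, keys, meta)


class TestSvmAuc:
    def test_perfect_separation(self):
        assert svm_auc(np.r_[np.zeros(5), np.ones(5)],
                       np.r_[-np.ones(5), np.ones(5)]) == 1.0

    def test_reversed_separation(self):
        assert svm_auc(np.r_[np.ones(5), np.zeros(5)],
                       np.r_[-np.ones(5), np.ones(5)]) == 0.0

    def test_random_scores_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = np.where(rng.random(4000) < 0.5, 1, -1)
        assert abs(svm_auc(scores, labels) - 0.5) < 0.05

    def test_six_point_tie_case(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        labels = np.array([-1, -1, 1, -1, 1, 1])
        assert svm_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels))

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 50),
           st.booleans())
    def test_rank_formula_equals_pairwise_oracle(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        scores = (rng.integers(0, 5, n).astype(float) if with_ties
                  else rng.standard_normal(n))
        labels = np.where(rng.random(n) < 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 1, -1
        assert svm_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(30)
        labels = np.where(rng.random(30) < 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[:2] = [1, -1]
        base = svm_auc(scores, labels)
        assert svm_auc(3 * scores + 7, labels) == pytest.approx(base)
        assert svm_auc(np.exp(scores), labels) == pytest.approx(base)

    def test_matches_sklearn(self, rng):
        scores = rng.integers(0, 8, 200).astype(float)
        labels = np.where(rng.random(200) < 0.4, 1, -1)
        assert svm_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels > 0, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_auc(np.arange(4.0), np.ones(4))


class TestAnovaScreen:
    def test_f_equals_t_squared(self, rng):
        a, b = rng.standard_normal((2, 30))
        F = stats.f_oneway(a, b).statistic
        t = stats.ttest_ind(a, b).statistic
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_planted_shift_detected(self, rng):
        table = make_table(rng, n_per_state=200, shift_channels=("O1",),
                           shift=5.0)
        res = anova_screen(table, alpha=0.01, min_combos=1)
        idx = {k: i for i, k in enumerate(table.keys)}
        shifted = [res.p[i] for k, i in idx.items() if k.channel == "O1"]
        assert max(shifted) < 1e-6

    def test_rejection_probability_of_large_shift(self, rng):
        # d = 5 pooled SDs, n = 200/group: essentially always rejected
        rejections = 0
        for _ in range(50):
            a = rng.standard_normal(200)
            b = rng.standard_normal(200) + 5.0
            rejections += stats.f_oneway(a, b).pvalue < 0.01
        assert rejections == 50

    def test_null_calibration_coarse(self, rng):
        table = make_table(rng, n_per_state=50)
        res = anova_screen(table, alpha=0.01, min_combos=1)
        rate = float((res.p < 0.01).mean())
        # 128 null columns: generous bound around the nominal 1 %
        assert rate < 0.08

    def test_constant_column_gets_p_one(self, rng):
        table = make_table(rng, n_per_state=10)
        table.X[:, 0] = 2.5
        res = anova_screen(table, min_combos=1)
        assert res.p[0] == 1.0

    def test_single_state_rejected(self, rng):
        table = make_table(rng, n_per_state=10)
        half = table.take(np.arange(10))
        with pytest.raises(ValueError):
            anova_screen(half)

    def test_retention_rule_counts(self, rng):
        table = make_table(rng, n_per_state=100, shift_channels=("O1", "O2"),
                           shift=3.0)
        res = anova_screen(table, alpha=0.01, min_combos=8)
        # every feature is shifted on 2 channels × 4 bands = 8 combos
        assert res.n_combos == 16  # 4 bands × 4 channels
        assert set(res.retained_features) == set(
            f for f, c in res.combo_counts.items() if c >= 8)


class TestChannelSelection:
    def test_planted_channel_has_high_auc(self, rng):
        table = make_table(rng, n_per_state=100, shift_channels=("O1",),
                           shift=3.0)
        m, s = channel_band_auc(table, "O1", "alpha",
                                ("MEA", "ENE", "VAR", "RMS"), n_folds=5)
        assert m > 0.9

    def test_noise_channel_near_chance(self, rng):
        table = make_table(rng, n_per_state=500)
        m, _ = channel_band_auc(table, "FP1", "alpha",
                                ("MEA", "ENE", "VAR", "RMS"), n_folds=5)
        assert 0.4 < m < 0.6

    def test_deterministic_under_seed(self, rng):
        table = make_table(rng, n_per_state=50, shift_channels=("O1",),
                           shift=1.0)
        r1 = channel_band_auc(table, "O1", "beta", ("ENE", "RMS"), n_folds=5,
                              seed=3)
        r2 = channel_band_auc(table, "O1", "beta", ("ENE", "RMS"), n_folds=5,
                              seed=3)
        assert r1 == r2

    def test_cross_band_variant_uses_all_bands(self, rng):
        table = make_table(rng, n_per_state=50, shift_channels=("O1",),
                           shift=2.0)
        m, _ = channel_band_auc(table, "O1", None, ("ENE", "RMS"), n_folds=5)
        assert m > 0.9

    def test_k_equals_all_channels(self, rng):
        table = make_table(rng, n_per_state=30)
        res = select_channels(table, ("ENE", "RMS"), k=4, n_folds=5)
        assert set(res.retained_channels) == set(res.ranked_channels)
        assert len(res.ranked_channels) == 4

    def test_planted_subset_recovered(self, rng):
        table = make_table(rng, n_per_state=120,
                           shift_channels=("O1", "O2"), shift=2.0)
        res = select_channels(table, ("MEA", "ENE", "VAR", "RMS"), k=2,
                              n_folds=5, seed=0)
        assert set(res.retained_channels) == {"O1", "O2"}

    def test_k_too_large(self, rng):
        table = make_table(rng, n_per_state=30)
        with pytest.raises(ValueError):
            select_channels(table, ("ENE",), k=5, n_folds=5)


class TestApplySelection:
    def test_512_to_192(self, rng):
        table = make_table(rng, n_per_state=2,
                           channels=tuple(all_feature_keys()[i].channel
                                          for i in range(16)))
        assert table.n_columns == 512
        out = apply_selection(
            table, ("ENE", "VAR", "RMS", "PSD", "CF", "MSF"),
            ("O1", "O2", "T3", "T4", "C3", "C4", "FP1", "FP2"))
        assert out.n_columns == 192
        assert out.n_samples == table.n_samples

    def test_identity_selection(self, rng):
        table = make_table(rng, n_per_state=3)
        out = apply_selection(table,
                              tuple(dict.fromkeys(k.feature for k in table.keys)),
                              tuple(dict.fromkeys(k.channel for k in table.keys)))
        assert out.keys == table.keys
        np.testing.assert_array_equal(out.X, table.X)

    def test_empty_selection_rejected(self, rng):
        table = make_table(rng, n_per_state=3)
        with pytest.raises(ValueError):
            apply_selection(table, (), ("O1",))


class TestFitSelection:
    def test_modes_produce_nested_widths(self, medium_study_table):
        table = medium_study_table
        none = fit_selection(table, SelectionConfig(mode="none"))
        feats = fit_selection(table, SelectionConfig(
            mode="features", min_combos=16))
        full = fit_selection(table, SelectionConfig(
            mode="features+channels", min_combos=16, k=8, svm_folds=5))
        w_none = none.apply(table).n_columns
        w_feat = feats.apply(table).n_columns
        w_full = full.apply(table).n_columns
        assert w_none == 512
        assert w_none > w_feat > w_full
        assert set(full.retained_features) >= {"ENE", "RMS"}

    def test_screen_failure_raises(self, rng):
        table = make_table(rng, n_per_state=20)  # pure noise
        with pytest.raises(ValueError):
            fit_selection(table, SelectionConfig(min_combos=16))
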