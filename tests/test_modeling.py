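"""Selection chain, SMOTE and the RFE-RF classifier."""

import numpy as np
import pandas as pd
import pytest

from deltarad.core import SUBTYPES
from deltarad.features import all_feature_names
from deltarad.modeling import (
    ModelingConfig,
    elasticnet_select,
    mrmr_select,
    radiomics_columns,
    smote_augment,
    split_cohort,
    train_rfe_rf,
    zscore_fit_apply,
)

from conftest import make_feature_table

SMALL = ModelingConfig(n_trees=80, n_trees_cv=40, cv_repeats=1, seed=0)


class TestSplit:
    def test_278_cohort_gives_222_train_56_test(self):
        df = make_feature_table(n=278, n_pcr=74, seed=2)
        out = split_cohort(df, seed=0)
        assert (out["split"] == "train").sum() == 222
        assert (out["split"] == "test").sum() == 56

    def test_small_split_counts(self):
        df = make_feature_table(n=10, n_pcr=5, seed=3)
        out = split_cohort(df, 0.8, seed=0)
        assert (out["split"] == "train").sum() == 8

    def test_stratification_within_five_points(self):
        df = make_feature_table(n=278, n_pcr=74, seed=4)
        out = split_cohort(df, seed=1)
        frac = {
            s: (g["label"] == "pCR").mean() for s, g in out.groupby("split")
        }
        assert abs(frac["train"] - frac["test"]) < 0.05

    def test_missing_class_raises(self):
        df = make_feature_table(n=20, n_pcr=20, seed=5)
        with pytest.raises(ValueError):
            split_cohort(df)


class TestZScore:
    def test_train_columns_standardized(self):
        df = make_feature_table(n=40, n_pcr=15, seed=6)
        cols = all_feature_names()[:10]
        out, mean, sd = zscore_fit_apply(df, df, cols)
        assert np.allclose(out[cols].mean(), 0.0, atol=1e-10)
        assert np.allclose(out[cols].std(ddof=1), 1.0, atol=1e-10)

    def test_test_rows_use_train_statistics(self):
        df = make_feature_table(n=40, n_pcr=15, seed=7)
        cols = all_feature_names()[:5]
        train = df.iloc[:30]
        out, mean, sd = zscore_fit_apply(train, df, cols)
        manual = (df.iloc[35][cols] - train[cols].mean()) / train[cols].std(ddof=1)
        assert np.allclose(out.iloc[35][cols].to_numpy(dtype=float),
                           manual.to_numpy(dtype=float))

    def test_constant_column_dropped_with_warning(self):
        df = make_feature_table(n=30, n_pcr=10, seed=8)
        col = all_feature_names()[0]
        df[col] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out, mean, sd = zscore_fit_apply(df, df, all_feature_names()[:4])
        assert col not in out.columns


class TestMRMR:
    def test_255_features_keep_204(self):
        df = make_feature_table(n=60, n_pcr=20, seed=9)
        y = (df["label"] == "pCR").astype(int).to_numpy()
        ranking, kept = mrmr_select(df[all_feature_names()], y)
        assert len(ranking) == 255
        assert len(kept) == 204

    def test_ten_features_keep_eight(self):
        df = make_feature_table(n=60, n_pcr=20, seed=10)
        _, kept = mrmr_select(df[all_feature_names()[:10]], y=(df["label"] == "pCR").astype(int).to_numpy())
        assert len(kept) == 8

    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 120)
        X = pd.DataFrame(rng.standard_normal((120, 12)), columns=[f"f{i}" for i in range(12)])
        X["oracle"] = y.astype(float)
        ranking, _ = mrmr_select(X, y)
        assert ranking[0] == "oracle"

    def test_single_feature_raises(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            mrmr_select(X, np.arange(10) % 2)


class TestElasticNet:
    def test_strong_effect_retained(self):
        rng = np.random.default_rng(12)
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.standard_normal((n, 20)), columns=[f"f{i}" for i in range(20)])
        X["hit"] = y + 0.3 * rng.standard_normal(n)
        X = (X - X.mean()) / X.std(ddof=1)
        kept, importance = elasticnet_select(X, y, seed=0)
        assert "hit" in kept
        assert set(kept) <= set(X.columns)

    def test_pure_noise_selects_almost_nothing(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(
            rng.standard_normal((400, 60)), columns=[f"f{i}" for i in range(60)]
        )
        y = rng.integers(0, 2, 400)
        with pytest.warns(UserWarning):
            kept, _ = elasticnet_select(X, y, seed=1)
        assert len(kept) <= 3  # at most 5% of 60


class TestSMOTE:
    def test_synthetic_rows_lie_between_same_class_parents(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(6, 1, (12, 5))])
        y = np.array([0] * 40 + [1] * 12)
        Xa, ya, synth = smote_augment(X, y, rng=np.random.default_rng(0))
        assert (ya == 0).sum() == (ya == 1).sum()
        for xi, yi in zip(Xa[synth], ya[synth]):
            members = X[y == yi]
            lo = members.min(axis=0) - 1e-9
            hi = members.max(axis=0) + 1e-9
            assert np.all(xi >= lo) and np.all(xi <= hi)

    def test_draw_ratio_favours_minority_three_to_one(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(0, 1, (400, 3)), rng.normal(5, 1, (40, 3))])
        y = np.array([0] * 400 + [1] * 40)
        _, ya, synth = smote_augment(X, y, rng=np.random.default_rng(1))
        new = ya[synth]
        ratio = (new == 1).sum() / max(1, (new == 0).sum())
        assert 2.2 < ratio < 4.2

    def test_small_minority_reduces_k_with_warning(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(5, 1, (4, 3))])
        y = np.array([0] * 12 + [1] * 4)
        with pytest.warns(UserWarning, match="reduced k"):
            Xa, ya, _ = smote_augment(X, y, k=5, rng=np.random.default_rng(2))
        assert (ya == 0).sum() == (ya == 1).sum()


class TestTrainRFERF:
    def test_strong_signal_reaches_high_cv_auc(self, signal_table):
        model = train_rfe_rf(signal_table, variant=1, config=SMALL)
        assert model.cv_auc > 0.9
        assert model.forest.n_estimators == SMALL.n_trees

    def test_out_of_fold_predictions_cover_each_row_once(self, signal_table):
        model = train_rfe_rf(signal_table, variant=1, config=SMALL)
        n_train = (signal_table["split"] == "train").sum()
        counts = model.cv_predictions.groupby("repeat")["row"].count()
        assert (counts == n_train).all()
        for _, g in model.cv_predictions.groupby("repeat"):
            assert sorted(g["row"]) == list(range(n_train))

    def test_deterministic_under_fixed_seed(self, signal_table):
        a = train_rfe_rf(signal_table, variant=1, config=SMALL)
        b = train_rfe_rf(signal_table, variant=1, config=SMALL)
        assert a.features == b.features
        assert a.cv_auc == b.cv_auc
        probe = signal_table[signal_table["split"] == "train"]
        assert np.array_equal(a.predict_scores(probe), b.predict_scores(probe))

    def test_perturbing_test_rows_leaves_model_identical(self, signal_table):
        tampered = signal_table.copy()
        test_rows = tampered["split"] == "test"
        cols = all_feature_names()
        tampered.loc[test_rows, cols] = tampered.loc[test_rows, cols] * 3.0 + 11.0
        a = train_rfe_rf(signal_table, variant=1, config=SMALL)
        b = train_rfe_rf(tampered, variant=1, config=SMALL)
        probe = signal_table[signal_table["split"] == "train"]
        assert a.features == b.features
        assert a.threshold == b.threshold
        assert np.array_equal(a.predict_scores(probe), b.predict_scores(probe))

    def test_variant2_appends_subtype_columns(self, signal_table):
        model = train_rfe_rf(signal_table, variant=2, config=SMALL)
        # subtype indicators bypass the radiomics pre-selection
        assert model.variant == 2
        assert set(model.features) <= set(
            model.selection.elasticnet_kept
            or model.selection.mrmr_kept
        ) | {f"subtype_{s}" for s in SUBTYPES}

    def test_variant3_excludes_intensity_features(self, signal_table):
        from deltarad.features import intensity_feature_names

        cols = radiomics_columns(signal_table, variant=3)
        assert len(cols) == 243
        model = train_rfe_rf(signal_table, variant=3, config=SMALL)
        assert not set(model.features) & set(intensity_feature_names())

    def test_invalid_variant_raises(self, signal_table):
        with pytest.raises(ValueError):
            train_rfe_rf(signal_table, variant=4, config=SMALL)
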