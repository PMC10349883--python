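import numpy as np
import pandas as pd
import pytest

from sleepsci.features import feature_manifest
from sleepsci.io import FeatureTable
from sleepsci.model import (KNNFeatureImputer, FoldModel, assemble_features,
                            bai_feature_subset, electrode_subset,
                            extract_features, fit_final_model, knn_impute,
                            nested_cv_elastic_net, run_electrode_ablation,
                            sci_score, train_bai)
from sleepsci.synthetic import (CohortGenSpec, SUPPORT_BETAS, simulate_cohort)


class TestManifest:
    @pytest.mark.parametrize("electrode_set,n",
                             [("central", 212), ("all", 532)])
    def test_counts_and_uniqueness(self, electrode_set, n):
        names = feature_manifest(electrode_set)
        assert len(names) == n
        assert len(set(names)) == n

    def test_central_prefix_of_all(self):
        assert feature_manifest("all")[:212] == feature_manifest("central")


class TestAssembly:
    def test_extracted_night_has_full_central_vector(self, night):
        row = extract_features(night["raw"], night["hypnogram"],
                               electrode_set="central")
        assert list(row.index) == feature_manifest("central")
        assert row.notna().all()

    def test_extraction_deterministic(self, short_night):
        a = extract_features(short_night["raw"], short_night["hypnogram"])
        b = extract_features(short_night["raw"], short_night["hypnogram"])
        assert np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)

    def test_incomplete_blocks_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            assemble_features({}, {}, {}, "central")


def _toy_table(n=30, d=8, seed=0, missing=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, d)),
                      columns=[f"f{j}" for j in range(d)],
                      index=[f"s{i}" for i in range(n)])
    if missing is not None:
        for i, j in missing:
            df.iloc[i, j] = np.nan
    return df


class TestKNNImputation:
    def test_complete_table_identity(self):
        df = _toy_table()
        out = knn_impute(FeatureTable(df), k=5)
        assert np.array_equal(out.values, df.to_numpy())

    def test_constant_neighborhood_imputes_the_constant(self):
        df = _toy_table(n=20)
        df.iloc[0, 0] = np.nan
        df.iloc[1:, 0] = 7.0
        out = knn_impute(FeatureTable(df), k=10)
        assert out.df.iloc[0, 0] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        df = _toy_table(n=25, d=6, seed=2)
        holes = {(int(i), int(j))
                 for i, j in zip(rng.integers(0, 25, 15),
                                 rng.integers(0, 6, 15))}
        for i, j in holes:
            df.iloc[i, j] = np.nan
        k = 4
        out = knn_impute(FeatureTable(df), k=k)
        # oracle: explicit z-scoring, RMS distance over shared features,
        # stable sort, mean of the k nearest donors
        X = df.to_numpy()
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        Z = (X - mu) / sd
        for i, j in holes:
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for t in range(25):
                if t == i:
                    continue
                shared = ~np.isnan(Z[i]) & ~np.isnan(Z[t])
                if shared.sum() == 0 or np.isnan(Z[t, j]):
                    continue
                d = np.sqrt(np.mean((Z[i, shared] - Z[t, shared]) ** 2))
                dists.append((d, t))
            dists.sort(key=lambda p: (p[0], p[1]))
            donors = [t for _, t in dists[:k]]
            want = np.mean(Z[donors, j]) * sd[j] + mu[j]
            assert out.df.iloc[i, j] == pytest.approx(want, rel=1e-9)

    def test_feature_missing_everywhere_rejected(self):
        df = _toy_table(n=10)
        df.iloc[:, 3] = np.nan
        with pytest.raises(ValueError, match="f3"):
            knn_impute(FeatureTable(df), k=3)

    def test_transform_uses_training_pool_only(self):
        train = _toy_table(n=20, seed=3)
        imp = KNNFeatureImputer(5).fit(train)
        test = _toy_table(n=4, seed=4)
        test.iloc[0, 2] = np.nan
        out = imp.transform(test)
        assert not out.isna().any().any()


def _cohort_table(n=60, seed=0, target_r=0.7):
    from sleepsci.synthetic import DEFAULT_BETAS
    spec = CohortGenSpec(n_subjects=n, betas=dict(DEFAULT_BETAS),
                         target_r={"total": target_r}, seed=seed)
    cohort, table, info = simulate_cohort(spec)
    return cohort, table, info


class TestNestedCV:
    def test_every_subject_predicted_exactly_once(self, fast_model_cfg):
        cohort, table, _ = _cohort_table(n=60, seed=1)
        res = nested_cv_elastic_net(table, cohort["total"].to_numpy(),
                                    seed=1, cfg=fast_model_cfg)
        assert not np.isnan(res.y_pred).any()
        assert sorted(np.bincount(res.fold_assignment)) == [6] * 10

    def test_no_leak_from_test_fold_targets(self, fast_model_cfg):
        cohort, table, _ = _cohort_table(n=40, seed=2)
        y = cohort["total"].to_numpy()
        res1 = nested_cv_elastic_net(table, y, seed=2, cfg=fast_model_cfg)
        fold0 = res1.fold_assignment == 0
        y2 = y.copy()
        y2[fold0] += 1000.0 * np.random.default_rng(0).normal(
            size=fold0.sum())
        res2 = nested_cv_elastic_net(table, y2, seed=2, cfg=fast_model_cfg)
        assert np.array_equal(res1.fold_models[0].coef,
                              res2.fold_models[0].coef)
        assert res1.fold_models[0].intercept == res2.fold_models[0].intercept

    def test_noiseless_target_near_perfect(self, fast_model_cfg):
        cohort, table, _ = _cohort_table(n=60, seed=3, target_r=1.0)
        res = nested_cv_elastic_net(table, cohort["total"].to_numpy(),
                                    seed=3, cfg=fast_model_cfg)
        assert res.r_heldout >= 0.99

    def test_constant_target_rejected(self, fast_model_cfg):
        _, table, _ = _cohort_table(n=30, seed=4)
        with pytest.raises(ValueError, match="constant"):
            nested_cv_elastic_net(table, np.ones(30), cfg=fast_model_cfg)

    def test_imputation_fitted_inside_folds(self, fast_model_cfg):
        from sleepsci.synthetic import DEFAULT_BETAS
        spec = CohortGenSpec(n_subjects=40, betas=dict(DEFAULT_BETAS),
                             target_r={"total": 0.9},
                             missing_rem_frac=0.2, seed=5)
        cohort, table, _ = simulate_cohort(spec)
        res = nested_cv_elastic_net(table, cohort["total"].to_numpy(),
                                    seed=5, cfg=fast_model_cfg)
        assert not np.isnan(res.y_pred).any()

    def test_support_recovery_union_over_folds(self):
        # 10 true coefficients at r* = 0.8: fold-union recovers >= 7
        recovered = []
        for sd in (1, 2, 3):
            spec = CohortGenSpec(n_subjects=150,
                                 betas={"total": dict(SUPPORT_BETAS)},
                                 target_r={"total": 0.8}, seed=sd)
            cohort, table, _ = simulate_cohort(spec)
            res = nested_cv_elastic_net(table, cohort["total"].to_numpy(),
                                        seed=sd)
            union = set()
            for m in res.fold_models:
                union |= {m.feature_names[j]
                          for j in np.flatnonzero(m.coef)}
            recovered.append(len(union & set(SUPPORT_BETAS)))
        assert np.median(recovered) >= 7


class TestElectrodeAblation:
    def test_one_result_per_electrode_set(self, fast_model_cfg):
        spec = CohortGenSpec(n_subjects=40, electrode_set="all",
                             betas={"total": dict(SUPPORT_BETAS)},
                             target_r={"total": 0.9}, seed=9)
        cohort, table, _ = simulate_cohort(spec)
        report = run_electrode_ablation(table, cohort["total"].to_numpy(),
                                        seed=9, cfg=fast_model_cfg)
        assert list(report["electrode_set"]) == ["central", "frontal",
                                                 "occipital", "all"]
        assert list(report["n_features"]) == [212, 212, 212, 532]
        assert report["r_heldout"].notna().all()

    def test_subset_projection_counts(self):
        spec = CohortGenSpec(n_subjects=25, electrode_set="all", seed=10)
        _, table, _ = simulate_cohort(spec)
        for es, n in (("central", 212), ("frontal", 212),
                      ("occipital", 212), ("all", 532)):
            assert electrode_subset(table, es).df.shape[1] == n


class TestScoring:
    def _model(self, d=5):
        return FoldModel(feature_names=[f"f{j}" for j in range(d)],
                         coef=np.zeros(d), intercept=2.5,
                         mean=np.zeros(d), sd=np.ones(d),
                         alpha=0.1, l1_ratio=0.5)

    def test_zero_coefficients_gives_intercept(self):
        assert sci_score(np.ones(5), self._model()) == 2.5

    def test_single_coefficient(self):
        m = self._model()
        m.coef = np.array([0, 0, 3.0, 0, 0])
        m.mean = np.array([0, 0, 1.0, 0, 0])
        m.sd = np.array([1, 1, 2.0, 1, 1])
        x = np.array([0, 0, 5.0, 0, 0])
        assert sci_score(x, m) == pytest.approx(2.5 + 3.0 * (5 - 1) / 2)

    def test_batch_equals_per_row(self):
        rng = np.random.default_rng(0)
        m = self._model()
        m.coef = rng.normal(size=5)
        X = rng.normal(size=(7, 5))
        batch = sci_score(X, m)
        rows = [sci_score(x, m) for x in X]
        assert np.allclose(batch, rows)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            sci_score(np.ones(3), self._model())


class TestBrainAge:
    def test_subset_restricts_to_waveform_and_frequency(self):
        _, table, _ = _cohort_table(n=25, seed=6)
        sub = bai_feature_subset(table)
        assert sub.df.shape[1] == 160
        assert all(c.startswith(("wave_", "freq_"))
                   for c in sub.df.columns)

    def test_perfect_age_signal_gives_small_bai(self, fast_model_cfg):
        age_eff = {f: s for f, s in zip(
            [c for c in feature_manifest("central")
             if c.startswith("freq_N3_C_relpow")][:6],
            [5.0, -5.0, 4.0, -4.0, 5.0, 4.0])}
        spec = CohortGenSpec(n_subjects=60, age_effect=age_eff, seed=7)
        cohort, table, _ = simulate_cohort(spec)
        ages = cohort["age"].to_numpy()
        bai, res = train_bai(table, ages, seed=7, cfg=fast_model_cfg)
        assert res.r_heldout > 0.95
        assert np.abs(bai).mean() < 0.25 * ages.std()

    def test_bai_unbiased_and_shift_raises_it(self, fast_model_cfg):
        age_eff = {"freq_N3_C_relpow_delta_mean": -2.0,
                   "freq_N3_C_ratio_dt_mean": -2.0,
                   "wave_N3_C3-M2_linelength": -1.5,
                   "freq_W_C_relpow_alpha_mean": -1.5}
        spec = CohortGenSpec(n_subjects=60, age_effect=age_eff, seed=8)
        cohort, table, _ = simulate_cohort(spec)
        ages = cohort["age"].to_numpy()
        bai, res = train_bai(table, ages, seed=8, cfg=fast_model_cfg)
        assert abs(bai.mean()) < 0.3 * ages.std()
        # shift one subject's features toward the old profile
        final = fit_final_model(bai_feature_subset(table), ages, res,
                                fast_model_cfg)
        x = bai_feature_subset(table).df.iloc[0].to_numpy().copy()
        pred_before = sci_score(x, final)
        names = list(bai_feature_subset(table).df.columns)
        for f, s in age_eff.items():
            x[names.index(f)] += 2.0 * s * 1.0   # two z-age units older
        assert sci_score(x, final) > pred_before
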