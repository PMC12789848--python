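"""kNN mutual information, importance profiles, robust trends, clustering."""
import numpy as np
import pandas as pd
import pytest

from wetlandghg.drivers import (
    cluster_siteyears,
    importance_profile,
    mann_kendall,
    mi_knn,
    theil_sen,
)


def gaussian_pair(rho, n, seed):
    r = np.random.default_rng(seed)
    x = r.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal(n)
    return x, y


class TestMIEstimator:
    def test_gaussian_analytic_oracle(self):
        x, y = gaussian_pair(0.9, 2000, seed=0)
        analytic = -0.5 * np.log(1 - 0.9**2)  # 0.830 nats
        assert mi_knn(x, y, k=3) == pytest.approx(analytic, abs=0.1)

    def test_independent_near_zero(self):
        r = np.random.default_rng(1)
        mi = mi_knn(r.standard_normal(2000), r.standard_normal(2000), k=3)
        assert -0.02 <= mi <= 0.05

    def test_deterministic_dependence_diverges(self):
        r = np.random.default_rng(2)
        x = r.standard_normal(500)
        assert mi_knn(x, x, k=3) > 1.0

    def test_symmetry(self):
        x, y = gaussian_pair(0.7, 1000, seed=3)
        assert mi_knn(x, y) == pytest.approx(mi_knn(y, x), abs=0.05)

    def test_invariance_under_monotone_rescaling(self):
        x, y = gaussian_pair(0.8, 1500, seed=4)
        base = mi_knn(x, y)
        assert mi_knn(np.exp(x), y) == pytest.approx(base, abs=0.1)
        assert mi_knn(3 * x + 7, y) == pytest.approx(base, abs=0.05)

    def test_cross_check_against_sklearn(self):
        """Independent implementation of the same estimator agrees."""
        from sklearn.feature_selection import mutual_info_regression

        x, y = gaussian_pair(0.85, 1500, seed=5)
        ours = mi_knn(x, y, k=3)
        theirs = float(mutual_info_regression(x[:, None], y, n_neighbors=3,
                                              random_state=0)[0])
        assert ours == pytest.approx(theirs, abs=0.1)

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert mi_knn(np.ones(100), np.arange(100.0)) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mi_knn(np.arange(3.0), np.arange(3.0), k=3)


def synthetic_daily(n=365, seed=0, ch4_from_ts=True):
    """Daily driver table; CH4 generated from soil temperature alone."""
    r = np.random.default_rng(seed)
    doy = np.arange(n)
    ts = 13 + 8 * np.cos(2 * np.pi * (doy - 215) / 365) + r.normal(0, 1.0, n)
    ta = ts + r.normal(0, 2.0, n)
    par = np.clip(500 + 400 * np.cos(2 * np.pi * (doy - 172) / 365) + r.normal(0, 120, n), 0, None)
    pa = 101.3 + r.normal(0, 0.4, n)
    wt = 0.15 + r.normal(0, 0.05, n)
    if ch4_from_ts:
        ch4 = 30 * 3.0 ** ((ts - 10) / 10) * r.lognormal(0, 0.15, n)
    else:
        ch4 = r.lognormal(3, 0.5, n)
    return pd.DataFrame({"FCH4": ch4, "PA": pa, "PAR": par, "TA": ta, "TS": ts, "WT": wt})


class TestImportanceProfile:
    def test_generative_recovery_ranks_ts_first(self):
        daily = synthetic_daily(seed=10)
        res = importance_profile(daily, "FCH4", k=3, seed=1)
        assert max(res.importance, key=res.importance.get) == "TS"
        assert res.importance["TS"] > res.importance["PA"]

    def test_importances_sum_to_100(self):
        res = importance_profile(synthetic_daily(seed=11), "FCH4")
        assert sum(res.importance.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in res.importance.values())

    def test_independent_target_flagged_low_signal(self):
        daily = synthetic_daily(seed=12, ch4_from_ts=False)
        res = importance_profile(daily, "FCH4", seed=2)
        assert res.low_signal
        assert all(v < 0.1 for v in res.mi_raw.values())

    def test_duplicated_predictor_shares_importance(self):
        daily = synthetic_daily(seed=13)
        single = importance_profile(daily, "FCH4", predictors=("PA", "PAR", "TA", "TS", "WT"))
        daily["TS2"] = daily["TS"]
        dup = importance_profile(daily, "FCH4",
                                 predictors=("PA", "PAR", "TA", "TS", "TS2", "WT"))
        pair = dup.importance["TS"] + dup.importance["TS2"]
        assert dup.importance["TS"] == pytest.approx(dup.importance["TS2"], rel=0.15)
        # the duplicated pair's combined share exceeds the single copy's share
        assert pair > single.importance["TS"]

    def test_complete_case_filtering_and_min_days(self):
        daily = synthetic_daily(seed=14)
        daily.loc[:350, "WT"] = np.nan
        with pytest.raises(ValueError):
            importance_profile(daily, "FCH4", min_days=30)


class TestTrend:
    def test_exact_line(self):
        res = theil_sen(2.0 * np.arange(10))
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 0.01

    def test_constant_series(self):
        res = theil_sen(np.full(8, 3.0))
        assert res.slope == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_outlier_robustness_vs_brute_force(self):
        r = np.random.default_rng(6)
        t = np.arange(20.0)
        y = -0.44 * t + r.normal(0, 0.05, 20)
        y[7] += 30.0  # gross outlier
        res = theil_sen(y)
        slopes = [(y[j] - y[i]) / (t[j] - t[i]) for i in range(20) for j in range(i + 1, 20)]
        assert res.slope == pytest.approx(np.median(slopes))
        assert abs(res.slope - (-0.44)) / 0.44 < 0.1
        # least squares is dragged off by the outlier
        lsq = np.polyfit(t, y, 1)[0]
        assert abs(lsq - (-0.44)) / 0.44 > 0.1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            theil_sen([1.0, 2.0])

    def test_mann_kendall_no_trend(self):
        r = np.random.default_rng(7)
        s, z, p = mann_kendall(r.standard_normal(40))
        assert p > 0.05


def separated_siteyears(seed=0):
    r = np.random.default_rng(seed)
    rows = []
    for label, (nee, ch4, age) in enumerate(
        [(150.0, 45.0, 2.0), (-300.0, 35.0, 6.0), (-500.0, 20.0, 15.0)]
    ):
        for _ in range(8):
            rows.append({
                "nee_cum": nee + r.normal(0, 10),
                "ch4_cum": ch4 + r.normal(0, 1),
                "wetland_age": age + r.normal(0, 0.2),
                "true": label,
            })
    return pd.DataFrame(rows)


class TestClustering:
    def test_recovery_of_separated_groups(self):
        from sklearn.metrics import adjusted_rand_score

        df = separated_siteyears(seed=8)
        res = cluster_siteyears(df, k=3, seed=0)
        assert adjusted_rand_score(df["true"], res.labels) == 1.0
        # labels aligned by age: youngest group gets label 0
        assert (res.labels[df["true"] == 0] == 0).all()
        assert res.pca_scores.shape == (len(df), 2)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_k1_single_label_centroid_is_mean(self):
        df = separated_siteyears(seed=9)
        res = cluster_siteyears(df, k=1, seed=0)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(
            res.centroids[0],
            df[["nee_cum", "ch4_cum", "wetland_age"]].mean().to_numpy(),
            rtol=1e-6,
        )

    def test_duplicate_rows_share_label(self):
        df = separated_siteyears(seed=10)
        df2 = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        res = cluster_siteyears(df2, k=3, seed=0)
        assert res.labels[0] == res.labels[len(df2) - 1]

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_siteyears(separated_siteyears().head(2), k=3)
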