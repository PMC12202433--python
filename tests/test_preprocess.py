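import numpy as np
import pandas as pd
import pytest

from bifactorlab.preprocess import (
    default_classification,
    em_impute,
    em_mvnorm,
    little_mcar_test,
    partial_credit_scores,
    preprocess_pipeline,
    score_composites,
    winsorize_outliers,
)
from bifactorlab.simulate import simulate_study


def _trials(records):
    rows = []
    for subj, task, ss, vals in records:
        for t, v in enumerate(vals, start=1):
            rows.append(
                {"subject": subj, "task": task, "set_size": ss,
                 "trial": t, "n_correct": v}
            )
    return pd.DataFrame(rows)


class TestPartialCredit:
    @pytest.mark.parametrize(
        "vals,expected",
        [((3, 3, 3, 3, 3, 3), 3.0), ((0, 0, 0, 0, 0, 0), 0.0)],
    )
    def test_boundary_scores(self, vals, expected):
        tr = _trials([(1, "phonological", 3, vals)])
        out = partial_credit_scores(tr)
        assert out.loc[1, "phonological_ss3"] == expected

    def test_mean_of_mixed_trials(self):
        tr = _trials([(1, "visuospatial", 6, (2, 5, 3, 6, 4, 4))])
        out = partial_credit_scores(tr)
        assert out.loc[1, "visuospatial_ss6"] == pytest.approx(4.0)

    def test_incomplete_condition_flagged_missing(self):
        tr = _trials([(1, "phonological", 3, (3, 3, 3, 3, 3))])  # 5 trials
        out = partial_credit_scores(tr)
        assert np.isnan(out.loc[1, "phonological_ss3"])

    def test_out_of_range_rejected(self):
        tr = _trials([(1, "phonological", 3, (4, 3, 3, 3, 3, 3))])
        with pytest.raises(ValueError, match="outside"):
            partial_credit_scores(tr)


class TestWinsorize:
    def _column_with_outlier(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, 200)
        x[0] = 10 + 12 * 2  # 6 population SDs high
        x[1] = 10 - 10 * 2  # 5 low
        return pd.DataFrame({"v": x})

    def test_outliers_replaced_by_next_most_extreme(self):
        df = self._column_with_outlier()
        out, report = winsorize_outliers(df)
        flagged_mask = (df["v"] - df["v"].mean()).abs() > 3 * df["v"].std(ddof=1)
        keep = df.loc[~flagged_mask, "v"]
        assert out.loc[0, "v"] == keep.max()
        assert out.loc[1, "v"] == keep.min()
        assert report.outlier_cells["all"] == int(flagged_mask.sum())

    def test_below_threshold_untouched(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"v": rng.uniform(0, 1, 50)})  # bounded, no outliers
        out, report = winsorize_outliers(df)
        pd.testing.assert_frame_equal(out, df)
        assert report.outlier_cells["all"] == 0

    def test_rank_order_and_range_preserved(self):
        df = self._column_with_outlier()
        out, _ = winsorize_outliers(df)
        assert out["v"].max() <= df["v"].max()
        assert out["v"].min() >= df["v"].min()
        # non-outlier values untouched
        assert (out["v"][2:] == df["v"][2:]).all()

    def test_single_pass_is_idempotent_when_clean(self):
        df = self._column_with_outlier()
        once, _ = winsorize_outliers(df)
        twice, rep2 = winsorize_outliers(once)
        if rep2.outlier_cells["all"] == 0:
            pd.testing.assert_frame_equal(once, twice)

    def test_per_group_screening(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 150)
        b = rng.normal(100, 1, 150)
        b[0] = 106  # outlier within group b, unremarkable pooled
        df = pd.DataFrame({"v": np.concatenate([a, b])})
        groups = ["a"] * 150 + ["b"] * 150
        out, report = winsorize_outliers(df, group_labels=groups)
        assert report.outlier_cells["b"] >= 1
        assert out.loc[150, "v"] != 106


class TestEmImpute:
    def test_complete_data_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        out, info = em_impute(df)
        pd.testing.assert_frame_equal(out, df)
        assert info["imputed_cells"] == 0

    def test_conditional_mean_regression(self):
        # bivariate normal r=.8 with MCAR holes in var2: imputed values
        # regress on var1 with slope ~ r * s2/s1
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        miss = rng.random(n) < 0.2
        df = pd.DataFrame({"x": x, "y": np.where(miss, np.nan, y)})
        out, _ = em_impute(df)
        imp = out.loc[miss]
        slope = np.polyfit(imp["x"], imp["y"], 1)[0]
        assert slope == pytest.approx(0.8, abs=0.03)

    def test_single_missing_cell_equals_ols_prediction(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3)) @ np.array(
            [[1, 0.5, 0.3], [0, 1, 0.4], [0, 0, 1]]
        )
        df = pd.DataFrame(X, columns=list("abc"))
        df.loc[0, "c"] = np.nan
        out, _ = em_impute(df, tol=1e-10)
        comp = df.dropna()
        # ML regression of c on (a, b) from complete rows (EM weights the
        # nearly-complete data the same way)
        Z = np.column_stack([np.ones(len(comp)), comp[["a", "b"]]])
        beta = np.linalg.lstsq(Z, comp["c"], rcond=None)[0]
        pred = beta[0] + beta[1] * df.loc[0, "a"] + beta[2] * df.loc[0, "b"]
        assert out.loc[0, "c"] == pytest.approx(pred, abs=5e-3)

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 4))
        mask = rng.random((100, 4)) < 0.1
        Xm = np.where(mask, np.nan, X)
        out, _ = em_impute(Xm)
        assert np.array_equal(out[~mask], Xm[~mask])

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        X = rng.multivariate_normal(
            [0, 0, 0], [[1, 0.6, 0.3], [0.6, 1, 0.5], [0.3, 0.5, 1]], 400
        )
        X[rng.random(X.shape) < 0.15] = np.nan
        _, _, _, trace = em_mvnorm(X)
        diffs = np.diff(trace)
        assert (diffs > -1e-8).all()


class TestLittleMcar:
    def test_complete_data_degenerate(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        with pytest.warns(UserWarning, match="undefined"):
            chi2, df, p = little_mcar_test(X)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_type_one_error_under_mcar(self):
        # rejection rate at alpha=.05 stays within binomial error of .05
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 200
        for _ in range(reps):
            X = rng.multivariate_normal(
                [0, 0, 0], [[1, 0.4, 0.2], [0.4, 1, 0.3], [0.2, 0.3, 1]], 500
            )
            X[rng.random(X.shape) < 0.10] = np.nan
            _, _, p = little_mcar_test(X)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10  # ~.05 +/- 3 binomial Sds

    def test_power_under_mar(self):
        # missingness in var2 driven by var1 -> pattern means differ
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 60
        for _ in range(reps):
            x = rng.standard_normal(800)
            y = 0.5 * x + rng.standard_normal(800)
            miss = x > 0.5  # strongly MAR
            Y = np.column_stack([x, np.where(miss, np.nan, y)])
            _, _, p = little_mcar_test(Y)
            rejections += p < 0.05
        assert rejections / reps > 0.5


class TestScoreComposites:
    def _items(self, fill):
        cols = [f"item{i:02d}" for i in range(1, 41)]
        return pd.DataFrame([[fill] * 40], columns=cols)

    def test_composite_extremes(self):
        hi = score_composites(self._items(3))
        lo = score_composites(self._items(0))
        assert hi.loc[0, "neither_composite"] == 51
        assert lo.loc[0, "neither_composite"] == 0
        assert hi.shape[1] == 23

    def test_wrong_classification_counts_rejected(self):
        cls = default_classification()
        cls["item02"] = "cognitive_worry"  # 12/11/16
        with pytest.raises(ValueError, match="11/11/17"):
            score_composites(self._items(1), cls)

    def test_missing_constituent_flags_composite(self):
        items = self._items(2)
        items.loc[0, "item02"] = np.nan  # a "neither" item
        out = score_composites(items)
        assert np.isnan(out.loc[0, "neither_composite"])

    def test_both_items_dropped(self):
        out = score_composites(self._items(1))
        assert "item40" not in out.columns


def test_pipeline_end_to_end_counts():
    ds = simulate_study(200, seed=10, missing_rate=0.004, outlier_count=3)
    cov = ds.indicators[["age", "sex", "ses"]]
    ind, report = preprocess_pipeline(
        ds.anxiety_items, ds.wm_trials, cov, ds.indicators["group"]
    )
    assert ind.shape == (200, 35)
    assert not ind.drop(columns="group").isna().any().any()
    assert report.missing_cells > 0
    assert 0 < report.mcar_p <= 1
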