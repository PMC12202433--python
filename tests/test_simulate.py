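import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bifactorlab.preprocess import partial_credit_scores, winsorize_outliers
from bifactorlab.simulate import (
    DEFAULT_GROUP_MEANS,
    aggregate_reference_loading,
    anxiety_population,
    build_population_model,
    discretize_to_likert,
    emit_wm_trials,
    inject_missing_and_outliers,
    joint_population,
    simulate_covariates,
    simulate_latents_and_indicators,
    simulate_study,
    wm_population,
)
from bifactorlab.specs import NEITHER_COMPOSITE, anxiety_spec, wm_spec


class TestPopulationModel:
    def test_wm_residual_variances(self, wm_pop):
        # non-reference: 1 - .36 - .16 = .48; reference: 1 - .36 = .64
        st = wm_pop.structure
        resid = dict(zip(st.indicators, wm_pop.residual_variances))
        assert resid["phonological_ss4"] == pytest.approx(0.48)
        assert resid["phonological_ss3"] == pytest.approx(0.64)

    def test_anxiety_item_residuals(self, anx_pop):
        st = anx_pop.structure
        resid = dict(zip(st.indicators, anx_pop.residual_variances))
        assert resid["item03"] == pytest.approx(1 - 0.36 - 0.09)

    def test_composite_reference_loading_is_aggregate_implied(self, anx_pop):
        st = anx_pop.structure
        i = st.indicators.index(NEITHER_COMPOSITE)
        g = st.factor_index("common_anxiety")
        expected = 17 * 0.6 / np.sqrt(17 + 17 * 16 * 0.36)
        assert anx_pop.loadings[i, g] == pytest.approx(expected)
        assert aggregate_reference_loading(0.6) == pytest.approx(expected)

    def test_heywood_population_rejected(self):
        with pytest.raises(ValueError, match="communality"):
            build_population_model(
                wm_spec(), lambda_general=0.9, lambda_specific=0.5
            )

    def test_within_construct_correlation_rejected(self):
        with pytest.raises(ValueError, match="fixed at 0"):
            build_population_model(
                wm_spec(),
                factor_corr={("central_executive", "phonological_stm"): 0.3},
            )

    def test_implied_correlation_rule(self, wm_pop):
        # rho_ij = lg_i lg_j + ls_i ls_j [same specific]
        st = wm_pop.structure
        sig = wm_pop.implied_corr()
        i = st.indicators.index("phonological_ss4")
        j = st.indicators.index("phonological_ss5")
        k = st.indicators.index("visuospatial_ss4")
        assert sig[i, j] == pytest.approx(0.36 + 0.16)
        assert sig[i, k] == pytest.approx(0.36)


class TestSimulateIndicators:
    def test_sample_moments_converge(self, big_wm_sample):
        ds = big_wm_sample
        st = ds.population.structure
        S = np.corrcoef(ds.indicators[list(st.indicators)].to_numpy(), rowvar=False)
        assert np.abs(S - ds.population.implied_corr()).max() < 0.01

    def test_latent_correlations_converge(self, big_wm_sample):
        eta = big_wm_sample.latents.to_numpy()
        C = np.corrcoef(eta, rowvar=False)
        assert np.abs(C - np.eye(3)).max() < 0.015

    def test_centered_means(self, big_wm_sample):
        m = big_wm_sample.indicators.select_dtypes("number").mean()
        assert m.abs().max() < 0.02

    def test_seed_determinism(self, wm_pop):
        a = simulate_latents_and_indicators(wm_pop, 200, seed=5)
        b = simulate_latents_and_indicators(wm_pop, 200, seed=5)
        pd.testing.assert_frame_equal(a.indicators, b.indicators)
        pd.testing.assert_frame_equal(a.latents, b.latents)

    def test_group_mean_offsets(self):
        pop = wm_population(group_latent_means=DEFAULT_GROUP_MEANS)
        ds = simulate_latents_and_indicators(
            pop, 60_000, seed=3, group_mix={"adhd": 0.5, "non_adhd": 0.5}
        )
        lat = ds.latents.join(ds.indicators["group"])
        diff = (
            lat[lat.group == "non_adhd"]["central_executive"].mean()
            - lat[lat.group == "adhd"]["central_executive"].mean()
        )
        assert diff == pytest.approx(1.0, abs=0.05)

    def test_cross_construct_correlation(self):
        pop = joint_population(r_general=0.30)
        ds = simulate_latents_and_indicators(pop, 100_000, seed=9)
        r = np.corrcoef(
            ds.latents["central_executive"], ds.latents["common_anxiety"]
        )[0, 1]
        assert r == pytest.approx(0.30, abs=0.01)


class TestLikert:
    def test_direct_binning(self):
        out = discretize_to_likert(np.array([[0.0]]), (-0.5, 0.5, 1.5))
        assert out[0, 0] == 1

    def test_degenerate_thresholds(self):
        out = discretize_to_likert(
            np.random.default_rng(0).standard_normal((100, 1)), (50.0, 60.0, 70.0)
        )
        assert (out == 0).all()

    def test_monotone_thresholds_required(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize_to_likert(np.zeros((2, 1)), (0.5, 0.5, 1.5))

    def test_category_frequencies_match_normal_areas(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((200_000, 1))
        out = discretize_to_likert(x, (-1.0, 0.0, 1.0))
        freq = np.bincount(out.ravel(), minlength=4) / out.size
        expected = np.diff([0, *stats.norm.cdf([-1, 0, 1]), 1])
        assert np.abs(freq - expected).max() < 0.005


class TestWmTrials:
    def test_ceiling_case(self):
        scores = pd.DataFrame({"phonological_ss3": [3.0]})
        trials = emit_wm_trials(scores)
        assert (trials["n_correct"] == 3).all() and len(trials) == 6

    def test_exact_grid_point(self):
        scores = pd.DataFrame({"phonological_ss3": [2.0]})
        trials = emit_wm_trials(scores)
        assert trials["n_correct"].sum() == 12

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            emit_wm_trials(pd.DataFrame({"phonological_ss3": [3.5]}))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_on_grid(self, seed):
        # rescoring emitted trials recovers the target within half a grid
        # step (1/12), and exactly for targets on the 1/6 grid
        rng = np.random.default_rng(seed)
        cols = list(wm_spec().indicators)
        scores = pd.DataFrame(
            {c: rng.uniform(0, int(c[-1]), 30) for c in cols}
        )
        trials = emit_wm_trials(scores, seed=seed)
        trials["subject"] = trials["subject"].astype(int)
        back = partial_credit_scores(trials)
        err = (back[cols] - scores[cols]).abs().to_numpy()
        assert err.max() <= 1 / 12 + 1e-12


class TestInjectMissingOutliers:
    def _table(self, n=340):
        pop = wm_population()
        ds = simulate_latents_and_indicators(
            pop, n, seed=11, group_mix={"adhd": 0.6, "non_adhd": 0.4}
        )
        return ds.indicators

    def test_zero_rate_identity(self):
        df = self._table()
        out, changes = inject_missing_and_outliers(df, 0.0, 0, seed=1)
        pd.testing.assert_frame_equal(out, df)
        assert not changes["missing"] and not changes["outliers"]

    def test_missing_count_near_expectation(self):
        df = self._table()
        out, changes = inject_missing_and_outliers(df, 0.002, 0, seed=2)
        n_cells = 340 * 8
        k = len(changes["missing"])
        # binomial(2720, .002): mean ~5.4
        assert stats.binom.pmf(k, n_cells, 0.002) > 1e-6
        assert out.isna().sum().sum() == k

    def test_outliers_flagged_by_winsorization(self):
        df = self._table()
        out, changes = inject_missing_and_outliers(df, 0.0, 5, seed=3)
        cleaned, report = winsorize_outliers(
            out.drop(columns="group"), group_labels=out["group"]
        )
        flagged = sum(report.outlier_cells.values())
        assert flagged >= 5  # all injected cells found (plus any natural ones)
        for idx, col, val in changes["outliers"]:
            assert cleaned.loc[idx, col] != val

    def test_too_many_outliers_rejected(self):
        df = self._table(20)
        with pytest.raises(ValueError, match="exceeds"):
            inject_missing_and_outliers(df, 0.0, 10_000, seed=1)


def test_covariate_distributions():
    rng = np.random.default_rng(0)
    cov = simulate_covariates(50_000, rng)
    assert cov["age"].between(8.1, 13.5).all()
    assert set(cov["sex"].unique()) <= {0.0, 1.0}
    assert cov["ses"].between(11, 66).all()
    # truncation to [11, 66] pulls the N(47, 11) mean down slightly
    a, b = (11 - 47) / 11, (66 - 47) / 11
    expected = stats.truncnorm.mean(a, b, loc=47, scale=11)
    assert cov["ses"].mean() == pytest.approx(expected, abs=0.2)


class TestSimulateStudy:
    def test_shapes_and_ranges(self):
        ds = simulate_study(120, seed=1)
        assert ds.anxiety_items.shape == (120, 40)
        vals = ds.anxiety_items.to_numpy()
        obs = vals[~np.isnan(vals)]
        assert set(np.unique(obs)) <= {0, 1, 2, 3}
        # six trials per subject x task x set size
        counts = ds.wm_trials.groupby(["subject", "task", "set_size"]).size()
        assert (counts == 6).all()
        assert len(counts) == 120 * 8

    def test_determinism(self):
        a = simulate_study(80, seed=4)
        b = simulate_study(80, seed=4)
        pd.testing.assert_frame_equal(a.anxiety_items, b.anxiety_items)
        pd.testing.assert_frame_equal(a.wm_trials, b.wm_trials)
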