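import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bifactorlab.engine import fit_baseline, fit_ml, moments_group_data
from bifactorlab.indices import (
    cohens_d,
    construct_h,
    delta_chi2,
    ecv,
    fit_indices,
    omega_indices,
    puc,
    relative_fit,
    reliability_report,
)
from bifactorlab.indices import _rmsea_ci
from bifactorlab.specs import BifactorSpec, anxiety_spec, wm_spec
from bifactorlab.simulate import wm_population


class TestRelativeFit:
    def test_hand_arithmetic(self):
        # chi2_m=100, df_m=50, chi2_b=1000, df_b=60, N=340
        out = relative_fit(100, 50, 1000, 60, 340)
        assert out["cfi"] == pytest.approx(1 - 50 / 940, abs=1e-9)
        rb = 1000 / 60
        assert out["tli"] == pytest.approx((rb - 2) / (rb - 1), abs=1e-9)
        assert out["rmsea"] == pytest.approx(np.sqrt(50 / (50 * 340)), abs=1e-9)

    def test_exact_average_fit_gives_zero_rmsea(self):
        out = relative_fit(50, 50, 500, 60, 300)
        assert out["rmsea"] == 0.0
        assert out["cfi"] == 1.0

    def test_rmsea_ci_inverts_noncentral_cdf(self):
        lo, hi = _rmsea_ci(100, 50, 340, 1)
        lam_lo = lo**2 * 50 * 340
        lam_hi = hi**2 * 50 * 340
        assert stats.ncx2.cdf(100, 50, lam_lo) == pytest.approx(0.95, abs=1e-6)
        assert stats.ncx2.cdf(100, 50, lam_hi) == pytest.approx(0.05, abs=1e-6)

    def test_perfect_fit_indices(self, wm_pop):
        gd = moments_group_data(wm_pop.implied_corr(), 400, wm_pop.structure)
        model = fit_ml(gd, wm_spec())
        base = fit_baseline(gd, wm_spec())
        idx = fit_indices(model, base)
        assert idx.cfi == pytest.approx(1.0)
        assert idx.srmr == pytest.approx(0.0, abs=1e-6)
        assert idx.rmsea == 0.0

    def test_mismatched_baseline_rejected(self, wm_sample, anx_sample):
        model = fit_ml(wm_sample, wm_spec())
        base = fit_baseline(anx_sample, anxiety_spec())
        with pytest.raises(ValueError, match="different data"):
            fit_indices(model, base)


class TestDeltaChi2:
    def test_identical_models(self, wm_sample):
        fit = fit_ml(wm_sample, wm_spec())
        d, ddf, p = delta_chi2(fit, fit)
        assert (d, ddf, p) == (0.0, 0, 1.0)

    def test_null_calibration(self, wm_pop):
        # data from the 1-factor population: bifactor-vs-1-factor LR test
        # rejects at ~alpha
        from bifactorlab.simulate import build_population_model, simulate_latents_and_indicators

        onef_pop = build_population_model(wm_spec().one_factor())
        rejections = 0
        reps = 150
        ss = np.random.SeedSequence(99)
        seeds = ss.generate_state(reps) % (2**31)
        cols = list(wm_spec().indicators)
        for r in range(reps):
            ds = simulate_latents_and_indicators(onef_pop, 340, int(seeds[r]))
            data = ds.indicators[cols]
            # under the null the specific factors vanish, so the bifactor
            # optimum sits near an identification boundary; the global
            # quasi-Newton path is the reliable way to reach it
            bif = fit_ml(data, wm_spec(), compute_se=False, method="lbfgs")
            one = fit_ml(
                data, wm_spec().one_factor(), compute_se=False, method="lbfgs"
            )
            d, ddf, p = delta_chi2(one, bif)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.11

    def test_power_against_bifactor_population(self, wm_sample):
        bif = fit_ml(wm_sample, wm_spec(), compute_se=False)
        one = fit_ml(wm_sample, wm_spec().one_factor(), compute_se=False)
        d, ddf, p = delta_chi2(one, bif)
        assert ddf == 6
        assert p < 1e-6


class TestOmega:
    def test_general_only_example(self):
        spec = BifactorSpec("t", ("a", "b", "c"), "g", {})
        lam = np.full((3, 1), 0.6)
        th = np.full(3, 0.64)
        out = omega_indices(spec, lam, th)
        assert out["omega_total"] == pytest.approx(3.24 / 5.16, abs=1e-9)
        assert out["omega_h"] == out["omega_total"]

    def test_subscale_example(self):
        # 3-item specific with lambda_s=.4, lambda_g=.6, theta=.48, plus a
        # general-only reference to make the spec valid
        spec = BifactorSpec("t", ("a", "b", "c", "r"), "g", {"s": ("a", "b", "c")})
        lam = np.array(
            [[0.6, 0.4], [0.6, 0.4], [0.6, 0.4], [0.6, 0.0]]
        )
        th = 1 - (lam**2).sum(1)
        out = omega_indices(spec, lam, th)
        assert out["omega_s"]["s"] == pytest.approx(4.68 / 6.12, abs=1e-9)
        assert out["omega_hs"]["s"] == pytest.approx(1.44 / 6.12, abs=1e-9)

    def test_zero_loadings(self):
        spec = BifactorSpec("t", ("a", "b"), "g", {})
        out = omega_indices(spec, np.zeros((2, 1)), np.ones(2))
        assert out["omega_total"] == 0.0

    def test_non_standardized_rejected(self):
        spec = BifactorSpec("t", ("a", "b"), "g", {})
        with pytest.raises(ValueError, match="standardized"):
            omega_indices(spec, np.full((2, 1), 0.6), np.full(2, 0.9))

    @given(
        lg=st.floats(0.1, 0.8),
        ls=st.floats(0.05, 0.5),
    )
    @settings(max_examples=30, deadline=None)
    def test_hierarchy_inequalities(self, lg, ls):
        if lg**2 + ls**2 >= 0.95:
            return
        spec = BifactorSpec(
            "t", ("a", "b", "c", "d", "r"), "g",
            {"s1": ("a", "b"), "s2": ("c", "d")},
        )
        lam = np.zeros((5, 3))
        lam[:, 0] = lg
        lam[[0, 1], 1] = ls
        lam[[2, 3], 2] = ls
        th = 1 - (lam**2).sum(1)
        out = omega_indices(spec, lam, th)
        assert out["omega_h"] <= out["omega_total"] + 1e-12
        for s in ("s1", "s2"):
            assert out["omega_hs"][s] <= out["omega_s"][s] + 1e-12


class TestEcv:
    def test_general_only(self):
        spec = BifactorSpec("t", ("a", "b"), "g", {})
        out = ecv(spec, np.full((2, 1), 0.5))
        assert out["g"] == 1.0

    def test_wm_default_population_value(self, wm_pop):
        # 8 x .36 = 2.88 general; 6 x .16 = .96 specific -> ECV_g = .75
        out = ecv(wm_spec(), wm_pop.loadings)
        assert out["central_executive"] == pytest.approx(0.75)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_normalization(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(-0.7, 0.7, size=(8, 3))
        st_ = wm_spec().structure()
        lam = np.where(st_.loading_free, lam, 0.0)
        if (lam**2).sum() == 0:
            return
        out = ecv(wm_spec(), lam)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ecv(wm_spec(), np.zeros((8, 3)))


class TestPuc:
    def test_anxiety_structural_value(self):
        # (253 - 110) / 253 = .565..., printed as .57
        val = puc(anxiety_spec())
        assert val == pytest.approx(143 / 253, abs=1e-12)
        assert round(val, 2) == 0.57

    def test_wm_structural_value(self):
        assert puc(wm_spec()) == pytest.approx(22 / 28, abs=1e-12)

    def test_single_specific_covering_everything(self):
        spec = BifactorSpec(
            "t", ("a", "b", "c", "r"), "g", {"s": ("a", "b", "c")}
        )
        # 6 pairs, 3 within the specific, the reference contributes 3 clean
        assert puc(spec) == pytest.approx(0.5)

    def test_reference_indicator_strictly_increases_puc(self):
        base = BifactorSpec(
            "t", ("a", "b", "c", "r"), "g", {"s": ("a", "b", "c")}
        )
        wider = BifactorSpec(
            "t", ("a", "b", "c", "r", "r2"), "g", {"s": ("a", "b", "c")}
        )
        assert puc(wider) > puc(base)

    def test_too_few_indicators(self):
        with pytest.raises(ValueError):
            puc(BifactorSpec("t", ("a",), "g", {}))


class TestConstructH:
    def test_single_loading(self):
        assert construct_h([0.6]) == pytest.approx(0.36)

    def test_eight_equal_loadings(self):
        assert construct_h([0.6] * 8) == pytest.approx(4.5 / 5.5)

    def test_limit_toward_one(self):
        assert construct_h([0.999]) > 0.99

    def test_unit_loading_rejected(self):
        with pytest.raises(ValueError):
            construct_h([1.0])


class TestCohensD:
    def test_age_from_group_descriptives(self):
        # ADHD 10.12 (1.39, n=197) vs non-ADHD 10.57 (1.34, n=143)
        assert round(cohens_d(10.12, 1.39, 197, 10.57, 1.34, 143), 2) == 0.33

    def test_attention_ratings_from_group_descriptives(self):
        # parent-rated attention problems: 68.58 (6.97) vs 56.71 (10.83)
        assert round(cohens_d(68.58, 6.97, 197, 56.71, 10.83, 143), 2) == -1.35


def test_reliability_report_shape(wm_sample):
    fit = fit_ml(wm_sample, wm_spec())
    rep = reliability_report(fit)
    assert set(rep) == {"omega", "ecv", "puc", "H"}
    assert rep["puc"] == pytest.approx(22 / 28)
    assert sum(rep["ecv"].values()) == pytest.approx(1.0, abs=1e-9)
    assert 0 < rep["omega"]["omega_total"] <= 1
    assert set(rep["H"]) == set(wm_spec().factor_names)
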