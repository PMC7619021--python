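"""Screening, preselection, the mixed model and AIC stepwise removal."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.regression.mixed_linear_model import MixedLM

from ringclim import synthetic_data as sd
from ringclim.age_detrend import SPECIES_AGE_PARAMS, detrend
from ringclim.sensitivity import (WATER_FACTORS, correlation_screen,
                                  fit_lme, fit_random_intercept, preselect,
                                  r2_decomposition, stepwise_aic)

BEECH = SPECIES_AGE_PARAMS["Fagus sylvatica"]


def _simulate_lmm(seed, g=10, per=50, p=3, beta=None, sigma_b=0.3,
                  sigma_e=0.5):
    rng = np.random.default_rng(seed)
    n = g * per
    groups = np.repeat([f"s{i}" for i in range(g)], per)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    beta = np.zeros(p + 1) if beta is None else np.asarray(beta)
    y = (X @ beta + rng.normal(0, sigma_b, g)[np.arange(g).repeat(per)]
         + rng.normal(0, sigma_e, n))
    return X, y, groups


class TestRandomInterceptFitter:
    """The profiled fitter against the reference mixed-model code."""

    @pytest.mark.parametrize("method", ["ml", "reml"])
    def test_matches_statsmodels(self, method):
        X, y, groups = _simulate_lmm(3, beta=[0.5, 0.2, -0.3, 0.1])
        fit = fit_random_intercept(X, y, groups, method=method)
        ref = MixedLM(y, X, groups).fit(reml=(method == "reml"))
        np.testing.assert_allclose(fit.params, ref.fe_params, atol=1e-5)
        np.testing.assert_allclose(fit.bse, ref.bse_fe, atol=1e-4)
        assert fit.sigma_e == pytest.approx(float(np.sqrt(ref.scale)),
                                            abs=1e-4)
        assert fit.sigma_b == pytest.approx(
            float(np.sqrt(np.asarray(ref.cov_re)[0, 0])), abs=1e-3)
        if method == "ml":
            assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_zero_group_variance_detected(self):
        X, y, groups = _simulate_lmm(5, sigma_b=0.0)
        fit = fit_random_intercept(X, y, groups)
        assert fit.sigma_b < 0.05

    def test_single_group_falls_back_to_ols(self):
        X, y, _ = _simulate_lmm(6, g=1, per=200)
        fit = fit_random_intercept(X, y, np.repeat("only", 200))
        assert fit.sigma_b == 0.0

    def test_type_one_error_near_nominal(self):
        # null fixed effects: per-term Wald rejection at 5% should be
        # close to nominal
        rejections = []
        for rep in range(150):
            X, y, groups = _simulate_lmm(900 + rep, g=8, per=25, p=3)
            fit = fit_random_intercept(X, y, groups, method="reml")
            rejections.extend(fit.pvalues()[1:] < 0.05)
        rate = np.mean(rejections)
        assert 0.02 < rate < 0.09

    def test_permutation_invariance(self):
        X, y, groups = _simulate_lmm(8, beta=[0.5, 0.2, -0.3, 0.1])
        fit = fit_random_intercept(X, y, groups)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit_p = fit_random_intercept(X[perm], y[perm], groups[perm])
        np.testing.assert_allclose(fit.params, fit_p.params, atol=1e-8)
        assert fit.loglik == pytest.approx(fit_p.loglik, abs=1e-8)


@pytest.fixture(scope="module")
def screened(small_study):
    """Rings with known effects + screen results on the small study."""
    _, hist_long, hist_wide, _ = small_study
    key = ("mean_soil_moisture", "Jun-Jul", "act")
    truth = sd.RingGenTruth(
        age_params=BEECH,
        beta={key: 0.12, ("mean_temp", "Jun-Jul", "act"): -0.12},
        site_intercept_sd=0.1, residual_sd=0.2,
        n_sites=4, trees_per_site=7, seed=77)
    rings = sd.generate_ring_series(truth, hist_long)
    resid = detrend(rings, BEECH)
    corr = correlation_screen(resid, hist_long)
    return truth, resid, corr, hist_long, hist_wide


class TestCorrelationScreen:
    def test_covers_all_legal_cells(self, screened):
        _, _, corr, _, _ = screened
        assert len(corr) == 7 * 14

    def test_planted_water_effect_ranks_first_in_its_season(self, screened):
        _, _, corr, _, _ = screened
        cell = corr[(corr.season == "Jun-Jul") & (corr.lag == "act")
                    & corr.factor.isin(WATER_FACTORS)]
        best = cell.loc[cell["r"].abs().idxmax(), "factor"]
        assert best == "mean_soil_moisture"

    def test_duplicated_factor_gets_identical_r(self, screened):
        _, resid, corr, hist_long, _ = screened
        dup = hist_long[hist_long.factor == "mean_temp"].copy()
        dup["factor"] = "mean_temp_copy"
        corr2 = correlation_screen(resid,
                                   pd.concat([hist_long, dup],
                                             ignore_index=True))
        a = corr2[corr2.factor == "mean_temp"].set_index(
            ["season", "lag"])["r"]
        b = corr2[corr2.factor == "mean_temp_copy"].set_index(
            ["season", "lag"])["r"]
        np.testing.assert_allclose(a, b.loc[a.index], atol=1e-12)

    def test_noise_response_within_permutation_envelope(self, small_study):
        _, hist_long, _, _ = small_study
        truth = sd.RingGenTruth(age_params=BEECH, beta={},
                                site_intercept_sd=0.0, residual_sd=0.25,
                                n_sites=4, trees_per_site=7, seed=55)
        rings = sd.generate_ring_series(truth, hist_long)
        resid = detrend(rings, BEECH)
        corr = correlation_screen(resid, hist_long)
        observed_max = corr["r"].abs().max()
        # permutation null envelope for the max |r| across cells
        rng = np.random.default_rng(1)
        site_year = resid.groupby(["site_id", "year"],
                                  as_index=False)["w_res"].mean()
        maxima = []
        for _ in range(100):
            shuffled = site_year.copy()
            shuffled["w_res"] = rng.permutation(
                shuffled["w_res"].to_numpy())
            c = correlation_screen(shuffled, hist_long)
            maxima.append(c["r"].abs().max())
        assert observed_max <= np.quantile(maxima, 0.99) * 1.25


class TestPreselect:
    def test_at_most_28_candidates_two_per_key(self, screened):
        _, _, corr, _, _ = screened
        cands = preselect(corr)
        assert len(cands) <= 28
        per_key = {}
        for f, s, l in cands:
            per_key.setdefault((s, l), []).append(f)
        for key, fs in per_key.items():
            water = [f for f in fs if f in WATER_FACTORS]
            assert len(water) <= 1
            assert "mean_temp" in fs

    def test_ties_broken_by_canonical_factor_order(self, screened):
        _, _, corr, _, _ = screened
        tied = corr.copy()
        tied["r"] = 0.3  # every water factor ties
        cands = preselect(tied)
        water = {(s, l): f for f, s, l in cands if f in WATER_FACTORS}
        assert all(f == WATER_FACTORS[0] for f in water.values())

    def test_highest_abs_correlation_wins(self, screened):
        _, _, corr, _, _ = screened
        cands = preselect(corr)
        assert ("mean_soil_moisture", "Jun-Jul", "act") in cands


class TestFitAndStepwise:
    def test_recovers_planted_effects(self, screened):
        truth, resid, corr, _, hist_wide = screened
        cands = preselect(corr)
        model, _ = fit_lme(resid, hist_wide, cands, species="test")
        for key, b in truth.beta.items():
            assert key in model.estimates
            assert model.estimates[key] == pytest.approx(b, abs=0.04)

    def test_stepwise_keeps_true_terms_and_lowers_aic(self, screened):
        truth, resid, corr, _, hist_wide = screened
        cands = preselect(corr)
        full, _ = fit_lme(resid, hist_wide, cands, species="test")
        reduced = stepwise_aic(resid, hist_wide, cands, species="test")
        assert reduced.aic <= full.aic + 1e-9
        for key in truth.beta:
            assert key in reduced.retained_terms

    def test_stepwise_deterministic(self, screened):
        _, resid, corr, _, hist_wide = screened
        cands = preselect(corr)
        a = stepwise_aic(resid, hist_wide, cands)
        b = stepwise_aic(resid, hist_wide, cands)
        assert a.retained_terms == b.retained_terms
        assert a.estimates == b.estimates

    def test_row_permutation_invariance(self, screened):
        _, resid, corr, _, hist_wide = screened
        cands = preselect(corr)
        a = stepwise_aic(resid, hist_wide, cands)
        shuffled = resid.sample(frac=1.0,
                                random_state=9).reset_index(drop=True)
        b = stepwise_aic(shuffled, hist_wide, cands)
        assert a.retained_terms == b.retained_terms
        for k in a.estimates:
            assert a.estimates[k] == pytest.approx(b.estimates[k],
                                                   abs=1e-8)

    def test_site_variance_near_zero_when_absent(self, small_study):
        _, hist_long, hist_wide, _ = small_study
        truth = sd.RingGenTruth(age_params=BEECH, beta={},
                                site_intercept_sd=0.0, residual_sd=0.2,
                                n_sites=4, trees_per_site=7, seed=31)
        rings = sd.generate_ring_series(truth, hist_long)
        resid = detrend(rings, BEECH)
        model, _ = fit_lme(resid, hist_wide,
                           [("mean_temp", "Jun-Jul", "act")])
        assert model.site_intercept_sd < 0.05


class TestR2Decomposition:
    def test_zero_random_variance_equalises_r2(self, small_study):
        _, hist_long, hist_wide, _ = small_study
        truth = sd.RingGenTruth(
            age_params=BEECH,
            beta={("mean_temp", "Jun-Jul", "act"): 0.15},
            site_intercept_sd=0.0, residual_sd=0.2,
            n_sites=4, trees_per_site=7, seed=41)
        rings = sd.generate_ring_series(truth, hist_long)
        resid = detrend(rings, BEECH)
        model, _ = fit_lme(resid, hist_wide,
                           [("mean_temp", "Jun-Jul", "act")])
        marg, cond = r2_decomposition(model)
        assert cond == pytest.approx(marg, abs=0.03)

    def test_known_variance_components_recovered(self, small_study):
        # marginal ~ var_fixed/total with planted sizes
        _, hist_long, hist_wide, _ = small_study
        beta, sb, se_ = 0.2, 0.15, 0.25
        truth = sd.RingGenTruth(
            age_params=BEECH,
            beta={("mean_temp", "Jun-Jul", "act"): beta},
            site_intercept_sd=sb, residual_sd=se_,
            n_sites=4, trees_per_site=7, seed=43)
        rings = sd.generate_ring_series(truth, hist_long)
        resid = detrend(rings, BEECH)
        model, _ = fit_lme(resid, hist_wide,
                           [("mean_temp", "Jun-Jul", "act")])
        total = beta ** 2 + sb ** 2 + se_ ** 2
        assert model.marginal_r2 == pytest.approx(beta ** 2 / total,
                                                  abs=0.05)

    def test_single_site_conditional_missing(self, small_study):
        _, hist_long, hist_wide, _ = small_study
        truth = sd.RingGenTruth(age_params=BEECH, beta={},
                                site_intercept_sd=0.0, residual_sd=0.2,
                                n_sites=1, trees_per_site=7, seed=47)
        rings = sd.generate_ring_series(truth, hist_long)
        resid = detrend(rings, BEECH)
        model, _ = fit_lme(resid, hist_wide,
                           [("mean_temp", "Jun-Jul", "act")])
        assert model.single_site_ols
        assert model.conditional_r2 is None
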