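"""Gamma-GLM fitting, likelihood-ratio comparison and single-step contrasts."""

import numpy as np
import pytest

from scatniche.glm import (
    GLMDesign,
    GLMError,
    build_design,
    fit_gamma_glm,
    hormone_vs_ndvi_lm,
    likelihood_ratio_test,
    model_comparison,
    pairwise_contrasts,
)
from scatniche.samples import FaecalSample


def cell_design(n_per_cell, coefs, rng, shape=5.0, year0=2017.5):
    """Balanced Area x Year layout with centred-year coding; returns X, y, names."""
    rows, y = [], []
    for area in (0.0, 1.0):
        for year in (2015.0, 2020.0):
            yc = year - year0
            eta = coefs[0] + coefs[1] * area + coefs[2] * yc + coefs[3] * area * yc
            mu = np.exp(eta)
            y.extend(rng.gamma(shape, mu / shape, size=n_per_cell))
            rows.extend([[1.0, area, yc, area * yc]] * n_per_cell)
    names = ("(Intercept)", "AreaWest", "Year", "AreaWest:Year")
    return GLMDesign(np.asarray(rows), names), np.asarray(y)


TRUE_COEFS = np.array([8.4, -0.3, -0.06, 0.18])  # published sign pattern


class TestGammaGlmFit:
    def test_intercept_only_fits_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(4.0, 2.0, size=50)
        design = GLMDesign(np.ones((50, 1)), ("(Intercept)",))
        fit = fit_gamma_glm(design, y)
        assert fit.converged
        assert np.exp(fit.coefficients[0]) == pytest.approx(y.mean(), rel=1e-10)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(2024)
        design, y = cell_design(500, TRUE_COEFS, rng)
        fit = fit_gamma_glm(design, y)
        assert fit.converged
        assert np.all(np.abs(fit.coefficients - TRUE_COEFS) < 3 * fit.se)

    def test_replicate_averaged_bias_below_five_percent(self):
        rng = np.random.default_rng(7)
        reps = 150
        est = np.zeros((reps, 4))
        for r in range(reps):
            design, y = cell_design(500, TRUE_COEFS, rng)
            est[r] = fit_gamma_glm(design, y).coefficients
        bias = est.mean(axis=0) - TRUE_COEFS
        assert np.all(np.abs(bias / TRUE_COEFS) < 0.05)

    def test_matches_statsmodels_reference_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        design, y = cell_design(60, TRUE_COEFS, rng)
        fit = fit_gamma_glm(design, y)
        ref = sm.GLM(
            y, design.matrix, family=sm.families.Gamma(sm.families.links.Log())
        ).fit(scale="X2")
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, rel=1e-6)
        assert fit.dispersion == pytest.approx(ref.scale, rel=1e-6)

    def test_low_noise_limit_approaches_log_scale_ols(self):
        rng = np.random.default_rng(11)
        design, y = cell_design(50, TRUE_COEFS, rng, shape=1e6)
        fit = fit_gamma_glm(design, y)
        X = design.matrix
        beta_ols = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta_ols, atol=1e-3)

    def test_irls_fixed_point_satisfies_normal_equations(self):
        rng = np.random.default_rng(3)
        design, y = cell_design(40, TRUE_COEFS, rng)
        fit = fit_gamma_glm(design, y)
        mu = fit.fitted_values
        score = design.matrix.T @ ((y - mu) / mu)
        assert np.linalg.norm(score) < 1e-6 * np.linalg.norm(y)

    def test_nonpositive_response_rejected(self):
        design = GLMDesign(np.ones((5, 1)), ("(Intercept)",))
        with pytest.raises(GLMError):
            fit_gamma_glm(design, np.array([1.0, 2.0, 0.0, 1.0, 1.0]))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(GLMError):
            GLMDesign(X, ("a", "b"))

    def test_deviance_never_exceeds_null_deviance(self):
        rng = np.random.default_rng(13)
        design, y = cell_design(30, TRUE_COEFS, rng)
        fit = fit_gamma_glm(design, y)
        assert fit.deviance <= fit.null_deviance + 1e-8
        assert fit.deviance >= 0.0


class TestBuildDesign:
    def test_area_year_coding(self):
        samples = [
            FaecalSample("a", "East", 2015, fgcm=3.0),
            FaecalSample("b", "West", 2015, fgcm=2.0),
            FaecalSample("c", "East", 2020, fgcm=5.0),
            FaecalSample("d", "West", 2020, fgcm=4.0),
            FaecalSample("e", "West", 2015),  # no response -> dropped
        ]
        design, y = build_design(samples, "fgcm")
        assert design.columns == ("(Intercept)", "AreaWest", "Year", "AreaWest:Year")
        np.testing.assert_array_equal(
            design.matrix,
            [[1, 0, 2015, 0], [1, 1, 2015, 2015], [1, 0, 2020, 0], [1, 1, 2020, 2020]],
        )
        np.testing.assert_array_equal(y, [3.0, 2.0, 5.0, 4.0])

    def test_prey_size_reference_is_large(self):
        samples = [
            FaecalSample(s, "East", 2015, fgcm=v, prey={p})
            for s, v, p in [("a", 3.0, "Sambar"), ("b", 4.0, "Chital"), ("c", 5.0, "Hare")]
        ]
        from scatniche.synth import default_prey_reference

        ref = default_prey_reference()
        design, _ = build_design(
            samples, "fgcm", terms=("prey_size",),
            prey_size_of=lambda s: ref.size_class(next(iter(s.prey))),
        )
        assert design.columns == ("(Intercept)", "PreySizeMedium", "PreySizeSmall")
        np.testing.assert_array_equal(design.matrix[:, 1:], [[0, 0], [1, 0], [0, 1]])


class TestLikelihoodRatio:
    def make_fits(self, rng, n=60, extra_effect=0.0):
        x = rng.normal(0.0, 1.0, n)
        mu = np.exp(1.0 + extra_effect * x)
        y = rng.gamma(5.0, mu / 5.0)
        reduced = fit_gamma_glm(GLMDesign(np.ones((n, 1)), ("(Intercept)",)), y)
        full = fit_gamma_glm(
            GLMDesign(np.column_stack([np.ones(n), x]), ("(Intercept)", "x")), y
        )
        return full, reduced

    def test_identical_models_give_zero_statistic(self):
        rng = np.random.default_rng(1)
        full, _ = self.make_fits(rng)
        res = likelihood_ratio_test(full, full)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_type_one_error_for_noise_covariate(self):
        rng = np.random.default_rng(2025)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            full, reduced = self.make_fits(rng)
            if likelihood_ratio_test(full, reduced).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_for_true_effect(self):
        rng = np.random.default_rng(31)
        hits = 0
        reps = 100
        for _ in range(reps):
            full, reduced = self.make_fits(rng, n=200, extra_effect=0.3)
            if likelihood_ratio_test(full, reduced).p_value < 0.05:
                hits += 1
        assert hits / reps > 0.8

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(4)
        n = 30
        y = rng.gamma(5.0, 1.0, n)
        f1 = fit_gamma_glm(
            GLMDesign(np.column_stack([np.ones(n), rng.normal(size=n)]),
                      ("(Intercept)", "a")), y
        )
        f2 = fit_gamma_glm(
            GLMDesign(np.column_stack([np.ones(n), rng.normal(size=n)]),
                      ("(Intercept)", "b")), y
        )
        with pytest.raises(GLMError):
            likelihood_ratio_test(f1, f2)

    def test_different_responses_rejected(self):
        rng = np.random.default_rng(5)
        full, _ = self.make_fits(rng)
        _, other_reduced = self.make_fits(rng)
        with pytest.raises(GLMError):
            likelihood_ratio_test(full, other_reduced)


def fit_cells(rng, cell_log_means, n_per_cell=50, shape=5.0):
    rows, y = [], []
    for (area, year), lm in cell_log_means.items():
        west = 1.0 if area == "West" else 0.0
        mu = np.exp(lm)
        y.extend(rng.gamma(shape, mu / shape, size=n_per_cell))
        rows.extend([[1.0, west, float(year), west * float(year)]] * n_per_cell)
    design = GLMDesign(
        np.asarray(rows), ("(Intercept)", "AreaWest", "Year", "AreaWest:Year")
    )
    return fit_gamma_glm(design, np.asarray(y))


CELLS = (("East", 2015), ("West", 2015), ("East", 2020), ("West", 2020))


class TestPairwiseContrasts:
    def test_adjustment_monotonicity_every_contrast(self):
        rng = np.random.default_rng(0)
        fit = fit_cells(rng, {c: 8.0 for c in CELLS})
        for method in ("single_step_mvn", "bonferroni"):
            for c in pairwise_contrasts(fit, method=method, n_draws=20000, seed=1):
                assert c.p_adjusted >= c.p_unadjusted - 1e-12
                assert 0.0 <= c.p_adjusted <= 1.0

    def test_reproducible_bit_for_bit_under_seed(self):
        rng = np.random.default_rng(1)
        fit = fit_cells(rng, {c: 8.0 for c in CELLS})
        a = pairwise_contrasts(fit, n_draws=20000, seed=9)
        b = pairwise_contrasts(fit, n_draws=20000, seed=9)
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]

    def test_shifted_cell_dominates_smallest_adjusted_p(self):
        rng = np.random.default_rng(17)
        means = {c: 8.0 for c in CELLS}
        means[("West", 2020)] = 8.5
        fit = fit_cells(rng, means)
        cons = pairwise_contrasts(fit, n_draws=20000, seed=2)
        ordered = sorted(cons, key=lambda c: c.p_adjusted)
        top3 = {frozenset(c.pair) for c in ordered[:3]}
        assert all("WRTR_2020" in pair for pair in top3)

    def test_familywise_error_under_global_null(self):
        rng = np.random.default_rng(404)
        reps = 500
        false_alarm = 0
        for _ in range(reps):
            fit = fit_cells(rng, {c: 8.0 for c in CELLS})
            cons = pairwise_contrasts(fit, n_draws=20000, seed=7)
            if min(c.p_adjusted for c in cons) < 0.05:
                false_alarm += 1
        assert false_alarm / reps <= 0.065


class TestHormoneVsNdvi:
    def test_df_structure_at_study_scale(self):
        rng = np.random.default_rng(3)
        ndvi = rng.uniform(0.4, 0.7, 203)
        hormone = 100.0 + 20.0 * ndvi + rng.normal(0, 5, 203)
        res, fit = hormone_vs_ndvi_lm(hormone, ndvi)
        assert res.df == (1, 201)
        assert res.statistic == pytest.approx(fit.t**2)

    def test_slope_zero_generator_t_centred_at_zero(self):
        rng = np.random.default_rng(8)
        ts = []
        for _ in range(300):
            ndvi = rng.uniform(0.3, 0.8, 50)
            hormone = rng.gamma(5.0, 20.0, 50)
            _, fit = hormone_vs_ndvi_lm(hormone, ndvi)
            ts.append(fit.t)
        assert abs(np.mean(ts)) < 3.0 / np.sqrt(300)

    def test_perfect_linear_association(self):
        ndvi = np.linspace(0.3, 0.8, 20)
        res, fit = hormone_vs_ndvi_lm(5.0 + 2.0 * ndvi, ndvi)
        assert fit.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-12


def test_model_comparison_ranks_true_model_first():
    rng = np.random.default_rng(55)
    means = {("East", 2015): 8.0, ("West", 2015): 8.1,
             ("East", 2020): 8.4, ("West", 2020): 8.9}
    fit_full = fit_cells(rng, means, n_per_cell=60)
    y = fit_full.response
    n = len(y)
    null_fit = fit_gamma_glm(GLMDesign(np.ones((n, 1)), ("(Intercept)",)), y)
    report = model_comparison({"area_year": fit_full}, null_fit)
    assert report[0]["model"] == "area_year"
    assert report[0]["aic"] < report[-1]["aic"]
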