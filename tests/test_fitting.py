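import math

import numpy as np
import pandas as pd
import pytest

import carepath as cp
from conftest import make_binary_diagram, make_gaussian_diagram, two_by_two


class TestLogitFit:
    def test_two_by_two_matches_closed_form_log_odds_ratio(self):
        """Oracle: the univariate logit MLE slope is ln(ad/bc)."""
        d = make_binary_diagram()
        data = two_by_two(a=30, b=10, c=20, d=40)
        fit = cp.fit_glm(data, d, "y")
        assert fit.coef("x1[yes]") == pytest.approx(math.log(6), abs=1e-8)
        assert fit.coef("const") == pytest.approx(math.log(20 / 40), abs=1e-8)

    @pytest.mark.parametrize("a,b,c,d", [(5, 15, 12, 8), (40, 25, 10, 45),
                                         (7, 3, 9, 11)])
    def test_closed_form_oracle_on_more_tables(self, a, b, c, d):
        data = two_by_two(a, b, c, d)
        fit = cp.fit_glm(data, make_binary_diagram(), "y")
        assert fit.coef("x1[yes]") == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-8)

    def test_deviance_trace_is_monotone(self):
        fit = cp.fit_glm(two_by_two(30, 10, 20, 40), make_binary_diagram(), "y")
        trace = fit.deviance_trace
        assert len(trace) >= 2
        assert all(b <= a + 1e-8 for a, b in zip(trace, trace[1:]))

    def test_row_order_invariance(self, diagram, survey):
        shuffled = survey.sample(frac=1.0, random_state=1)
        a = cp.fit_glm(survey, diagram, "anc4")
        b = cp.fit_glm(shuffled, diagram, "anc4")
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)

    def test_separation_raises_naming_term(self):
        data = two_by_two(a=25, b=0, c=0, d=25)  # x == y exactly
        with pytest.raises(cp.SeparationError, match="x1"):
            cp.fit_glm(data, make_binary_diagram(), "y")

    def test_ridge_fallback_pushes_through_separation(self):
        data = two_by_two(a=25, b=0, c=0, d=25)
        fit = cp.fit_glm(data, make_binary_diagram(), "y", ridge=1e-6)
        assert fit.penalized
        assert np.isfinite(fit.params).all()

    def test_rank_deficiency_names_collinear_terms(self):
        d = make_binary_diagram(n_predictors=2)
        data = two_by_two(30, 10, 20, 40).rename(columns={})
        data["x2"] = data["x1"]  # exact copy
        with pytest.raises(cp.RankDeficiencyError, match="x"):
            cp.fit_glm(data, d, "y")


class TestGaussianFit:
    def test_noise_free_line_recovered_to_machine_precision(self):
        d = make_gaussian_diagram()
        x = np.linspace(-2, 5, 40)
        data = pd.DataFrame({"x": x, "y": 1.5 + 0.75 * x})
        fit = cp.fit_glm(data, d, "y")
        assert fit.coef("x") == pytest.approx(0.75, abs=1e-12)
        assert fit.coef("const") == pytest.approx(1.5, abs=1e-12)


@pytest.fixture(scope="module")
def logit_fit():
    rng = np.random.default_rng(4)
    n = 500
    x = rng.random(n) < 0.4
    p = 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))
    data = pd.DataFrame({
        "x1": np.where(x, "yes", "no"),
        "y": np.where(rng.random(n) < p, "yes", "no"),
    })
    return cp.fit_glm(data, make_binary_diagram(), "y"), data


class TestSandwich:

    def test_meat_matches_explicit_score_loop(self, logit_fit):
        """Oracle: per-observation score outer products summed in a loop."""
        fit, _ = logit_fit
        U = fit.scores.to_numpy()
        n, k = U.shape
        meat = np.zeros((k, k))
        for i in range(n):
            meat += np.outer(U[i], U[i])
        expected = n / (n - k) * fit.bread_inv @ meat @ fit.bread_inv
        np.testing.assert_allclose(cp.sandwich_covariance(fit), expected,
                                   atol=1e-10)

    def test_matches_statsmodels_sandwich(self, logit_fit):
        """Independent route: statsmodels' HC0 sandwich times the n/(n-k)
        small-sample factor (statsmodels applies none for GLMs)."""
        import statsmodels.api as sm

        fit, data = logit_fit
        y = (data["y"] == "yes").astype(float)
        X = np.column_stack([np.ones(len(data)),
                             (data["x1"] == "yes").astype(float)])
        res = sm.GLM(y.to_numpy(), X, family=sm.families.Binomial()).fit(
            cov_type="HC0")
        n, k = X.shape
        np.testing.assert_allclose(fit.cov, n / (n - k) * res.cov_params(),
                                   rtol=1e-6)

    def test_singleton_clusters_equal_hc1(self, logit_fit):
        fit, data = logit_fit
        ids = pd.Series(np.arange(len(fit.scores)), index=fit.scores.index)
        clustered = cp.sandwich_covariance(fit, cluster_ids=ids)
        # G = n: the small-sample factors coincide exactly
        np.testing.assert_allclose(clustered, cp.sandwich_covariance(fit),
                                   atol=1e-12)

    def test_robust_close_to_classical_under_homoskedasticity(self):
        rng = np.random.default_rng(8)
        n = 10_000
        x = rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": 2.0 + 0.5 * x + rng.normal(size=n)})
        d = make_gaussian_diagram()
        robust = cp.fit_glm(data, d, "y", cov_type="hc1")
        classical = cp.fit_glm(data, d, "y", cov_type="classical")
        for term in robust.terms:
            assert robust.se(term) == pytest.approx(classical.se(term), rel=0.10)


class TestSignificanceLabel:
    @pytest.mark.parametrize("z, label", [(1.0, ""), (2.0, "*"), (3.0, "**")])
    def test_wald_stars(self, z, label):
        assert cp.significance_label(z, 1.0) == label

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            cp.significance_label(1.0, 0.0)


class TestSystem:
    def test_equation_sample_sizes_match_subpopulations(self, system_fit, survey):
        n_sick = int(survey["sick_neonate"].sum())
        n_comp = int((survey["sick_neonate"] & survey["had_complication"]).sum())
        for eq, fit in system_fit.fits.items():
            expected = n_comp if eq == "maternal_careseeking" else n_sick
            assert fit.n_used == expected

    def test_block_diagonal_cross_blocks_are_zero(self, system_fit):
        terms = system_fit.joint_terms
        cov = system_fit.joint_cov
        eqs = np.array([eq for eq, _ in terms])
        off = eqs[:, None] != eqs[None, :]
        assert np.all(cov[off] == 0.0)
        assert np.allclose(cov, cov.T)

    def test_stacked_mode_disjoint_subpopulations_zero_cross_block(
            self, diagram, survey):
        """Equations over disjoint record sets share no score products."""
        part_a = survey[survey["sick_neonate"]]
        fit_a = cp.fit_glm(part_a, diagram, "anc4")
        part_b = survey[~survey["sick_neonate"]]
        fit_b = cp.fit_glm(part_b, diagram, "anc4")
        shared = fit_a.scores.index.intersection(fit_b.scores.index)
        assert len(shared) == 0

    def test_stacked_mode_populates_cross_blocks(self, diagram, survey):
        sub = survey[survey["sick_neonate"]].head(4000)
        system = cp.fit_system(sub.assign(sick_neonate=True), diagram,
                               cp.FitOptions(joint="stacked_sandwich"))
        i = system.index_of("anc4", "const")
        j = system.index_of("facility_delivery", "const")
        assert system.joint_cov[i, j] != 0.0
        assert np.allclose(system.joint_cov, system.joint_cov.T)

    def test_exp_coefficient_presentation(self, system_fit):
        table = system_fit.to_table()
        row = table[(table.equation == "facility_delivery")
                    & (table.term == "anc4[yes]")].iloc[0]
        b = system_fit.coef("facility_delivery", "anc4[yes]")
        s = system_fit.se("facility_delivery", "anc4[yes]")
        assert row["estimate"] == pytest.approx(math.exp(b))
        assert row["ci_low"] == pytest.approx(math.exp(b - cp.Z95 * s))
        assert row["ci_high"] == pytest.approx(math.exp(b + cp.Z95 * s))

    def test_json_round_trip(self, system_fit):
        back = cp.SystemFit.from_json(system_fit.to_json())
        assert back.joint_terms == system_fit.joint_terms
        np.testing.assert_allclose(back.joint_cov, system_fit.joint_cov)
        for eq in system_fit.fits:
            np.testing.assert_allclose(back.fits[eq].params,
                                       system_fit.fits[eq].params)

    def test_fitted_anc_effect_covers_truth(self, system_fit):
        b = system_fit.coef("facility_delivery", "anc4[yes]")
        s = system_fit.se("facility_delivery", "anc4[yes]")
        truth = math.log(2.53)
        assert b - cp.Z95 * s <= truth <= b + cp.Z95 * s
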