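"""Fourth-root transform, influence screening, MCMC fit and prediction."""

import numpy as np
import pytest

from atworkforce.domains import DOMAINS
from atworkforce.prevalence_model import (
    TransformedObservation,
    fit_mcmc,
    inverse_transform,
    predict_prevalence,
    screen_outliers,
    transform_prevalence,
    _design_matrix,
)
from atworkforce.synthetic_world import SyntheticWorldConfig, generate_country_panel

from conftest import observations_from_world


class TestTransform:
    def test_analytic_values_and_fixed_points(self):
        assert transform_prevalence(0.0625) == pytest.approx(0.5)
        assert transform_prevalence(0.0) == 0.0
        assert transform_prevalence(1.0) == 1.0
        assert inverse_transform(0.5) == pytest.approx(0.0625)

    def test_round_trip_on_grid(self):
        grid = np.linspace(0.0, 1.0, 101)
        back = inverse_transform(transform_prevalence(grid))
        np.testing.assert_allclose(back, grid, atol=1e-12)

    def test_monotone_back_transform_preserves_interval_order(self):
        lo, mid, hi = 0.1, 0.3, 0.5
        assert inverse_transform(lo) <= inverse_transform(mid) <= inverse_transform(hi)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            transform_prevalence(-0.01)
        with pytest.raises(ValueError):
            transform_prevalence(1.5)


def leave_one_out_cooks(obs):
    """Independent oracle: Cook's distance by refitting without each point."""
    X, y, _ = _design_matrix(obs, DOMAINS)
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    yhat = X @ beta
    s2 = np.sum((y - yhat) ** 2) / (n - p)
    out = []
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        out.append(float(np.sum((yhat - X @ beta_i) ** 2) / (p * s2)))
    return np.array(out)


class TestOutlierScreen:
    def test_clean_data_not_flagged(self, recovery_world):
        obs = observations_from_world(recovery_world)
        kept, flagged = screen_outliers(obs)
        assert flagged == []
        assert len(kept) == len(obs)

    def test_two_planted_gross_outliers_flagged(self, recovery_world):
        obs = observations_from_world(recovery_world)
        # plant residuals of 20x the generating noise sd at the highest-
        # leverage design points of two distinct countries: masking (both
        # outliers inflate the residual variance of the screening fit)
        # makes smaller or lower-leverage plants fall under the threshold
        X, _, _ = _design_matrix(obs, DOMAINS)
        hat = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
        order = np.argsort(hat)[::-1]
        i = order[0]
        j = next(t for t in order if obs[t].country_id != obs[i].country_id)
        obs[i].y = min(1.0, obs[i].y + 0.4)
        obs[j].y = min(1.0, obs[j].y + 0.4)
        kept, flagged = screen_outliers(obs)
        assert {(o.country_id, o.domain) for o in flagged} == {
            (obs[i].country_id, obs[i].domain),
            (obs[j].country_id, obs[j].domain),
        }
        assert len(kept) == len(obs) - 2

    def test_cooks_distance_matches_leave_one_out_refit(self, recovery_world):
        obs = observations_from_world(recovery_world)[:60]
        # need >= 2 per domain: 60 consecutive obs cover 12 countries x 5 domains
        _, _ = screen_outliers(obs, threshold=np.inf)
        oracle = leave_one_out_cooks(obs)
        np.testing.assert_allclose([o.influence for o in obs], oracle, rtol=1e-8)

    def test_infinite_threshold_keeps_everything(self, recovery_world):
        obs = observations_from_world(recovery_world)
        obs[3].y = min(1.0, obs[3].y + 0.3)
        kept, flagged = screen_outliers(obs, threshold=np.inf)
        assert flagged == [] and len(kept) == len(obs)

    def test_singular_design_reported(self):
        obs = [
            TransformedObservation("A", d, 0.3, 30.0, 0.5)
            for d in DOMAINS
            for _ in range(3)
        ]  # identical covariates within every domain -> collinear
        with pytest.raises(ValueError, match="singular"):
            screen_outliers(obs)


class TestFit:
    def test_parameter_recovery_within_three_posterior_sd(self, recovery_world, recovery_fit):
        cfg = recovery_world.config
        fit = recovery_fit
        for j, d in enumerate(fit.domains):
            for draws, truth in (
                (fit.slopes_medage[:, j], cfg.true_slopes[d][0]),
                (fit.slopes_hdi[:, j], cfg.true_slopes[d][1]),
            ):
                z = abs(np.mean(draws) - truth) / np.std(draws)
                assert z < 3.0, f"{d}: posterior mean {z:.2f} sd from truth"

    def test_convergence_diagnostics_reported(self, recovery_fit):
        assert recovery_fit.converged
        assert max(recovery_fit.rhat.values()) <= 1.05
        assert min(recovery_fit.ess.values()) > 400
        assert recovery_fit.n_draws >= 1_000

    def test_identical_seed_gives_identical_draws(self, recovery_world):
        obs = observations_from_world(recovery_world)
        a = fit_mcmc(obs, seed=9, n_iter=600, burn_in=200)
        b = fit_mcmc(obs, seed=9, n_iter=600, burn_in=200)
        np.testing.assert_array_equal(a.slopes_hdi, b.slopes_hdi)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_null_hdi_slopes_covered_by_intervals(self):
        """With no true HDI effect, ~95% intervals should contain zero."""
        contain = 0
        total = 0
        for rep in range(10):
            cfg = SyntheticWorldConfig(
                seed=100 + rep,
                n_unsurveyed=1,
                true_slopes={d: (s[0], 0.0) for d, s in SyntheticWorldConfig().true_slopes.items()},
            )
            world = generate_country_panel(cfg)
            obs = observations_from_world(world)
            fit = fit_mcmc(obs, seed=rep, n_iter=8_000, burn_in=2_000)
            for j in range(len(fit.domains)):
                lo, hi = np.percentile(fit.slopes_hdi[:, j], [2.5, 97.5])
                contain += lo <= 0.0 <= hi
                total += 1
        assert contain / total >= 0.90

    def test_ols_limit_equivalence(self):
        """As residual noise vanishes, posterior means approach OLS."""
        cfg = SyntheticWorldConfig(seed=9, n_unsurveyed=1, residual_sd=5e-4)
        world = generate_country_panel(cfg)
        obs = observations_from_world(world)
        X, y, _ = _design_matrix(obs, DOMAINS)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        fit = fit_mcmc(obs, seed=2, n_iter=6_000, burn_in=2_000)
        post = np.concatenate(
            [fit.intercepts.mean(0), fit.slopes_medage.mean(0), fit.slopes_hdi.mean(0)]
        )
        assert np.max(np.abs(post - ols)) < 1e-3

    def test_degenerate_inputs_rejected(self, recovery_world):
        obs = [o for o in observations_from_world(recovery_world) if o.domain == "hearing"]
        with pytest.raises(ValueError):
            fit_mcmc(obs, seed=0, n_iter=500, burn_in=100)
        with pytest.raises(ValueError):
            fit_mcmc(observations_from_world(recovery_world), seed=0, n_iter=100, burn_in=100)


class TestPrediction:
    def test_interval_coverage_of_truth(self, recovery_world, coverage_predictions):
        hits = [
            p.ci_low <= recovery_world.true_prevalence[(p.country_id, p.domain)] <= p.ci_high
            for p in coverage_predictions
        ]
        assert 0.90 <= np.mean(hits) <= 0.98

    def test_mean_absolute_error_bounded_by_residual_noise(
        self, recovery_world, coverage_predictions
    ):
        errors, bounds = [], []
        sd = recovery_world.config.residual_sd
        for p in coverage_predictions:
            truth = recovery_world.true_prevalence[(p.country_id, p.domain)]
            errors.append(abs(p.p_hat - truth))
            # first-order error in p from y-scale noise: dp = 4 y^3 dy
            bounds.append(4 * truth ** 0.75 * sd)
        assert np.mean(errors) < 2 * np.mean(bounds)

    def test_prediction_invariant_to_country_order(self, recovery_world, recovery_fit):
        unsurveyed = [c for c in recovery_world.countries if not c.surveyed][:10]
        fwd = predict_prevalence(recovery_fit, unsurveyed, seed=3)
        rev = predict_prevalence(recovery_fit, list(reversed(unsurveyed)), seed=3)
        fwd_map = {(p.country_id, p.domain): p.p_hat for p in fwd}
        rev_map = {(p.country_id, p.domain): p.p_hat for p in rev}
        assert fwd_map == rev_map

    def test_interpolation_at_design_point(self, recovery_world, recovery_fit):
        """A country sharing a surveyed country's covariates predicts close
        to that country's observed prevalence."""
        surveyed = recovery_world.countries[4]
        clone = type(surveyed)(
            country_id="CLONE",
            population_total=surveyed.population_total,
            population_under18=surveyed.population_under18,
            population_18plus=surveyed.population_18plus,
            median_age=surveyed.median_age,
            hdi=surveyed.hdi,
            surveyed=False,
        )
        result = predict_prevalence(recovery_fit, [clone], include_residual=False, seed=1)
        for p in result:
            observed = recovery_world.true_prevalence[(surveyed.country_id, p.domain)]
            assert p.p_hat == pytest.approx(observed, abs=0.01)

    def test_missing_covariates_reported(self, recovery_fit):
        from atworkforce.prevalence_model import CountryRecord

        with pytest.raises(ValueError, match="X"):
            c = CountryRecord("X", 1e6, 3e5, 7e5, float("nan"), 0.5, False)
            predict_prevalence(recovery_fit, [c])
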