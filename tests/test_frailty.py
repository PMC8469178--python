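"""Frailty mixtures, posterior growth densities, orders and bounds."""

import math

import numpy as np
import pytest

import pvit


class TestFrailtyDistributions:
    @pytest.mark.parametrize(
        "dist, lo",
        [
            (pvit.pareto_unit_frailty(), 1.0),
            (pvit.uniform_frailty(1.0, 2.0), 1.0),
        ],
    )
    def test_density_integrates_to_one(self, dist, lo):
        from pvit.frailty import _frailty_expectation

        assert _frailty_expectation(dist, lambda x: 1.0) == pytest.approx(1.0, abs=1e-6)
        assert dist.pdf(lo - 0.5) == 0.0

    def test_config_families(self):
        assert pvit.frailty_from_config({"family": "pareto_unit"}).mean == math.inf
        u = pvit.frailty_from_config({"family": "uniform", "low": 1, "high": 3})
        assert u.mean == 2.0
        p = pvit.frailty_from_config({"family": "point", "loc": 1.5})
        assert p.atom == 1.5
        with pytest.raises(pvit.InvalidParameterError):
            pvit.frailty_from_config({"family": "gamma"})

    def test_joint_validity_rejected_when_support_too_low(self, exp1):
        # xi as small as 0.2 cannot dominate t/v0(t) on [0, 100]
        with pytest.raises(pvit.ModelInvalidError):
            pvit.MixtureModel(exp1, pvit.uniform_frailty(0.2, 0.4))


class TestMixtureLaws:
    def test_sf_one_at_zero(self, example1_mixture, uniform_mixture):
        assert pvit.mixture_sf(example1_mixture, 0.0) == 1.0
        assert pvit.mixture_sf(uniform_mixture, 0.0) == 1.0

    def test_sf_matches_conditional_monte_carlo(self, example1_mixture):
        """Rao-Blackwellized Monte Carlo over sampled growths is an
        independent oracle for the mixture survival."""
        rng = np.random.default_rng(11)
        xis = 1.0 / (1.0 - rng.uniform(size=100_000))  # inverse cdf of 1/xi^2
        lam = 1.0 / 3.0
        for t in (0.5, 1.0, 3.0):
            vals = ((xis - 1.0) * lam * t / xis + 1.0) ** (-xis / (xis - 1.0))
            mc, se = vals.mean(), vals.std() / math.sqrt(len(vals))
            assert abs(pvit.mixture_sf(example1_mixture, t) - mc) < 3 * se

    def test_narrow_frailty_reduces_to_conditional(self, exp1):
        xi0, eps = 1.8, 1e-3
        mix = pvit.MixtureModel(exp1, pvit.uniform_frailty(xi0 - eps, xi0 + eps))
        cond = pvit.ConditionalPVIT(exp1, xi0)
        for t in (0.5, 2.0):
            assert pvit.mixture_sf(mix, t) == pytest.approx(
                pvit.conditional_sf(cond, t), abs=1e-5
            )
            assert pvit.mixture_pdf(mix, t) == pytest.approx(
                pvit.conditional_pdf(cond, t), abs=1e-5
            )
            assert pvit.mixture_hazard(mix, t) == pytest.approx(
                pvit.conditional_hazard(cond, t), abs=1e-5
            )

    def test_pdf_is_negative_sf_derivative(self, uniform_mixture):
        for t in (0.5, 1.5):
            fd = -(
                pvit.mixture_sf(uniform_mixture, t + 1e-4)
                - pvit.mixture_sf(uniform_mixture, t - 1e-4)
            ) / 2e-4
            assert pvit.mixture_pdf(uniform_mixture, t) == pytest.approx(fd, abs=1e-5)

    def test_pdf_normalized(self, uniform_mixture):
        from scipy import integrate

        total, _ = integrate.quad(
            lambda t: pvit.mixture_pdf(uniform_mixture, t), 0, math.inf, limit=400
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_hazard_equals_survivor_posterior_average(self, uniform_mixture):
        """Two routes to h_U: pdf/sf ratio versus the survivor-posterior
        expectation of the conditional hazard."""
        from pvit.frailty import _frailty_expectation
        from pvit.baseline import _fast_conditional_sf

        bl = uniform_mixture.baseline
        for t in (0.5, 1.0, 2.0):
            num = _frailty_expectation(
                uniform_mixture.frailty,
                lambda xi: pvit.conditional_hazard(pvit.ConditionalPVIT(bl, xi), t)
                * _fast_conditional_sf(bl, xi, t),
            )
            den = _frailty_expectation(
                uniform_mixture.frailty, lambda xi: _fast_conditional_sf(bl, xi, t)
            )
            assert pvit.mixture_hazard(uniform_mixture, t) == pytest.approx(
                num / den, abs=1e-5
            )


class TestMixtureVitality:
    def test_at_zero_equals_mean_product(self, uniform_mixture):
        # sf(0|xi) = 1 so the ratio is E(Xi); v_U(0) = E(Xi) E(X)
        assert pvit.mixture_vitality(uniform_mixture, 0.0) == pytest.approx(1.5)

    def test_identity_matches_direct_tail_route(self, uniform_mixture):
        for t in (0.0, 0.5, 1.0, 2.0):
            a = pvit.mixture_vitality(uniform_mixture, t)
            b = pvit.mixture_vitality_direct(uniform_mixture, t)
            assert a == pytest.approx(b, abs=1e-5)

    def test_ratio_dominates_mean_growth(self, uniform_mixture):
        for t in np.linspace(0.0, 4.0, 9):
            ratio = pvit.mixture_vitality(uniform_mixture, t) / uniform_mixture.baseline.v0(t)
            assert ratio >= 1.5 - 1e-9

    def test_infinite_mean_growth_flagged(self, example1_mixture):
        assert pvit.mixture_vitality(example1_mixture, 0.5) == math.inf
        assert pvit.survivor_posterior_mean(example1_mixture, 0.5) == math.inf


class TestPosteriors:
    def test_trapezoid_mass_is_one(self, example1_mixture):
        grid = np.geomspace(1.0, 200.0, 400)
        for t in (0.5, 2.0):
            for post in (
                pvit.posterior_at_death(example1_mixture, t, grid),
                pvit.posterior_survivor(example1_mixture, t, grid),
            ):
                assert np.trapezoid(post, grid) == pytest.approx(1.0, abs=1e-4)

    def test_survivor_posterior_at_zero_proportional_to_prior(self, example1_mixture):
        grid = np.geomspace(1.0, 50.0, 100)
        post = pvit.posterior_survivor(example1_mixture, 0.0, grid)
        prior = np.array([example1_mixture.frailty.pdf(x) for x in grid])
        ratio = post / prior
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_death_posterior_matches_direct_bayes_formula(self, example1_mixture):
        """The at-death posterior is f(t|xi) g(xi) normalized, by direct
        evaluation of hazard * survival * prior."""
        grid = np.geomspace(1.0001, 100.0, 200)
        t, lam = 1.0, 1.0 / 3.0
        haz = lam / ((grid - 1.0) * lam * t / grid + 1.0)
        sf = ((grid - 1.0) * lam * t / grid + 1.0) ** (-grid / (grid - 1.0))
        raw = haz * sf * grid**-2.0
        expected = raw / np.trapezoid(raw, grid)
        post = pvit.posterior_at_death(example1_mixture, t, grid)
        assert np.allclose(post, expected, rtol=1e-7)

    def test_likelihood_ratio_orders(self, example1_mixture):
        """Survivors carry stochastically larger growth than deaths, and the
        survivor posterior lr-increases with age."""
        grid = np.geomspace(1.0001, 100.0, 250)
        for t in (0.5, 1.0, 2.0):
            surv = pvit.posterior_survivor(example1_mixture, t, grid)
            death = pvit.posterior_at_death(example1_mixture, t, grid)
            assert np.all(np.diff(surv / death) >= -1e-9)
        p1 = pvit.posterior_survivor(example1_mixture, 0.5, grid)
        p2 = pvit.posterior_survivor(example1_mixture, 2.0, grid)
        assert np.all(np.diff(p2 / p1) >= -1e-9)

    def test_survivor_posterior_mean_grows(self, uniform_mixture):
        means = [pvit.survivor_posterior_mean(uniform_mixture, t) for t in (0.0, 1.0, 3.0)]
        assert means[0] == pytest.approx(1.5)
        assert means[0] <= means[1] <= means[2]

    def test_degenerate_grid_raises(self, example1_mixture):
        with pytest.raises(pvit.DegeneratePosteriorError):
            # grid entirely outside the frailty support: prior density is 0
            pvit.posterior_survivor(example1_mixture, 1.0, np.linspace(0.1, 0.9, 10))


class TestOrderChecks:
    def test_example1_report(self, example1_mixture):
        rep = pvit.check_orders(
            example1_mixture, np.linspace(0.5, 8.0, 8), np.geomspace(1.0001, 60.0, 150)
        )
        assert rep.lr_death_vs_survivor
        assert rep.lr_survivor_time_monotone
        assert rep.hazard_below_baseline
        assert rep.st_order
        # v0(t)/t is strictly decreasing here, so the lr certificate for
        # U versus X does not apply
        assert rep.density_ratio_monotone is None

    def test_point_mass_orders_hold_with_equality(self, exp1):
        mix = pvit.MixtureModel(exp1, pvit.point_frailty(1.0))
        rep = pvit.check_orders(mix, np.linspace(0.5, 4.0, 5), np.linspace(1, 3, 5))
        assert rep.lr_death_vs_survivor and rep.lr_survivor_time_monotone
        assert rep.hazard_below_baseline and rep.st_order
        for t in (0.5, 2.0):
            assert pvit.mixture_hazard(mix, t) == pytest.approx(
                pvit.conditional_hazard(pvit.ConditionalPVIT(exp1, 1.0), t)
            )

    def test_density_ratio_turns_at_inverse_rate(self, example1_mixture):
        """f_U/f dips below one and turns upward at t = 1/rate = 3."""
        left = [pvit.density_ratio(example1_mixture, t) for t in np.linspace(0.5, 3.0, 6)]
        right = [pvit.density_ratio(example1_mixture, t) for t in np.linspace(3.0, 9.0, 6)]
        assert np.all(np.diff(left) < 0)
        assert np.all(np.diff(right) > 0)
        assert pvit.density_ratio(example1_mixture, 0.01) == pytest.approx(1.0, abs=0.02)


class TestConditionalMoments:
    def test_example2_moments(self, example2_model):
        mom = pvit.conditional_moments(example2_model)
        # sf = (1+t)^-3: mean = 1/2, E T^2 = 2 int t(1+t)^-3 = 1, var = 3/4
        assert mom.mean == pytest.approx(0.5, abs=1e-5)
        assert mom.second_moment == pytest.approx(1.0, abs=1e-4)
        assert mom.variance == pytest.approx(0.75, abs=1e-4)

    def test_unit_growth_recovers_exponential_variance(self):
        m = pvit.ConditionalPVIT(pvit.make_exponential_baseline(2.0), 1.0)
        mom = pvit.conditional_moments(m)
        assert mom.mean == pytest.approx(0.5, abs=1e-6)
        assert mom.variance == pytest.approx(0.25, abs=1e-5)

    def test_heavy_tail_variance_is_infinite(self, exp1):
        # tail exponent xi/(xi-1) <= 2 for xi >= 2: infinite second moment
        assert pvit.conditional_moments(pvit.ConditionalPVIT(exp1, 2.5)).variance == math.inf


class TestSurvivalBounds:
    def test_example2_printed_values(self, example2_model):
        assert pvit.sf_lower_bound(example2_model, 0.25) == pytest.approx(0.4)
        assert pvit.sf_upper_bound(example2_model, 1.0) == pytest.approx(0.25, abs=1e-6)
        assert pvit.sf_lower_bound(example2_model, 0.0) == pytest.approx(1.0)
        assert pvit.sf_upper_bound(example2_model, 0.0) == pytest.approx(1.0)

    def test_lower_bound_window(self, example2_model):
        with pytest.raises(pvit.InvalidParameterError):
            pvit.sf_lower_bound(example2_model, 0.5)  # t >= xi E(X)

    def test_sandwich(self, example2_model):
        """k1 <= true survival <= k2 wherever both bounds exist."""
        for t in np.linspace(0.0, 2.0, 41):
            sf = pvit.conditional_sf(example2_model, t)
            if t < 0.5:
                assert pvit.sf_lower_bound(example2_model, t) <= sf + 1e-9
            assert sf <= pvit.sf_upper_bound(example2_model, t) + 1e-9

    def test_upper_bound_unavailable_for_infinite_variance(self, exp1):
        with pytest.raises(pvit.BoundUnavailableError):
            pvit.sf_upper_bound(pvit.ConditionalPVIT(exp1, 3.0), 1.0)

    def test_closed_forms_of_example2(self, example2_model):
        # k1 = (1-2t)/(1+t), k2 = 1/(1+3t^2) over the printed grid
        for t in (0.1, 0.25, 0.4):
            assert pvit.sf_lower_bound(example2_model, t) == pytest.approx(
                (1 - 2 * t) / (1 + t)
            )
        for t in (0.25, 1.0, 2.0):
            assert pvit.sf_upper_bound(example2_model, t) == pytest.approx(
                1 / (1 + 3 * t**2), abs=1e-6
            )

    def test_st_order_mixture_dominates_baseline(self, uniform_mixture):
        for t in np.linspace(0.0, 6.0, 13):
            base_sf = pvit.conditional_sf(
                pvit.ConditionalPVIT(uniform_mixture.baseline, 1.0), t
            )
            assert base_sf <= pvit.mixture_sf(uniform_mixture, t) + 1e-9
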