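"""Unit tests of the coupled density / trait-mean right-hand side."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ecoevometa.climate import ClimateProfile, patch_temperatures
from ecoevometa.closures import ToleranceParams, TraitDistribution, mean_intrinsic_growth
from ecoevometa.dynamics import (
    CommunityParams,
    MigrationOperator,
    ModelState,
    assemble_rhs,
    dispersal_terms,
    feeding_rates,
    pack_state,
    per_capita_growth_terms,
    unpack_state,
)


def make_params(s=3, consumers=0, dispersal=100.0, a_inter=0.3, eta=2.5, sigma_g2=0.1):
    total = s + consumers
    is_consumer = np.zeros(total, dtype=bool)
    is_consumer[s:] = True
    a_const = np.zeros((total, total))
    a_const[:s, :s] = a_inter
    np.fill_diagonal(a_const[:s, :s], 1.0)
    wprey = np.zeros((total, total))
    if consumers:
        wprey[s:, :s] = 1.0 / s
    return CommunityParams(
        rho=np.where(is_consumer, 0.1, 1.0).astype(float),
        kappa=np.full(total, 0.1),
        b_w=7.0,
        a_w=0.08,
        sigma_g2=np.full(total, sigma_g2),
        sigma_e2=1e-2,
        dispersal=np.full(total, dispersal),
        dx=2e5,
        epsilon=np.where(is_consumer, 0.3, 0.0).astype(float),
        q=np.where(is_consumer, 5.0, 0.0).astype(float),
        handling=np.where(is_consumer, 2.0, 0.0).astype(float),
        is_consumer=is_consumer,
        a_const=a_const,
        wprey=wprey,
        eta=eta,
    )


class TestFeedingRates:
    def test_no_links_no_feeding(self):
        p = make_params(s=3, consumers=0)
        f = feeding_rates(np.array([1.0, 2.0, 3.0]), p)
        assert np.all(f == 0)

    def test_linear_functional_response_when_handling_zero(self):
        p = make_params(s=2, consumers=1)
        p.handling[:] = 0.0
        n = np.array([0.5, 0.2, 0.1])
        f = feeding_rates(n, p)
        expected = p.q[2] * p.wprey[2] * n
        np.testing.assert_allclose(f[2], expected)

    def test_holling_saturation_at_inverse_handling(self):
        p = make_params(s=1, consumers=1)
        p.wprey[1, 0] = 1.0  # single prey, full effort
        f = feeding_rates(np.array([1e9, 1.0]), p)
        assert f[1, 0] == pytest.approx(1.0 / p.handling[1], rel=1e-6)

    def test_negative_density_rejected(self):
        p = make_params(s=2, consumers=0)
        with pytest.raises(ValueError):
            feeding_rates(np.array([-0.1, 1.0]), p)


class TestDispersal:
    def test_homogeneous_landscape_is_fixed_point(self):
        p = make_params(s=2)
        n = np.full((2, 5), 0.7)
        mu = np.full((2, 5), 3.0)
        dn, dmu = dispersal_terms(ModelState(n, mu), p.migration)
        np.testing.assert_allclose(dn, 0.0, atol=1e-15)
        np.testing.assert_allclose(dmu, 0.0, atol=1e-15)

    def test_pure_dispersal_conserves_total_abundance(self):
        p = make_params(s=2)
        rng = np.random.default_rng(3)
        n = rng.uniform(0, 2, size=(2, 8))
        dn, _ = dispersal_terms(ModelState(n, np.zeros((2, 8))), p.migration)
        np.testing.assert_allclose(dn.sum(axis=1), 0.0, atol=1e-14)

    def test_no_trait_flux_without_trait_differences(self):
        p = make_params(s=1)
        rng = np.random.default_rng(4)
        n = rng.uniform(0.1, 2, size=(1, 6))
        mu = np.full((1, 6), -2.0)
        _, dmu = dispersal_terms(ModelState(n, mu), p.migration)
        np.testing.assert_allclose(dmu, 0.0, atol=1e-15)

    def test_trait_mixing_is_mass_weighted(self):
        # an abundant immigrant pool shifts the local mean more than a sparse one
        op = MigrationOperator(rates=np.array([1e-3]))
        mu = np.array([[0.0, 1.0]])
        heavy = op.trait_flux(np.array([[0.1, 10.0]]), mu)[0, 0]
        light = op.trait_flux(np.array([[0.1, 0.2]]), mu)[0, 0]
        assert heavy > light > 0


class TestPerCapitaGrowth:
    def test_logistic_reduction_single_species(self):
        # one resource alone at its optimum: growth = mean intrinsic growth - a*N
        p = make_params(s=1, dispersal=0.0)
        profile = ClimateProfile(n_patches=1)
        temps = patch_temperatures(0.0, profile)
        n0 = 0.4
        state = ModelState(np.array([[n0]]), np.array([[temps[0]]]), t=0.0)
        rates, _ = per_capita_growth_terms(state, 1, p, mode="constant", climate=profile)
        dist = TraitDistribution(temps[0], p.sigma_g2[0] + p.sigma_e2)
        tol = ToleranceParams(rho=1.0, b_w=7.0, a_w=0.08, kappa=0.1)
        expected = mean_intrinsic_growth(dist, temps[0], tol) - 1.0 * n0
        assert rates[0] == pytest.approx(expected, rel=1e-12)

    def test_consumer_without_prey_declines(self):
        p = make_params(s=1, consumers=1)
        profile = ClimateProfile(n_patches=1)
        state = ModelState(np.array([[0.0], [0.5]]), np.full((2, 1), 10.0), t=0.0)
        rates, _ = per_capita_growth_terms(state, 1, p, climate=profile)
        assert rates[1] < 0

    def test_identical_distributions_compete_at_kernel_maximum(self):
        # two resources with identical trait distributions: temperature-dependent
        # coefficient equals the self-overlap value for both
        p = make_params(s=2, dispersal=0.0)
        profile = ClimateProfile(n_patches=1)
        temps = patch_temperatures(0.0, profile)
        n = np.array([[0.3], [0.5]])
        mu = np.full((2, 1), temps[0])
        rates, _ = per_capita_growth_terms(ModelState(n, mu, 0.0), 1, p, mode="temperature", climate=profile)
        sigma2 = p.sigma_g2[0] + p.sigma_e2
        dist = TraitDistribution(temps[0], sigma2)
        from ecoevometa.closures import effective_competition

        alpha = effective_competition(dist, dist, p.eta)
        tol = ToleranceParams(rho=1.0, b_w=7.0, a_w=0.08, kappa=0.1)
        expected = mean_intrinsic_growth(dist, temps[0], tol) - alpha * n.sum()
        assert rates[0] == pytest.approx(expected, rel=1e-10)


class TestAssembleRhs:
    def test_zero_heritability_freezes_traits(self):
        p = make_params(s=3, consumers=1)
        p.sigma_g2[:] = 0.0  # no genetic variance -> h^2 = 0
        profile = ClimateProfile(n_patches=4)
        rng = np.random.default_rng(5)
        state = ModelState(rng.uniform(0, 1, (4, 4)), rng.uniform(-5, 25, (4, 4)), t=0.0)
        _, dmu = assemble_rhs(state, p, profile)
        np.testing.assert_allclose(dmu, 0.0, atol=1e-15)

    def test_trophic_terms_never_enter_trait_dynamics(self):
        # removing all feeding links changes dN/dt but leaves dmu/dt untouched
        profile = ClimateProfile(n_patches=3)
        rng = np.random.default_rng(6)
        n = rng.uniform(0.1, 1, (3, 3))
        mu = rng.uniform(-5, 25, (3, 3))
        p_with = make_params(s=2, consumers=1)
        p_without = make_params(s=2, consumers=1)
        p_without.wprey[:] = 0.0
        dn_w, dmu_w = assemble_rhs(ModelState(n, mu, 0.0), p_with, profile)
        dn_wo, dmu_wo = assemble_rhs(ModelState(n, mu, 0.0), p_without, profile)
        assert not np.allclose(dn_w, dn_wo)
        np.testing.assert_allclose(dmu_w, dmu_wo, rtol=1e-14)

    def test_growth_disabled_conserves_abundance_over_integration(self):
        # pure dispersal for 1000 years: per-species totals drift < 1e-8 relative
        p = make_params(s=2, dispersal=100.0)
        p.rho[:] = 1e-30  # disable growth terms
        p.kappa[:] = 0.0
        p.a_const[:] = 0.0
        profile = ClimateProfile(n_patches=10)
        rng = np.random.default_rng(7)
        n0 = rng.uniform(0.1, 2, (2, 10))
        mu0 = np.repeat(np.array([[0.0], [10.0]]), 10, axis=1)

        def rhs(t, y):
            n, mu = unpack_state(y, 2, 10)
            dn, dmu = assemble_rhs(ModelState(n, mu, t), p, profile)
            return pack_state(dn, dmu)

        sol = solve_ivp(rhs, (0, 1000), pack_state(n0, mu0), rtol=1e-10, atol=1e-12)
        n_end, _ = unpack_state(sol.y[:, -1], 2, 10)
        np.testing.assert_allclose(n_end.sum(axis=1), n0.sum(axis=1), rtol=1e-8)

    def test_two_species_lotka_volterra_equilibrium(self):
        # constant competition, frozen traits at the local optimum: the model is
        # plain Lotka-Volterra; the integrated state converges to the linear solve
        p = make_params(s=2, dispersal=0.0, a_inter=0.3)
        p.sigma_g2[:] = 0.0
        profile = ClimateProfile(c_max=0.0, c_min=0.0, n_patches=1)  # constant climate
        temps = patch_temperatures(0.0, profile)
        tol = ToleranceParams(rho=1.0, b_w=7.0, a_w=0.08, kappa=0.1)
        r = np.array(
            [mean_intrinsic_growth(TraitDistribution(temps[0], 1e-2), temps[0], tol)] * 2
        )
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        expected = np.linalg.solve(a, r)

        def rhs(t, y):
            n, mu = unpack_state(y, 2, 1)
            dn, dmu = assemble_rhs(ModelState(n, mu, t), p, profile)
            return pack_state(dn, dmu)

        y0 = pack_state(np.array([[0.1], [0.2]]), np.full((2, 1), temps[0]))
        sol = solve_ivp(rhs, (0, 4000), y0, rtol=1e-10, atol=1e-13)
        n_end, _ = unpack_state(sol.y[:, -1], 2, 1)
        np.testing.assert_allclose(n_end[:, 0], expected, rtol=1e-6)

    def test_non_finite_state_raises_with_diagnostics(self):
        p = make_params(s=1)
        profile = ClimateProfile(n_patches=2)
        state = ModelState(np.array([[1.0, np.nan]]), np.zeros((1, 2)), t=0.0)
        with pytest.raises(FloatingPointError):
            assemble_rhs(state, p, profile)

    def test_full_two_trophic_default_has_ten_thousand_state_variables(self):
        from ecoevometa.params import Scenario, draw_replicate, initial_state

        cfg = draw_replicate(Scenario("high", "high", "two", "constant"), seed=0)
        state = initial_state(cfg)
        assert pack_state(state.n, state.mu).size == 10_000
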