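"""Multispecies competition and the seed-banking annual-plant model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stochcomm import (
    CommunityParams,
    PopulationParams,
    SeedBank,
    bh_step,
    community_step_expected,
    simulate_community,
    simulate_population,
    simulate_seedbank_community,
)


def symmetric_params(S=20, R=2.25, intra=0.03, inter=0.0075, **kwargs):
    alpha = np.full((S, S), inter)
    np.fill_diagonal(alpha, intra)
    return CommunityParams(R=np.full(S, R), alpha=alpha, **kwargs)


class TestCommunityStep:
    def test_single_species_matches_bh(self):
        params = CommunityParams(R=[1.6], alpha=[[0.02]])
        out = community_step_expected(np.array([10.0]), params)
        assert out[0] == pytest.approx(bh_step(10.0, 1.6, 0.02))

    def test_two_species_equilibrium_from_linear_solve(self):
        # two identical species: N* = (R-1)/(intra+inter) = 1.25/0.0375
        params = symmetric_params(S=2, R=2.25, intra=0.03, inter=0.0075)
        n_star = params.equilibrium()
        np.testing.assert_allclose(n_star, [1.25 / 0.0375] * 2)
        np.testing.assert_allclose(community_step_expected(n_star, params), n_star)

    def test_absent_species_stays_absent(self):
        params = symmetric_params(S=3)
        out = community_step_expected(np.array([10.0, 0.0, 5.0]), params)
        assert out[1] == 0.0

    def test_shape_mismatch_rejected(self):
        params = symmetric_params(S=3)
        with pytest.raises(ValueError):
            community_step_expected(np.array([1.0, 2.0]), params)


class TestSimulateCommunity:
    def test_deterministic_converges_to_linear_solve_equilibrium(self):
        """S=20 fixed parameters: trajectory reaches alpha^-1 (R-1) to 1e-6."""
        params = symmetric_params(S=20)
        traj = simulate_community(params, np.full(20, 50.0), T=500)
        np.testing.assert_allclose(traj.abundances[-1], params.equilibrium(), atol=1e-6)

    def test_single_species_community_matches_population_engine(self):
        """S=1 community output is bitwise identical to the population engine."""
        cp = CommunityParams(R=[1.6], alpha=[[0.02]], zeta=[0.3], a=0.5, variant="both")
        pp = PopulationParams(R=1.6, alpha=0.02, zeta=0.3, a=0.5, variant="both")
        tc = simulate_community(cp, [30.0], T=200, seed=21)
        tp = simulate_population(pp, n0=30, T=200, seed=21)
        np.testing.assert_array_equal(tc.abundances, tp.abundances)

    def test_zeta_zero_reductions(self):
        base = dict(S=5, R=2.0, intra=0.03, inter=0.005)
        for noisy, clean in (("environmental", "deterministic"), ("both", "demographic")):
            pa = symmetric_params(**base, zeta=0.0, a=0.75, variant=noisy)
            pb = symmetric_params(**base, variant=clean)
            ta = simulate_community(pa, np.full(5, 40.0), T=80, seed=5)
            tb = simulate_community(pb, np.full(5, 40.0), T=80, seed=5)
            np.testing.assert_array_equal(ta.abundances, tb.abundances)

    def test_environmental_noise_independent_across_species(self):
        """Species with equal parameters get distinct noise streams."""
        params = symmetric_params(S=3, zeta=0.3, variant="environmental")
        traj = simulate_community(params, np.full(3, 30.0), T=50, seed=2)
        cols = traj.abundances
        assert not np.array_equal(cols[:, 0], cols[:, 1])
        assert not np.array_equal(cols[:, 1], cols[:, 2])

    def test_extinction_absorbing_per_species(self):
        params = symmetric_params(S=10, R=1.5, intra=0.1, inter=0.02, variant="demographic")
        traj = simulate_community(params, np.full(10, 5.0), T=200, seed=8)
        for i, et in enumerate(traj.extinction_times):
            if et is not None:
                assert np.all(traj.abundances[et:, i] == 0.0)

    def test_ricker_form_rejected_for_multispecies(self):
        with pytest.raises(ValueError):
            symmetric_params(S=2, density_form="ricker")


class TestSeedbank:
    def make_params(self, S=2, s=0.8, g=0.5, zeta=0.0, a=0.0, variant="deterministic"):
        alpha = np.full((S, S), 0.001)
        np.fill_diagonal(alpha, 0.007)
        return CommunityParams(
            R=np.full(S, 1.4), alpha=alpha, zeta=zeta, a=a, variant=variant,
            seedbank=SeedBank(s=s, g=g),
        )

    def test_full_germination_reduces_to_plain_community(self):
        """g=1: no seed carries over, dynamics equal the plain BH community."""
        params = self.make_params(g=1.0)
        plain = CommunityParams(R=params.R, alpha=params.alpha)
        n0 = np.full(2, 30.0)
        tsb = simulate_seedbank_community(params, n0, T=100)
        tpl = simulate_community(plain, n0, T=100)
        np.testing.assert_allclose(tsb.abundances, tpl.abundances, atol=1e-12)

    def test_zeta_zero_means_constant_germination(self):
        """Without noise the environmental variant equals the deterministic one."""
        pa = self.make_params(zeta=0.0, a=0.75, variant="environmental")
        pb = self.make_params(variant="deterministic")
        n0 = np.full(2, 30.0)
        ta = simulate_seedbank_community(pa, n0, T=50, seed=4)
        tb = simulate_seedbank_community(pb, n0, T=50)
        np.testing.assert_array_equal(ta.abundances, tb.abundances)

    def test_no_germination_gives_geometric_decay(self):
        """g=0, s=0.8: pure seed-bank decay N_t = N_0 0.8^t until extinction."""
        params = self.make_params(g=0.0, s=0.8)
        traj = simulate_seedbank_community(params, np.full(2, 100.0), T=10)
        expected = 100.0 * 0.8 ** np.arange(11)
        expected[expected < 1.0] = 0.0
        np.testing.assert_allclose(traj.abundances[:, 0], expected, rtol=1e-12)

    @given(zeta=st.floats(0.0, 2.0), a=st.floats(-0.9, 0.9), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_germination_always_clipped_to_unit_interval(self, zeta, a, seed):
        """Realised germination fractions stay in [0, 1] whatever the noise,
        so abundances can never become negative through germination."""
        params = self.make_params(zeta=zeta, a=a, variant="environmental")
        traj = simulate_seedbank_community(params, np.full(2, 50.0), T=50, seed=seed)
        assert np.all(traj.abundances >= 0.0)
        # with s,g in [0,1] and clipped g_t, one step can at most multiply by
        # s + g_t R <= s + R, bounding growth even under extreme noise
        ratios = traj.abundances[1:][traj.abundances[:-1] > 0] / \
            traj.abundances[:-1][traj.abundances[:-1] > 0]
        assert np.all(ratios <= 0.8 + 1.4 + 1e-9)

    def test_demographic_variant_rejected(self):
        params = self.make_params(variant="demographic")
        with pytest.raises(ValueError):
            simulate_seedbank_community(params, np.full(2, 30.0), T=10, seed=1)

    def test_survival_domain_error(self):
        with pytest.raises(ValueError):
            SeedBank(s=1.2, g=0.5)
        with pytest.raises(ValueError):
            SeedBank(s=0.8, g=-0.1)
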