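"""Single-species dynamics: density maps, stochastic variants, extinction rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stochcomm import (
    PopulationParams,
    bh_step,
    persistence_time,
    ricker_step,
    simulate_population,
)


class TestBHStep:
    def test_extinction_is_fixed_point(self):
        assert bh_step(0.0, 1.6, 0.02) == 0.0

    def test_hand_computed_value(self):
        # 1.6*10 / (1 + 0.2) = 16/1.2
        assert bh_step(10, 1.6, 0.02) == pytest.approx(16 / 1.2)

    def test_carrying_capacity_fixed_point(self):
        # K = (R-1)/alpha = 30
        assert bh_step(30, 1.6, 0.02) == pytest.approx(30.0)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            bh_step(-1.0, 1.6, 0.02)


class TestRickerStep:
    def test_zero_and_fixed_point(self):
        K = (1.6 - 1) / 0.02
        assert ricker_step(0.0, 1.6, 0.02) == 0.0
        assert ricker_step(K, 1.6, 0.02) == pytest.approx(K)

    def test_overcompensation_closed_form(self):
        # R = e so r = 1; N = 2K maps to 2K e^{-1}
        R = math.e
        K = (R - 1) / 0.05
        assert ricker_step(2 * K, R, 0.05) == pytest.approx(2 * K * math.exp(-1))

    def test_requires_R_above_one(self):
        with pytest.raises(ValueError):
            ricker_step(5.0, 0.9, 0.05)

    def test_same_fixed_point_as_bh(self):
        """The parameterization matches the BH fixed point by construction."""
        K = (2.2 - 1) / 0.01
        assert ricker_step(K, 2.2, 0.01) == pytest.approx(bh_step(K, 2.2, 0.01))


class TestSimulatePopulation:
    def test_deterministic_monotone_convergence(self):
        params = PopulationParams(R=1.6, alpha=0.02)
        traj = simulate_population(params, n0=5, T=200)
        col = traj.species(0)
        assert np.all(np.diff(col) >= -1e-12)
        assert col[-1] == pytest.approx(30.0, abs=1e-6)

    def test_deterministic_is_seed_independent(self):
        params = PopulationParams(R=1.6, alpha=0.02)
        t1 = simulate_population(params, n0=5, T=50, seed=1)
        t2 = simulate_population(params, n0=5, T=50, seed=999)
        np.testing.assert_array_equal(t1.abundances, t2.abundances)

    def test_default_initial_condition_is_carrying_capacity(self):
        params = PopulationParams(R=1.6, alpha=0.02)
        traj = simulate_population(params, T=5)
        assert traj.species(0)[0] == 30.0

    @pytest.mark.parametrize("noisy,clean", [("environmental", "deterministic"),
                                             ("both", "demographic")])
    def test_zeta_zero_reduction_identity(self, noisy, clean):
        """zeta=0 collapses each environmental variant onto its noise-free twin."""
        pa = PopulationParams(R=1.6, alpha=0.02, zeta=0.0, a=0.5, variant=noisy)
        pb = PopulationParams(R=1.6, alpha=0.02, variant=clean)
        ta = simulate_population(pa, n0=30, T=100, seed=17)
        tb = simulate_population(pb, n0=30, T=100, seed=17)
        np.testing.assert_array_equal(ta.abundances, tb.abundances)

    def test_demographic_conditional_mean(self):
        """E[N_{t+1} | N_t] equals the deterministic map (2000 one-step reps)."""
        params = PopulationParams(R=1.6, alpha=0.02, variant="demographic")
        draws = [simulate_population(params, n0=30, T=1, seed=s).species(0)[1]
                 for s in range(2000)]
        se = np.sqrt(30.0 / len(draws))
        assert abs(np.mean(draws) - 30.0) < 3 * se

    def test_demographic_variant_is_integer_valued(self):
        params = PopulationParams(R=1.6, alpha=0.02, variant="demographic")
        traj = simulate_population(params, n0=30, T=50, seed=3)
        assert np.all(traj.abundances == np.round(traj.abundances))

    def test_extinction_is_absorbing(self):
        """Once below one individual the population stays at exactly zero."""
        params = PopulationParams(R=1.6, alpha=0.1, variant="demographic")
        for s in range(30):
            col = simulate_population(params, n0=6, T=300, seed=s).species(0)
            pt = persistence_time(col)
            if pt is not None:
                assert np.all(col[pt:] == 0.0)

    def test_extinction_risk_increases_with_competition(self):
        """Extinct-by-T fraction is higher at K=6 than K=30 (demographic noise)."""
        fractions = {}
        for alpha in (0.1, 0.02):
            params = PopulationParams(R=1.6, alpha=alpha, variant="demographic")
            extinct = sum(
                persistence_time(simulate_population(params, T=300, seed=s).species(0))
                is not None
                for s in range(100)
            )
            fractions[alpha] = extinct / 100
        assert fractions[0.1] > fractions[0.02]

    def test_ricker_persistence_increases_with_red_noise(self):
        """Overcompensatory dynamics persist longer under positively
        autocorrelated environmental noise (red) than under white noise."""
        R = math.exp(2.3)  # oscillatory regime, r = 2.3
        mean_pt = {}
        for a in (0.0, 0.75):
            pts = []
            for s in range(150):
                params = PopulationParams(R=R, alpha=(R - 1) / 20, zeta=0.3, a=a,
                                          variant="environmental", density_form="ricker")
                pt = persistence_time(simulate_population(params, n0=20, T=500, seed=s).species(0))
                pts.append(500 if pt is None else pt)
            mean_pt[a] = np.mean(pts)
        assert mean_pt[0.75] > mean_pt[0.0]

    @given(
        R=st.floats(1.1, 3.0),
        alpha=st.floats(0.005, 0.2),
        zeta=st.floats(0.0, 0.5),
        a=st.floats(-0.9, 0.9),
        variant=st.sampled_from(["deterministic", "demographic", "environmental", "both"]),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_trajectories_nonnegative_and_absorbing(self, R, alpha, zeta, a, variant, seed):
        params = PopulationParams(R=R, alpha=alpha, zeta=zeta, a=a, variant=variant)
        col = simulate_population(params, T=60, seed=seed).species(0)
        assert np.all(col >= 0)
        assert np.all((col == 0) | (col >= 1))
        pt = persistence_time(col)
        if pt is not None:
            assert np.all(col[pt:] == 0.0)

    def test_parameter_domain_errors(self):
        for kwargs in ({"R": 0.0, "alpha": 0.1}, {"R": 1.5, "alpha": -0.1},
                       {"R": 1.5, "alpha": 0.1, "zeta": -1}, {"R": 1.5, "alpha": 0.1, "a": 2},
                       {"R": 1.5, "alpha": 0.1, "variant": "nope"}):
            with pytest.raises(ValueError):
                PopulationParams(**kwargs)

    def test_stochastic_variant_requires_seed(self):
        params = PopulationParams(R=1.6, alpha=0.02, variant="demographic")
        with pytest.raises(ValueError):
            simulate_population(params, n0=30, T=10)
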