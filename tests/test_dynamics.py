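"""Monte Carlo engine: Fermi rule, payoffs, update protocol, determinism."""

import math

import numpy as np
import pytest

from inspectgame import (
    InitialStateSpec,
    LatticeState,
    PayoffParams,
    SimulationConfig,
    Strategy,
    build_payoff_matrix,
    elementary_step,
    fermi_probability,
    get_variant,
    run_simulation,
    site_payoff,
)

S = Strategy


class TestFermiProbability:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(1.3, 1.3, 0.5) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # Pi_x - Pi_y = -2 at K = 0.5: W = 1/(1+e^-4)
        assert fermi_probability(0.0, 2.0, 0.5) == pytest.approx(
            1 / (1 + math.exp(-4)), rel=1e-12
        )

    def test_worse_performing_neighbor_can_still_be_imitated(self):
        w = fermi_probability(1.0, 0.0, 0.5)
        assert 0 < w < 0.5

    def test_monotone_in_payoff_difference(self):
        ws = [fermi_probability(0.0, d, 0.5) for d in np.linspace(-3, 3, 13)]
        assert np.all(np.diff(ws) > 0)

    def test_extreme_differences_saturate_without_overflow(self):
        assert fermi_probability(0.0, 1e6, 0.5) == pytest.approx(1.0)
        assert fermi_probability(1e6, 0.0, 0.5) == pytest.approx(0.0)

    def test_low_noise_limit_approaches_step_function(self):
        K = 1e-6
        assert fermi_probability(1.0, 2.0, K) == pytest.approx(1.0)
        assert fermi_probability(2.0, 1.0, K) == pytest.approx(0.0)
        assert fermi_probability(1.5, 1.5, K) == pytest.approx(0.5)

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError):
            fermi_probability(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            fermi_probability(0.0, 0.0, -1.0)


class TestSitePayoff:
    def test_ordinary_surrounded_by_criminals(self):
        v = get_variant("three_strategy")
        grid = np.full((5, 5), v.index[S.C], dtype=np.int8)
        grid[2, 2] = v.index[S.O]
        state = LatticeState(v, grid)
        m = build_payoff_matrix(PayoffParams(alpha=0.5, beta=0.8, gamma=0.8), v)
        assert site_payoff(state, (2, 2), m) == pytest.approx(-3.2)

    def test_all_ordinary_is_zero(self):
        v = get_variant("three_strategy")
        state = LatticeState(v, np.full((5, 5), v.index[S.O], dtype=np.int8))
        m = build_payoff_matrix(PayoffParams(0.5, 0.8, 0.8), v)
        assert site_payoff(state, (1, 3), m) == 0.0

    def test_punisher_with_mixed_neighborhood(self):
        # P with neighbors {C, C, O, P}: 2(gamma-alpha) + 2(-alpha)
        v = get_variant("three_strategy")
        grid = np.full((5, 5), v.index[S.O], dtype=np.int8)
        grid[2, 2] = v.index[S.P]
        grid[1, 2] = v.index[S.C]  # up
        grid[3, 2] = v.index[S.C]  # down
        grid[2, 3] = v.index[S.P]  # right
        state = LatticeState(v, grid)
        m = build_payoff_matrix(PayoffParams(alpha=0.5, beta=0.8, gamma=0.8), v)
        assert site_payoff(state, (2, 2), m) == pytest.approx(
            2 * (0.8 - 0.5) + 2 * (-0.5)
        )


class TestElementaryStep:
    def test_homogeneous_state_is_absorbing(self):
        v = get_variant("three_strategy")
        state = LatticeState(v, np.full((6, 6), v.index[S.C], dtype=np.int8))
        m = build_payoff_matrix(PayoffParams(0.5, 0.8, 0.8), v)
        rng = np.random.default_rng(0)
        for _ in range(500):
            elementary_step(state, m, 0.5, rng)
        assert np.all(state.grid == v.index[S.C])

    def test_at_most_one_site_changes_per_step(self):
        v = get_variant("five_strategy")
        rng = np.random.default_rng(1)
        state = LatticeState(v, rng.integers(0, 5, (8, 8)).astype(np.int8))
        m = build_payoff_matrix(PayoffParams(0.5, 0.8, 1.5), v)
        for _ in range(200):
            before = state.grid.copy()
            elementary_step(state, m, 0.5, rng)
            assert (state.grid != before).sum() <= 1

    def test_adoption_rate_matches_fermi_closed_form(self):
        # On a C/L checkerboard with alpha=0.5, gamma=1.5, beta=1/6 every
        # site's payoff difference to any neighbor is |Pi_C - Pi_L| = 2,
        # so a drawn criminal flips with probability 1/(1+e^-4) and a
        # drawn L-punisher with probability 1/(1+e^4).  The per-step
        # probability that the criminal count decreases is therefore
        # 0.5/(1+e^-4); check it by Monte Carlo within 3 sigma.
        v = get_variant("minimal_CLM")
        base = np.indices((8, 8)).sum(axis=0) % 2
        grid = np.where(base == 0, v.index[S.C], v.index[S.L]).astype(np.int8)
        m = build_payoff_matrix(PayoffParams(alpha=0.5, beta=1 / 6, gamma=1.5), v)
        pi_C = 4 * (1 / 6 - 1 / 3)
        pi_L = 4 * (1.5 - 0.5) / 3
        assert pi_C - pi_L == pytest.approx(-2)
        p_expect = 0.5 * fermi_probability(pi_C, pi_L, 0.5)
        rng = np.random.default_rng(1234)
        n, hits = 20000, 0
        idx_C = v.index[S.C]
        for _ in range(n):
            state = LatticeState(v, grid.copy())
            before = int((state.grid == idx_C).sum())
            elementary_step(state, m, 0.5, rng)
            hits += int((state.grid == idx_C).sum()) < before
        sigma = math.sqrt(p_expect * (1 - p_expect) / n)
        assert hits / n == pytest.approx(p_expect, abs=3 * sigma)


class TestRunSimulation:
    @pytest.mark.parametrize(
        "variant, params",
        [
            ("three_strategy", PayoffParams(0.5, 0.8, 0.8)),
            ("five_strategy", PayoffParams(0.5, 0.7, 1.5)),
            ("minimal_CLM", PayoffParams(0.5, 0.5, 1.5)),
        ],
    )
    def test_fast_kernel_matches_literal_reference(self, variant, params):
        """The optimized kernel and the literal transcription of the update
        protocol produce bit-identical seeded trajectories."""
        cfg = SimulationConfig(
            variant=variant, params=params, L=8, max_mcs=100, sample_every=10, seed=99
        )
        fast = run_simulation(cfg, engine="fast")
        ref = run_simulation(cfg, engine="reference")
        np.testing.assert_array_equal(fast.mcs, ref.mcs)
        np.testing.assert_array_equal(fast.fractions, ref.fractions)
        np.testing.assert_array_equal(fast.final_state.grid, ref.final_state.grid)
        assert fast.extinction_mcs == ref.extinction_mcs

    def test_conservation_and_normalization(self, small_config):
        ts = run_simulation(small_config)
        assert np.all(ts.fractions >= 0)
        np.testing.assert_allclose(ts.fractions.sum(axis=1), 1.0, atol=1e-12)
        counts = ts.fractions * small_config.L**2
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_determinism_bit_identical(self, small_config):
        a = run_simulation(small_config)
        b = run_simulation(small_config)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        np.testing.assert_array_equal(a.final_state.grid, b.final_state.grid)

    def test_zero_mcs_returns_initial_fractions_only(self, small_config):
        from dataclasses import replace

        ts = run_simulation(replace(small_config, max_mcs=0))
        assert list(ts.mcs) == [0.0]
        assert ts.fractions.shape[0] == 1

    def test_homogeneous_initial_state_stays_homogeneous(self, homogeneous_C_config):
        ts = run_simulation(homogeneous_C_config)
        idx = ts.variant.index[S.C]
        assert np.all(ts.final_state.grid == idx)
        assert np.all(ts.fractions[:, idx] == 1.0)

    def test_extinction_logged_with_mcs_time(self, fig5_params):
        from inspectgame import stripes_CLM

        cfg = SimulationConfig(
            variant="minimal_CLM",
            params=fig5_params(0.5),
            L=60,
            max_mcs=400,
            sample_every=10,
            seed=2,
            initial=stripes_CLM(),
        )
        ts = run_simulation(cfg)
        # at low temptation the high-rank punisher M is squeezed out by L
        assert S.M in ts.extinction_mcs
        t_ext = ts.extinction_mcs[S.M]
        assert 0 < t_ext <= 400
        after = ts.mcs >= np.ceil(t_ext)
        assert np.all(ts.fraction_of(S.M)[after] == 0.0)

    def test_pure_criminal_fixation_at_low_reward(self):
        # low reward for punishing: criminals take over completely
        cfg = SimulationConfig(
            variant="three_strategy",
            params=PayoffParams(alpha=0.5, beta=0.8, gamma=0.3),
            L=100,
            max_mcs=2000,
            sample_every=20,
            seed=5,
        )
        ts = run_simulation(cfg)
        assert np.all(ts.final_state.grid == ts.variant.index[S.C])

    def test_invalid_engine_and_config(self, small_config):
        with pytest.raises(ValueError, match="engine"):
            run_simulation(small_config, engine="gpu")
        with pytest.raises(ValueError):
            SimulationConfig(L=16, max_mcs=10, relaxation_mcs=20)
        with pytest.raises(ValueError):
            SimulationConfig(L=16, sample_every=0)
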