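"""Move set: proposals, acceptance, xi bookkeeping, heat bath, chains."""

import numpy as np
import pytest
from scipy.stats import kstest

from napimc.action import (PathConfiguration, ThermoContext, potential_action,
                           pseudo_action, spring_action)
from napimc.estimators import default_recorders
from napimc.moves import (MoveSchedule, XiState, allowed_xi, com_move,
                          count_xi, global_excitation_move,
                          label_heatbath_move, metropolis_accept, poe_move,
                          poe_resample_xi, poe_shift, run_chain, staging_move)
from napimc.potentials import (AdiabaticSurfaceSet, HarmonicSurface,
                               Particle1DSystem)
from napimc.units import beta_from_temperature


class TestMetropolis:
    def test_nonpositive_always_accepts(self, rng):
        assert all(metropolis_accept(d, rng) for d in (-5.0, -1e-12, 0.0))

    def test_infinite_always_rejects(self, rng):
        assert not any(metropolis_accept(np.inf, rng) for _ in range(100))

    def test_nan_rejects(self, rng):
        assert not metropolis_accept(np.nan, rng)

    def test_ln2_accept_rate_half(self, rng):
        n = 100_000
        hits = sum(metropolis_accept(np.log(2.0), rng) for _ in range(n))
        # binomial 3-sigma band around p = 1/2
        assert abs(hits / n - 0.5) < 3.0 * np.sqrt(0.25 / n)

    def test_hastings_shift(self, rng):
        n = 50_000
        hits = sum(metropolis_accept(np.log(4.0), rng, log_hastings=np.log(2.0))
                   for _ in range(n))
        assert abs(hits / n - 0.5) < 3.0 * np.sqrt(0.25 / n)


class TestComMove:
    def test_spring_action_exactly_unchanged(self, rng):
        ctx = ThermoContext(beta=300.0, P=6, masses=[1836.0, 900.0])
        path = PathConfiguration(rng.normal(size=(6, 2, 3)), np.zeros(6, int))
        prop = com_move(path, 0, 0.4, rng)
        assert spring_action(prop, ctx) == pytest.approx(
            spring_action(path, ctx), rel=1e-12)

    def test_component_distribution_uniform(self, rng):
        path = PathConfiguration(np.zeros((2, 1, 1)), np.zeros(2, int))
        delta = 0.7
        shifts = np.array([com_move(path, 0, delta, rng).positions[0, 0, 0]
                           for _ in range(20_000)])
        stat = kstest(shifts, "uniform", args=(-delta, 2 * delta))
        assert stat.pvalue > 1e-3

    def test_zero_delta_is_identity(self, rng):
        path = PathConfiguration(rng.normal(size=(4, 1, 3)), np.zeros(4, int))
        prop = com_move(path, 0, 1e-300, rng)
        assert np.allclose(prop.positions, path.positions)


class TestStagingMove:
    def test_endpoints_bit_identical(self, rng):
        ctx = ThermoContext(beta=500.0, P=8, masses=[1836.0])
        path = PathConfiguration(rng.normal(size=(8, 1, 1)), np.zeros(8, int))
        j, alpha = 2, 5
        prop = staging_move(path, 0, j, alpha, ctx, rng)
        assert prop.positions[j, 0, 0] == path.positions[j, 0, 0]
        assert prop.positions[(j + alpha) % 8, 0, 0] == path.positions[(j + alpha) % 8, 0, 0]
        moved = [(j + s) % 8 for s in range(1, alpha)]
        untouched = [k for k in range(8) if k not in moved]
        assert np.array_equal(prop.positions[untouched], path.positions[untouched])

    def test_bridge_mean_and_variance(self, rng):
        # one interior bead: Gaussian with mean = midpoint, var = tau/(2m)
        m, beta, P = 1836.0, 400.0, 6
        ctx = ThermoContext(beta=beta, P=P, masses=[m])
        pos = np.zeros((P, 1, 1))
        pos[2, 0, 0] = 1.0  # endpoints at beads 0 (=0.0) and 2 (=1.0)
        path = PathConfiguration(pos, np.zeros(P, int))
        draws = np.array([
            staging_move(path, 0, 0, 2, ctx, rng).positions[1, 0, 0]
            for _ in range(100_000)])
        var = (beta / P) / (2.0 * m)
        assert abs(draws.mean() - 0.5) < 3.0 * np.sqrt(var / draws.size)
        assert abs(draws.var() - var) < 3.0 * var * np.sqrt(2.0 / draws.size)

    def test_invalid_stage_length(self, rng):
        ctx = ThermoContext(beta=400.0, P=4, masses=[1836.0])
        path = PathConfiguration(np.zeros((4, 1, 1)), np.zeros(4, int))
        with pytest.raises(ValueError):
            staging_move(path, 0, 0, 4, ctx, rng)


class TestElectronicMoves:
    def test_two_state_flip_deterministic(self, rng):
        path = PathConfiguration(np.zeros((4, 1, 1)), np.zeros(4, int))
        prop = global_excitation_move(path, rng, 2)
        assert np.all(prop.states == 1)
        assert np.array_equal(prop.positions, path.positions)

    def test_four_state_uniform_choice(self, rng):
        path = PathConfiguration(np.zeros((2, 1, 1)), np.full(2, 1))
        counts = np.zeros(4)
        n = 30_000
        for _ in range(n):
            counts[global_excitation_move(path, rng, 4).states[0]] += 1
        assert counts[1] == 0
        for s in (0, 2, 3):
            assert abs(counts[s] / n - 1 / 3) < 3 * np.sqrt(2 / 9 / n)

    def test_allowed_xi_sets(self):
        assert list(allowed_xi(7, 2)) == [0, 2, 4, 6]
        assert list(allowed_xi(8, 2)) == [0, 2, 4, 6, 8]
        assert list(allowed_xi(5, 3)) == [0, 2, 3, 4, 5]
        assert list(allowed_xi(6, 1)) == [0]

    def test_count_xi(self):
        assert count_xi(np.array([0, 0, 0, 0])) == 0
        assert count_xi(np.array([0, 1, 1, 0])) == 2
        assert count_xi(np.array([0, 1, 0, 1])) == 4


class TestPoE:
    def test_resample_pattern_hits_target_xi(self, rng):
        path = PathConfiguration(np.zeros((10, 1, 1)), np.zeros(10, int))
        xi_state = XiState.from_path(path, 2)
        for _ in range(300):
            prop, _ = poe_resample_xi(path, xi_state, rng)
            assert count_xi(prop.states) in allowed_xi(10, 2)

    def test_xi_zero_proposal_uniform(self, rng):
        path = PathConfiguration(np.zeros((6, 1, 1)),
                                 np.array([0, 1, 1, 0, 0, 1]))
        xi_state = XiState.from_path(path, 2)
        for _ in range(200):
            prop, _ = poe_resample_xi(path, xi_state, rng)
            if count_xi(prop.states) == 0:
                assert np.all(prop.states == prop.states[0])
                break
        else:
            pytest.fail("xi = 0 never drawn from 4 allowed values in 200 tries")

    def test_wall_shift_conserves_xi(self, rng):
        states = np.array([0, 0, 1, 1, 1, 0, 1, 1])
        path = PathConfiguration(np.zeros((8, 1, 1)), states)
        xi0 = count_xi(states)
        kept = 0
        for _ in range(10_000):
            prop, _ = poe_shift(path, rng)
            if prop is not None:
                assert count_xi(prop.states) == xi0
                kept += 1
                path = prop
        assert kept > 5000  # most shifts are geometrically possible

    def test_poe_move_dispatches(self, rng):
        path = PathConfiguration(np.zeros((6, 1, 1)), np.zeros(6, int))
        xi_state = XiState.from_path(path, 2)
        prop, log_h = poe_move(path, xi_state, rng)
        assert prop is None or count_xi(prop.states) in allowed_xi(6, 2)


class TestLabelHeatBath:
    def test_exact_conditional_distribution(self, memoized_coupled, rng):
        """Empirical heat-bath pattern frequencies match the enumerated
        conditional distribution of labels given frozen positions."""
        import itertools
        P = 5
        x = np.linspace(8.2, 9.3, P).reshape(P, 1, 1)
        path = PathConfiguration(x, np.zeros(P, int))
        ctx = ThermoContext(beta=beta_from_temperature(25.0), P=P,
                            masses=memoized_coupled.masses)
        # exact enumeration of the magnitude weight at fixed positions
        probs = {}
        for states in itertools.product((0, 1), repeat=P):
            p = PathConfiguration(x, np.array(states))
            s = pseudo_action(p, memoized_coupled)
            w = 0.0 if not np.isfinite(s) else np.exp(
                -potential_action(p, memoized_coupled, ctx) - s)
            probs[states] = w
        Z = sum(probs.values())
        n = 20_000
        counts = dict.fromkeys(probs, 0)
        for _ in range(n):
            prop = label_heatbath_move(path, ctx, memoized_coupled, rng)
            counts[tuple(prop.states)] += 1
        chi2 = sum((counts[s] - n * probs[s] / Z) ** 2 / (n * probs[s] / Z)
                   for s in probs if probs[s] / Z > 1e-4)
        ndof = sum(1 for s in probs if probs[s] / Z > 1e-4) - 1
        assert chi2 < ndof + 5 * np.sqrt(2 * ndof)


class TestChain:
    def test_flat_potential_com_always_accepted(self, rng):
        sys = Particle1DSystem(AdiabaticSurfaceSet([HarmonicSurface(0.0)]), 1836.0)
        ctx = ThermoContext(beta=200.0, P=4, masses=[1836.0])
        sch = MoveSchedule(delta=0.5, alpha=3, staging_prob=0.0,
                           global_excitation_period=0)
        _, stats, _ = run_chain(sys, ctx, sch, 2000, rng, burn_in=0,
                                tune_delta=False)
        assert stats.rate("com") == 1.0

    def test_free_particle_radius_of_gyration(self, rng):
        # staging on a free ring polymer: closed-form internal spread
        m, beta, P = 1836.0, 600.0, 8
        sys = Particle1DSystem(AdiabaticSurfaceSet([HarmonicSurface(0.0)]), m)
        ctx = ThermoContext(beta=beta, P=P, masses=[m])
        sch = MoveSchedule(delta=0.5, alpha=5, staging_prob=1.0,
                           global_excitation_period=0)
        rec = {"rg2": lambda p: float(np.var(p.positions[:, 0, 0]))}
        samples, _, _ = run_chain(sys, ctx, sch, 40_000, rng, burn_in=0.2,
                                  sample_stride=5, recorders=rec)
        k = np.arange(1, P)
        rg2_exact = (beta / (2 * m * P**2)) * np.sum(
            1.0 / (1.0 - np.cos(2 * np.pi * k / P)))
        vals = samples["rg2"]
        err = vals.std(ddof=1) / np.sqrt(len(vals) / 20.0)  # crude corr. factor
        assert abs(vals.mean() - rg2_exact) < 3.0 * err

    def test_delta_autotuning_targets_window(self, harmonic_system, rng):
        sys = harmonic_system["system"]
        ctx = ThermoContext(beta=harmonic_system["beta"], P=8,
                            masses=[harmonic_system["mass"]])
        sch = MoveSchedule(delta=100.0, alpha=4, staging_prob=0.5,
                           global_excitation_period=0)
        _, stats, _ = run_chain(sys, ctx, sch, 30_000, rng, burn_in=0.5,
                                recorders=default_recorders(ctx, sys))
        assert 0.25 < stats.rate("com") < 0.75
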