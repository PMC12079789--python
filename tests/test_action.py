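"""Classical isomorphic Hamiltonian: spring, potential, pseudopotential."""

import numpy as np
import pytest

from napimc.action import (PathConfiguration, ThermoContext, path_sign,
                           potential_action, pseudo_action, pseudopotential,
                           spring_action, total_action)
from napimc.moves import _delta_pot_pseudo
from napimc.potentials import (AdiabaticSurfaceSet, CoupledParticle1DSystem,
                               DiatomicSystem, MorseSurface, Particle1DSystem,
                               HarmonicSurface)
from napimc.units import cm1_to_hartree


def _random_coupled_path(rng, P=6):
    x = 8.0 + rng.normal(scale=1.0, size=(P, 1, 1))
    states = rng.integers(0, 2, size=P)
    return PathConfiguration(x, states)


class TestSpring:
    def test_coincident_beads_zero(self, harmonic_system):
        ctx = ThermoContext(beta=harmonic_system["beta"], P=8,
                            masses=[harmonic_system["mass"]])
        path = PathConfiguration.collapsed(8, np.array([[0.3]]))
        assert spring_action(path, ctx) == 0.0

    def test_two_bead_hand_value(self):
        # P = 2, positions (0, a): two links of length a, S = 2 m P a^2/(2 beta)
        m, beta, a = 1836.0, 200.0, 0.05
        ctx = ThermoContext(beta=beta, P=2, masses=[m])
        path = PathConfiguration(np.array([[[0.0]], [[a]]]), np.zeros(2, int))
        assert spring_action(path, ctx) == pytest.approx(
            2.0 * m * 2 * a**2 / (2 * beta), rel=1e-12)

    def test_homogeneity_degree_two(self, rng):
        ctx = ThermoContext(beta=500.0, P=5, masses=[1000.0, 2000.0])
        pos = rng.normal(size=(5, 2, 3))
        p1 = PathConfiguration(pos, np.zeros(5, int))
        p2 = PathConfiguration(2.0 * pos, np.zeros(5, int))
        assert spring_action(p2, ctx) == pytest.approx(
            4.0 * spring_action(p1, ctx), rel=1e-12)


class TestPotential:
    def test_minimum_zero(self, harmonic_system):
        ctx = ThermoContext(beta=harmonic_system["beta"], P=6,
                            masses=[harmonic_system["mass"]])
        path = PathConfiguration.collapsed(6, np.array([[0.0]]))
        assert potential_action(path, harmonic_system["system"], ctx) == 0.0

    def test_excited_surface_offset(self):
        # all beads on an offset surface at its minimum: action = beta * offset
        off = cm1_to_hartree(716.0)
        surfaces = AdiabaticSurfaceSet([
            MorseSurface(D=0.23, rho=1.3, re=2.35),
            MorseSurface(D=0.23, rho=1.15, re=2.48, offset=off)])
        sys = DiatomicSystem(surfaces, [21874.6, 21874.6])
        beta, P = 450.0, 10
        ctx = ThermoContext(beta=beta, P=P, masses=sys.masses)
        x0 = np.array([[0, 0, 1.24], [0, 0, -1.24]])
        path = PathConfiguration.collapsed(P, x0, state=1)
        assert potential_action(path, sys, ctx) == pytest.approx(
            beta * off, rel=1e-12)

    def test_mixed_states_brute_sum(self, memoized_coupled, rng):
        path = _random_coupled_path(rng)
        ctx = ThermoContext(beta=3000.0, P=path.P, masses=memoized_coupled.masses)
        expected = ctx.tau * sum(
            memoized_coupled.model.adiabatic_energies(float(path.positions[k, 0, 0]))[path.states[k]]
            for k in range(path.P))
        assert potential_action(path, memoized_coupled, ctx) == pytest.approx(
            expected, rel=1e-12)

    def test_rejects_bad_state_label(self, harmonic_system):
        ctx = ThermoContext(beta=100.0, P=4, masses=[1836.0])
        path = PathConfiguration.collapsed(4, np.array([[0.0]]), state=3)
        with pytest.raises(ValueError):
            potential_action(path, harmonic_system["system"], ctx)


class TestPseudopotential:
    def test_uncoupled_uniform_states_zero(self, harmonic_system):
        ctx = ThermoContext(beta=100.0, P=4, masses=[1836.0])
        path = PathConfiguration.collapsed(4, np.array([[0.0]]))
        assert pseudopotential(path, ctx, harmonic_system["system"]) == 0.0

    def test_uncoupled_mixed_states_infinite(self):
        surfaces = AdiabaticSurfaceSet([HarmonicSurface(1.0), HarmonicSurface(1.0, offset=0.1)])
        sys = Particle1DSystem(surfaces, 1836.0)
        ctx = ThermoContext(beta=100.0, P=4, masses=[1836.0])
        path = PathConfiguration.collapsed(4, np.array([[0.0]]))
        path.states[2] = 1
        assert pseudopotential(path, ctx, sys) == np.inf
        assert total_action(path, ctx, sys) == np.inf

    def test_single_excitation_segment_finite(self, memoized_coupled):
        # xi = 2 near the coupling centre: finite positive penalty
        P = 6
        x = np.linspace(8.4, 9.1, P).reshape(P, 1, 1)
        states = np.array([0, 0, 1, 1, 0, 0])
        path = PathConfiguration(x, states)
        s = pseudo_action(path, memoized_coupled)
        assert np.isfinite(s) and s > 0.0

    def test_sign_uncoupled_is_one(self, harmonic_system):
        path = PathConfiguration.collapsed(4, np.array([[0.0]]))
        assert path_sign(path, harmonic_system["system"]) == 1.0


class TestTotalAction:
    def test_free_particle_total_is_spring(self):
        sys = Particle1DSystem(
            AdiabaticSurfaceSet([HarmonicSurface(0.0)]), 1836.0)
        ctx = ThermoContext(beta=100.0, P=4, masses=[1836.0])
        path = PathConfiguration(np.linspace(0, 1, 4).reshape(4, 1, 1),
                                 np.zeros(4, int))
        assert total_action(path, ctx, sys) == pytest.approx(
            spring_action(path, ctx), rel=1e-12)

    def test_delta_equals_full_recomputation(self, memoized_coupled, rng):
        ctx = ThermoContext(beta=3000.0, P=6, masses=memoized_coupled.masses)
        old = _random_coupled_path(rng)
        new = old.copy()
        new.positions[3, 0, 0] += 0.2
        d = _delta_pot_pseudo(old, new, ctx, memoized_coupled)
        full = ((potential_action(new, memoized_coupled, ctx)
                 + pseudo_action(new, memoized_coupled))
                - (potential_action(old, memoized_coupled, ctx)
                   + pseudo_action(old, memoized_coupled)))
        assert d == pytest.approx(full, abs=1e-10)

    def test_cyclic_invariance(self, memoized_coupled, rng):
        ctx = ThermoContext(beta=3000.0, P=6, masses=memoized_coupled.masses)
        path = _random_coupled_path(rng)
        S0 = total_action(path, ctx, memoized_coupled)
        for shift in (1, 3, 5):
            rolled = PathConfiguration(np.roll(path.positions, shift, axis=0),
                                       np.roll(path.states, shift))
            assert total_action(rolled, ctx, memoized_coupled) == pytest.approx(
                S0, rel=1e-10)

    def test_translation_invariance_diatomic(self, h2_morse, rng):
        sys = DiatomicSystem(AdiabaticSurfaceSet([h2_morse]), [1837.0, 1837.0])
        ctx = ThermoContext(beta=1000.0, P=5, masses=sys.masses)
        pos = rng.normal(scale=0.1, size=(5, 2, 3))
        pos[:, 0, 2] += 1.4
        path = PathConfiguration(pos, np.zeros(5, int))
        shifted = PathConfiguration(pos + np.array([0.3, -0.2, 0.5]),
                                    np.zeros(5, int))
        assert total_action(shifted, ctx, sys) == pytest.approx(
            total_action(path, ctx, sys), rel=1e-12)

    def test_adiabatic_limit_per_surface_decomposition(self):
        # with zero coupling and uniform states the action has no cross terms
        surfaces = AdiabaticSurfaceSet([HarmonicSurface(1e-4),
                                        HarmonicSurface(2e-4, offset=1e-3)])
        sys = Particle1DSystem(surfaces, 1836.0)
        ctx = ThermoContext(beta=800.0, P=4, masses=[1836.0])
        pos = np.array([0.1, -0.2, 0.15, 0.0]).reshape(4, 1, 1)
        for s in (0, 1):
            path = PathConfiguration(pos, np.full(4, s))
            single = Particle1DSystem(
                AdiabaticSurfaceSet([surfaces.surfaces[s]]), 1836.0)
            ref = PathConfiguration(pos, np.zeros(4, int))
            assert total_action(path, ctx, sys) == pytest.approx(
                total_action(ref, ctx, single), rel=1e-12)


class TestThermoContext:
    def test_validation(self):
        with pytest.raises(ValueError):
            ThermoContext(beta=-1.0, P=4, masses=[1.0])
        with pytest.raises(ValueError):
            ThermoContext(beta=1.0, P=1, masses=[1.0])
        with pytest.raises(ValueError):
            ThermoContext(beta=1.0, P=4, masses=[-2.0])

    def test_derived_quantities(self):
        ctx = ThermoContext(beta=100.0, P=25, masses=[2.0])
        assert ctx.tau == pytest.approx(4.0)
        assert ctx.omega_P == pytest.approx(np.sqrt(25) / 100.0)
        assert ctx.spring_k(2.0) == pytest.approx(2.0 * 25 / 200.0)
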