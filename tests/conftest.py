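import numpy as np
import pytest

from napimc.potentials import (AdiabaticSurfaceSet, CoupledParticle1DSystem,
                               HarmonicSurface, MorseSurface,
                               Particle1DSystem, TwoStateGaussianModel)


@pytest.fixture(scope="session")
def benchmark_model() -> TwoStateGaussianModel:
    """Two harmonic diabats with Gaussian coupling (printed parameter set)."""
    return TwoStateGaussianModel.benchmark()


@pytest.fixture(scope="session")
def h2_morse() -> MorseSurface:
    from napimc.io_cli import h2_surface
    return h2_surface()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250918)


@pytest.fixture(scope="session")
def harmonic_system():
    """1D harmonic oscillator (m = 1836, omega = 0.01 a.u.) with beta*omega = 2."""
    mass, omega = 1836.0, 0.01
    system = Particle1DSystem(
        AdiabaticSurfaceSet([HarmonicSurface.from_frequency(mass, omega)]), mass)
    return {"system": system, "mass": mass, "omega": omega, "beta": 2.0 / omega,
            "E_exact": omega / 2.0 / np.tanh(1.0),
            "T_exact": omega / 4.0 / np.tanh(1.0)}


class MemoizedCoupledSystem(CoupledParticle1DSystem):
    """Coupled 1D system with cached diagonalizations (frozen-grid tests)."""

    def __init__(self, model):
        super().__init__(model)
        self._cache = {}

    def adiabatic_point(self, x):
        key = float(x[0, 0])
        if key not in self._cache:
            self._cache[key] = super().adiabatic_point(x)
        return self._cache[key]

    def bead_energy(self, x, state):
        return float(self.adiabatic_point(x).energies[state])


@pytest.fixture(scope="session")
def memoized_coupled(benchmark_model):
    return MemoizedCoupledSystem(benchmark_model)
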