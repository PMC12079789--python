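"""Electronic models: scalar surfaces, the two-state diabatic benchmark,
adiabatization and electronic overlaps.

Two kinds of electronic-structure input are supported:

* an :class:`AdiabaticSurfaceSet` — a list of uncoupled scalar potential
  curves (Morse, harmonic), one per electronic state; appropriate when the
  diabatic couplings vanish, so electronic overlaps reduce to Kronecker
  deltas;
* a :class:`TwoStateGaussianModel` — two harmonic diabats with an
  off-diagonal Gaussian coupling, the classic 1D benchmark for nonadiabatic
  statistical mechanics.  Adiabatic states are obtained by diagonalizing the
  2x2 diabatic matrix at each geometry; since the diabatic basis is taken to
  be geometry independent and orthonormal, the overlap between adiabatic
  states at two geometries is the dot product of their eigenvector
  coefficient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh


@dataclass(frozen=True)
class MorseSurface:
    """Morse curve V(r) = D (1 - exp(-rho (r - re)))^2 + offset, atomic units.

    Parameters
    ----------
    D : well depth (Ha), D > 0
    rho : range parameter (1/bohr), rho > 0
    re : equilibrium separation (bohr), re > 0
    offset : vertical shift of the minimum (Ha); used e.g. for the excited
        surface of C2, whose minimum sits 716 cm^-1 above the ground state.
    """

    D: float
    rho: float
    re: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.rho > 0 and self.re > 0):
            raise ValueError("MorseSurface requires D > 0, rho > 0, re > 0")

    def energy(self, r: float) -> float:
        u = 1.0 - np.exp(-self.rho * (r - self.re))
        return self.D * u * u + self.offset

    def gradient(self, r: float) -> float:
        e = np.exp(-self.rho * (r - self.re))
        return 2.0 * self.D * self.rho * e * (1.0 - e)

    @property
    def dissociation_limit(self) -> float:
        return self.D + self.offset


@dataclass(frozen=True)
class HarmonicSurface:
    """V(x) = 0.5 k (x - x0)^2 + offset (standard half-k convention)."""

    k: float
    x0: float = 0.0
    offset: float = 0.0

    def energy(self, x: float) -> float:
        return 0.5 * self.k * (x - self.x0) ** 2 + self.offset

    def gradient(self, x: float) -> float:
        return self.k * (x - self.x0)

    @classmethod
    def from_frequency(cls, mass: float, omega: float, x0: float = 0.0,
                       offset: float = 0.0) -> "HarmonicSurface":
        return cls(k=mass * omega * omega, x0=x0, offset=offset)

    def frequency(self, mass: float) -> float:
        return np.sqrt(self.k / mass)


@dataclass(frozen=True)
class TwoStateGaussianModel:
    """Two harmonic diabats with a Gaussian diabatic coupling (1D, 1 particle).

    Diagonal elements use the bare-k convention,

        V_ii(x) = k_ii (x - x_ii)^2 + eps_ii,

    under which the Table-1 diabats cross exactly at the coupling centre
    x_12; the off-diagonal element is

        V_12(x) = V_21(x) = c exp(-phi (x - x_12)^2).

    All parameters in atomic units.
    """

    k11: float
    k22: float
    x11: float
    x22: float
    eps11: float
    eps22: float
    c: float
    phi: float
    x12: float
    mass: float
    n_states: int = field(default=2, init=False)

    def diabatic_matrix(self, x: float) -> np.ndarray:
        if not np.isfinite(x):
            raise ValueError(f"non-finite position: {x}")
        v11 = self.k11 * (x - self.x11) ** 2 + self.eps11
        v22 = self.k22 * (x - self.x22) ** 2 + self.eps22
        v12 = self.c * np.exp(-self.phi * (x - self.x12) ** 2)
        return np.array([[v11, v12], [v12, v22]])

    def diabatic_gradient(self, x: float) -> np.ndarray:
        d11 = 2.0 * self.k11 * (x - self.x11)
        d22 = 2.0 * self.k22 * (x - self.x22)
        d12 = -2.0 * self.phi * (x - self.x12) * self.c * np.exp(
            -self.phi * (x - self.x12) ** 2)
        return np.array([[d11, d12], [d12, d22]])

    def adiabatic_energies(self, x: float) -> np.ndarray:
        """Closed-form 2x2 eigenvalues, ascending."""
        v = self.diabatic_matrix(x)
        mean = 0.5 * (v[0, 0] + v[1, 1])
        gap = np.hypot(0.5 * (v[0, 0] - v[1, 1]), v[0, 1])
        return np.array([mean - gap, mean + gap])

    def adiabatic_gradients(self, x: float) -> np.ndarray:
        """dE_i/dx by the Hellmann-Feynman route (exact for 2x2)."""
        v = self.diabatic_matrix(x)
        g = self.diabatic_gradient(x)
        d = 0.5 * (v[0, 0] - v[1, 1])
        c = v[0, 1]
        s = np.hypot(d, c)
        mean_g = 0.5 * (g[0, 0] + g[1, 1])
        if s == 0.0:
            return np.array([mean_g, mean_g])
        sg = (d * 0.5 * (g[0, 0] - g[1, 1]) + c * g[0, 1]) / s
        return np.array([mean_g - sg, mean_g + sg])

    @classmethod
    def benchmark(cls) -> "TwoStateGaussianModel":
        """The printed benchmark parameter set (atomic units)."""
        return cls(k11=4e-5, k22=3.2e-5, x11=7.0, x22=10.5,
                   eps11=0.0, eps22=2.2782e-5, c=5e-5, phi=0.4,
                   x12=8.75, mass=3.6743e3)


@dataclass(frozen=True)
class AdiabaticPoint:
    """Adiabatic data at a single geometry.

    ``energies`` ascending; ``vectors[:, i]`` is the orthonormal coefficient
    vector of adiabatic state i in the (geometry-independent) diabatic basis,
    with a deterministic phase: the first component of magnitude above
    1e-12 of each eigenvector is made positive.  For models whose coupling
    does not change sign this renders the overlaps continuous along a path.
    """

    energies: np.ndarray
    vectors: np.ndarray


def diabatic_matrix(x: float, model: TwoStateGaussianModel) -> np.ndarray:
    """Evaluate the n x n diabatic potential matrix at position ``x``."""
    return model.diabatic_matrix(x)


def morse_energy(r: float, s: MorseSurface) -> float:
    """Morse energy at separation r > 0."""
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    return s.energy(r)


def _fix_phase(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for i in range(out.shape[1]):
        col = out[:, i]
        idx = np.argmax(np.abs(col) > 1e-12)
        if col[idx] < 0:
            out[:, i] = -col
    return out


def adiabatize(V: np.ndarray) -> AdiabaticPoint:
    """Eigen-decompose a symmetric diabatic matrix.

    Returns ascending energies and phase-fixed orthonormal eigenvectors.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("diabatic matrix must be square")
    if not np.allclose(V, V.T, atol=1e-12 * max(1.0, np.abs(V).max())):
        raise ValueError("diabatic matrix must be symmetric")
    w, v = eigh(V)
    return AdiabaticPoint(energies=w, vectors=_fix_phase(v))


def electronic_overlap(a: AdiabaticPoint, i: int, b: AdiabaticPoint, j: int) -> float:
    """Overlap <Psi_i(R_a)|Psi_j(R_b)> between adiabatic states.

    With a geometry-independent orthonormal diabatic basis this is the inner
    product of the eigenvector coefficient vectors.  At equal geometry it
    reduces to the Kronecker delta.
    """
    if a.vectors.shape != b.vectors.shape:
        raise ValueError("adiabatic points have mismatching dimensions")
    return float(a.vectors[:, i] @ b.vectors[:, j])


class AdiabaticSurfaceSet:
    """Uncoupled electronic states given as scalar potential curves."""

    def __init__(self, surfaces):
        if not surfaces:
            raise ValueError("need at least one surface")
        self.surfaces = list(surfaces)

    @property
    def n_states(self) -> int:
        return len(self.surfaces)

    def energy(self, r: float, state: int) -> float:
        return self.surfaces[state].energy(r)

    def gradient(self, r: float, state: int) -> float:
        return self.surfaces[state].gradient(r)


# ---------------------------------------------------------------------------
# System wrappers: map bead coordinates (N atoms x d dims) onto the scalar
# coordinate the electronic model lives on.  These are what the action and
# move modules consume.
# ---------------------------------------------------------------------------

class System:
    """Interface: per-bead surface energy/gradient plus adiabatic data."""

    n_atoms: int
    n_dim: int
    n_states: int
    coupled: bool = False

    def bead_energy(self, x: np.ndarray, state: int) -> float:
        raise NotImplementedError

    def bead_gradient(self, x: np.ndarray, state: int) -> np.ndarray:
        raise NotImplementedError

    def adiabatic_point(self, x: np.ndarray) -> AdiabaticPoint:
        raise NotImplementedError


class Particle1DSystem(System):
    """One particle in one dimension on a set of uncoupled surfaces."""

    n_atoms = 1
    n_dim = 1
    coupled = False

    def __init__(self, surfaces: AdiabaticSurfaceSet, mass: float):
        self.surfaces = surfaces
        self.masses = np.array([mass])

    @property
    def n_states(self) -> int:
        return self.surfaces.n_states

    def bead_energy(self, x, state):
        return self.surfaces.energy(float(x[0, 0]), state)

    def bead_gradient(self, x, state):
        return np.array([[self.surfaces.gradient(float(x[0, 0]), state)]])


class CoupledParticle1DSystem(System):
    """One particle in one dimension on a diabatic two-state model."""

    n_atoms = 1
    n_dim = 1
    coupled = True

    def __init__(self, model: TwoStateGaussianModel):
        self.model = model
        self.masses = np.array([model.mass])

    @property
    def n_states(self) -> int:
        return self.model.n_states

    def adiabatic_point(self, x) -> AdiabaticPoint:
        return adiabatize(self.model.diabatic_matrix(float(x[0, 0])))

    def bead_energy(self, x, state):
        return self.model.adiabatic_energies(float(x[0, 0]))[state]

    def bead_gradient(self, x, state):
        return np.array([[self.model.adiabatic_gradients(float(x[0, 0]))[state]]])


class DiatomicSystem(System):
    """Two atoms in 3D whose uncoupled surfaces depend on the bond length."""

    n_atoms = 2
    n_dim = 3
    coupled = False

    def __init__(self, surfaces: AdiabaticSurfaceSet, masses):
        self.surfaces = surfaces
        self.masses = np.asarray(masses, dtype=float)
        if self.masses.shape != (2,):
            raise ValueError("a diatomic needs exactly two masses")

    @property
    def n_states(self) -> int:
        return self.surfaces.n_states

    @staticmethod
    def bond_length(x: np.ndarray) -> float:
        return float(np.linalg.norm(x[0] - x[1]))

    def bead_energy(self, x, state):
        return self.surfaces.energy(self.bond_length(x), state)

    def bead_gradient(self, x, state):
        rvec = x[0] - x[1]
        r = float(np.linalg.norm(rvec))
        dv = self.surfaces.gradient(r, state)
        unit = rvec / r
        return np.array([dv * unit, -dv * unit])
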