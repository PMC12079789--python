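"""The classical isomorphic Hamiltonian of the discretized path integral.

A quantum particle at inverse temperature beta is mapped onto a ring polymer
of P beads.  The sampling weight of a configuration (bead positions R^k plus
one electronic label i_k per bead) is exp(-S) with the dimensionless action

    S = sum_{I,k} m_I P / (2 beta) |R_I^{k+1} - R_I^k|^2        (spring)
      + (beta / P) sum_k E_{i_k}(R^k)                            (potential)
      - sum_k ln |<Psi_{i_k}(R^k) | Psi_{i_{k-1}}(R^{k-1})>|     (pseudo)

(hbar = 1, cyclic convention R^{P+1} = R^1).  The third term is
beta * V_pseudo, a temperature-dependent pseudopotential built from the
electronic overlaps of neighbouring beads; it carries all nonadiabatic
effects.  When two neighbouring beads sit on different states of an
uncoupled model the overlap vanishes and the action diverges, which enforces
the adiabatic limit (all beads on one surface).  Divergence is represented
by an infinite-action sentinel (numpy.inf), never an exception, so the
Metropolis step rejects such proposals deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potentials import System, electronic_overlap

#: action value standing in for "+infinity" (zero statistical weight)
INFINITE_ACTION = np.inf

#: overlap magnitudes below this are treated as exactly zero
OVERLAP_FLOOR = 1e-300


@dataclass(frozen=True)
class ThermoContext:
    """Inverse temperature, bead count and masses (atomic units)."""

    beta: float
    P: int
    masses: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "masses", np.atleast_1d(np.asarray(self.masses, float)))
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.P < 2:
            raise ValueError("need at least two beads")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def tau(self) -> float:
        """Imaginary-time step beta / P."""
        return self.beta / self.P

    @property
    def omega_P(self) -> float:
        """Ring-polymer spring frequency sqrt(P)/beta."""
        return np.sqrt(self.P) / self.beta

    def spring_k(self, mass: float) -> float:
        """Action per squared link displacement: m P / (2 beta)."""
        return mass * self.P / (2.0 * self.beta)


@dataclass
class PathConfiguration:
    """Ring-polymer state: P x N x d bead positions plus P electronic labels."""

    positions: np.ndarray  # (P, N, d)
    states: np.ndarray     # (P,) int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (P, N, d)")
        if self.states.shape != (self.positions.shape[0],):
            raise ValueError("need exactly one electronic label per bead")

    @property
    def P(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "PathConfiguration":
        return PathConfiguration(self.positions.copy(), self.states.copy())

    @classmethod
    def collapsed(cls, P: int, x0: np.ndarray, state: int = 0) -> "PathConfiguration":
        """All beads coincident at geometry ``x0`` on one surface."""
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        return cls(np.repeat(x0[None, :, :], P, axis=0), np.full(P, state))


def spring_action(path: PathConfiguration, ctx: ThermoContext) -> float:
    """Kinetic spring term: sum over atoms and cyclic bead links."""
    diff = path.positions - np.roll(path.positions, -1, axis=0)
    per_atom = np.einsum("pnd,pnd->n", diff, diff)
    return float(np.sum(ctx.spring_k(ctx.masses) * per_atom))


def potential_action(path: PathConfiguration, model: System,
                     ctx: ThermoContext) -> float:
    """(beta/P)-weighted sum of per-bead surface energies."""
    n = model.n_states
    if np.any((path.states < 0) | (path.states >= n)):
        raise ValueError("electronic label out of range")
    tot = 0.0
    for k in range(path.P):
        tot += model.bead_energy(path.positions[k], int(path.states[k]))
    return ctx.tau * tot


def pseudopotential(path: PathConfiguration, ctx: ThermoContext,
                    model: System) -> float:
    """The temperature-dependent pseudopotential V_pseudo (energy units).

    Returns +inf when any cyclic neighbour overlap vanishes (zero weight).
    For an uncoupled model this is 0 if all beads share one state and +inf
    otherwise.
    """
    return pseudo_action(path, model) / ctx.beta


def pseudo_action(path: PathConfiguration, model: System) -> float:
    """beta * V_pseudo = -sum_k ln |<Psi_{i_k}^k | Psi_{i_{k-1}}^{k-1}>|."""
    if not model.coupled:
        return 0.0 if np.all(path.states == path.states[0]) else INFINITE_ACTION
    points = [model.adiabatic_point(path.positions[k]) for k in range(path.P)]
    s = 0.0
    for k in range(path.P):
        o = abs(electronic_overlap(points[k], int(path.states[k]),
                                   points[k - 1], int(path.states[k - 1])))
        if o < OVERLAP_FLOOR:
            return INFINITE_ACTION
        s -= np.log(o)
    return s


def path_sign(path: PathConfiguration, model: System) -> float:
    """Sign of the cyclic product of electronic overlaps (+1 or -1).

    The discretized partition function carries *signed* overlap factors;
    the chain samples their magnitude, and expectation values are
    reweighted as <A sgn>/<sgn>.  Uncoupled models always give +1.
    """
    if not model.coupled:
        return 1.0
    points = [model.adiabatic_point(path.positions[k]) for k in range(path.P)]
    prod = 1.0
    for k in range(path.P):
        o = electronic_overlap(points[k], int(path.states[k]),
                               points[k - 1], int(path.states[k - 1]))
        prod *= np.sign(o) if o != 0.0 else 0.0
    return float(prod)


def total_action(path: PathConfiguration, ctx: ThermoContext,
                 model: System) -> float:
    """Full dimensionless action S = beta * H_classical-isomorphic."""
    ps = pseudo_action(path, model)
    if not np.isfinite(ps):
        return INFINITE_ACTION
    return spring_action(path, ctx) + potential_action(path, model, ctx) + ps


# ---------------------------------------------------------------------------
# Cached evaluation for the Markov chain: per-bead energies and per-link
# overlaps are stored so a local move only touches the beads it displaced.
# The delta contract (delta == full recomputation to 1e-10) is covered by
# the move-module tests; a full refresh every RECOMPUTE_PERIOD sweeps guards
# against floating-point drift.
# ---------------------------------------------------------------------------

RECOMPUTE_PERIOD = 10_000


@dataclass
class ActionCache:
    """Per-bead energies and adiabatic data kept in sync with a path."""

    model: System
    ctx: ThermoContext
    path: PathConfiguration
    energies: np.ndarray = field(init=False)
    points: list = field(init=False)

    def __post_init__(self):
        self.refresh()

    def refresh(self) -> None:
        P = self.path.P
        self.energies = np.array([
            self.model.bead_energy(self.path.positions[k], int(self.path.states[k]))
            for k in range(P)])
        self.points = ([self.model.adiabatic_point(self.path.positions[k])
                        for k in range(P)] if self.model.coupled else [None] * P)

    def link_log_overlap(self, k: int) -> float:
        """ln |overlap| on the cyclic link (k-1, k); -inf for zero overlap."""
        if not self.model.coupled:
            same = self.path.states[k] == self.path.states[k - 1]
            return 0.0 if same else -np.inf
        o = abs(electronic_overlap(self.points[k], int(self.path.states[k]),
                                   self.points[k - 1], int(self.path.states[k - 1])))
        return np.log(o) if o >= OVERLAP_FLOOR else -np.inf

    def potential_action_total(self) -> float:
        return self.ctx.tau * float(self.energies.sum())

    def pseudo_action_total(self) -> float:
        s = 0.0
        for k in range(self.path.P):
            lo = self.link_log_overlap(k)
            if not np.isfinite(lo):
                return INFINITE_ACTION
            s -= lo
        return s
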