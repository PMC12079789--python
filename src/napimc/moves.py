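"""Markov-chain move set and Metropolis-Hastings acceptance.

Move types
----------
* centre-of-mass (CoM): translate every bead of one atom by a single random
  vector uniform in [-delta, delta)^d; the spring action is exactly
  unchanged, so acceptance uses only the potential (+ pseudopotential)
  change.
* staging: redraw the interior of a path segment of length ``alpha``
  between two fixed beads from the exact free-particle Gaussian bridge
  (Levy construction); the kinetic action is sampled exactly, so again only
  the potential change enters acceptance.
* global excitation: move every bead simultaneously to one new electronic
  state drawn uniformly from all states except the current one; needed in
  the adiabatic limit where all beads share one surface.
* propagation of excitation (PoE): two paired sub-moves for coupled models
  that control xi, the number of unlike-neighbour bead pairs along the
  necklace — (a) resample xi uniformly from its allowed values and propose
  a uniformly random state pattern with that xi, (b) shift one
  domain-wall boundary by one bead at fixed xi (a random walk of the
  excitation through the necklace).

Sub-move (a) is not symmetric across xi classes (the classes have
different sizes), so its acceptance carries the exact Hastings factor
C(P, xi_old) / C(P, xi_new); sub-move (b) is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .action import (INFINITE_ACTION, PathConfiguration, ThermoContext,
                     pseudo_action, potential_action, spring_action,
                     total_action)
from .potentials import System


@dataclass
class MoveSchedule:
    """Per-sweep move protocol and its parameters.

    One sweep attempts either a CoM or a staging move (probability
    ``staging_prob`` for staging), followed by a PoE move when
    ``poe_enabled``; every ``global_excitation_period``-th sweep a global
    excitation is attempted (0 disables excitations).
    """

    delta: float = 0.5
    alpha: int = 12
    staging_prob: float = 0.5
    global_excitation_period: int = 5
    poe_enabled: bool = False
    heatbath_period: int = 0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0.0 <= self.staging_prob <= 1.0:
            raise ValueError("staging_prob must lie in [0, 1]")


@dataclass
class AcceptanceStats:
    attempts: dict = field(default_factory=dict)
    accepts: dict = field(default_factory=dict)

    def record(self, kind: str, accepted: bool) -> None:
        self.attempts[kind] = self.attempts.get(kind, 0) + 1
        if accepted:
            self.accepts[kind] = self.accepts.get(kind, 0) + 1

    def rate(self, kind: str) -> float:
        a = self.attempts.get(kind, 0)
        return self.accepts.get(kind, 0) / a if a else float("nan")


def metropolis_accept(delta_action: float, rng: np.random.Generator,
                      log_hastings: float = 0.0) -> bool:
    """Accept with min(1, exp(-delta_action + log_hastings)).

    A NaN action difference rejects the move (and should be investigated);
    the +inf sentinel rejects deterministically.
    """
    arg = -delta_action + log_hastings
    if np.isnan(arg):
        return False
    if arg >= 0:
        return True
    return rng.random() < np.exp(arg)


# -- nuclear moves ----------------------------------------------------------

def com_move(path: PathConfiguration, atom_index: int, delta: float,
             rng: np.random.Generator) -> PathConfiguration:
    """Translate all beads of one atom by a vector uniform in [-delta, delta)."""
    d = path.positions.shape[2]
    shift = delta * (2.0 * rng.random(d) - 1.0)
    new = path.copy()
    new.positions[:, atom_index, :] += shift
    return new


def staging_move(path: PathConfiguration, atom_index: int, j: int, alpha: int,
                 ctx: ThermoContext, rng: np.random.Generator) -> PathConfiguration:
    """Redraw beads j+1 .. j+alpha-1 (cyclic) of one atom from the free bridge.

    Sequential Levy construction: bead j+s is Gaussian with mean
    ((alpha-s) R^{j+s-1} + R^{j+alpha})/(alpha-s+1) and variance
    (tau/m) (alpha-s)/(alpha-s+1) per Cartesian component.
    """
    P = path.P
    if not 1 < alpha < P:
        raise ValueError(f"stage length must satisfy 1 < alpha < P, got {alpha}")
    m = ctx.masses[atom_index]
    tau = ctx.tau
    new = path.copy()
    end = new.positions[(j + alpha) % P, atom_index, :]
    prev = new.positions[j % P, atom_index, :]
    for s in range(1, alpha):
        gap = alpha - s
        mean = (gap * prev + end) / (gap + 1.0)
        var = (tau / m) * gap / (gap + 1.0)
        prev = mean + np.sqrt(var) * rng.standard_normal(prev.shape)
        new.positions[(j + s) % P, atom_index, :] = prev
    return new


# -- electronic moves -------------------------------------------------------

def global_excitation_move(path: PathConfiguration, rng: np.random.Generator,
                           n_states: int) -> PathConfiguration:
    """Assign one new state (uniform among the others) to every bead."""
    if n_states < 2:
        return path.copy()
    current = int(path.states[0])
    choices = [s for s in range(n_states) if s != current]
    new_state = choices[int(rng.integers(len(choices)))]
    new = path.copy()
    new.states[:] = new_state
    return new


def count_xi(states: np.ndarray) -> int:
    """Number of unlike cyclic neighbour pairs (the overlap-count indicator)."""
    return int(np.sum(states != np.roll(states, 1)))


def allowed_xi(P: int, n_states: int) -> np.ndarray:
    """Allowed values of the unlike-neighbour count on a P-bead necklace.

    With two electronic states domain walls come in pairs, so xi is even;
    with more states any count except 1 can occur.
    """
    if n_states < 2:
        return np.array([0])
    if n_states == 2:
        return np.arange(0, 2 * (P // 2) + 1, 2)
    return np.array([0] + list(range(2, P + 1)))


@dataclass
class XiState:
    """Current unlike-neighbour count and its allowed set."""

    xi: int
    allowed: np.ndarray

    @classmethod
    def from_path(cls, path: PathConfiguration, n_states: int) -> "XiState":
        return cls(xi=count_xi(path.states), allowed=allowed_xi(path.P, n_states))


def _log_binom(P: int, k: int) -> float:
    return float(gammaln(P + 1) - gammaln(k + 1) - gammaln(P - k + 1))


def poe_resample_xi(path: PathConfiguration, xi_state: XiState,
                    rng: np.random.Generator):
    """Sub-move (a): draw xi uniformly, propose a random two-state pattern.

    Returns (proposal, log_hastings).  Each pattern in the xi class is
    proposed with probability 1/(2 C(P, xi)), so the Hastings correction
    W(new->old)/W(old->new) contributes ln C(P, xi_new) - ln C(P, xi_old)
    to the log acceptance.
    """
    P = path.P
    xi_new = int(rng.choice(xi_state.allowed))
    walls = rng.choice(P, size=xi_new, replace=False) if xi_new else np.array([], int)
    is_wall = np.zeros(P, dtype=bool)
    is_wall[walls] = True  # wall w sits between beads w and w+1 (cyclic)
    states = np.empty(P, dtype=int)
    states[0] = int(rng.integers(2))
    for k in range(1, P):
        states[k] = states[k - 1] ^ int(is_wall[k - 1])
    new = path.copy()
    new.states = states
    log_h = _log_binom(P, xi_new) - _log_binom(P, xi_state.xi)
    return new, log_h


def poe_shift(path: PathConfiguration, rng: np.random.Generator):
    """Sub-move (b): move one domain wall by one bead, keeping xi fixed.

    Returns (proposal, 0.0); the proposal is None when no wall exists or the
    shift would merge two walls (which would change xi).
    """
    P = path.P
    walls = np.flatnonzero(path.states != np.roll(path.states, -1))
    if walls.size == 0:
        return None, 0.0
    w = int(walls[int(rng.integers(walls.size))])
    direction = 1 if rng.random() < 0.5 else -1
    new = path.copy()
    if direction == 1:
        # bead w+1 joins the left domain; wall moves to edge w+1
        new.states[(w + 1) % P] = new.states[w]
    else:
        # bead w joins the right domain; wall moves to edge w-1
        new.states[w] = new.states[(w + 1) % P]
    if count_xi(new.states) != count_xi(path.states):
        return None, 0.0
    return new, 0.0


def poe_move(path: PathConfiguration, xi_state: XiState,
             rng: np.random.Generator):
    """One propagation-of-excitation move: resample xi or shift a wall."""
    if rng.random() < 0.5:
        return poe_resample_xi(path, xi_state, rng)
    return poe_shift(path, rng)


def label_heatbath_move(path: PathConfiguration, ctx: ThermoContext,
                        model: System, rng: np.random.Generator) -> PathConfiguration:
    """Exact conditional resampling of all electronic labels at fixed positions.

    Draws the label pattern from its full conditional distribution under the
    sampled (magnitude) weight, by forward filtering / backward sampling
    around the cyclic chain of beads.  Being a heat-bath move it is always
    accepted and satisfies detailed balance exactly; it mixes the
    excitation sectors far faster than blind pattern proposals when the
    wall overlaps are strongly position dependent.
    """
    if not model.coupled:
        return path.copy()
    from .potentials import electronic_overlap
    P, n = path.P, model.n_states
    pts = [model.adiabatic_point(path.positions[k]) for k in range(P)]
    # bead Boltzmann factors (stabilized) and link overlap magnitudes
    E = np.array([[model.bead_energy(path.positions[k], s) for s in range(n)]
                  for k in range(P)])
    b = np.exp(-ctx.tau * (E - E.min()))
    O = np.empty((P, n, n))
    for k in range(P):  # O[k][i, j] couples bead k-1 (state i) to bead k (j)
        for i in range(n):
            for j in range(n):
                O[k, i, j] = abs(electronic_overlap(pts[k - 1], i, pts[k], j))
    f = np.empty((n, P, n))     # f[a, k, :] forward messages anchored at s_0 = a
    logw = np.zeros(n)
    for a in range(n):
        v = O[1, a, :] * b[1]
        for k in range(1, P):
            if k > 1:
                v = (v @ O[k]) * b[k]
            s = v.sum()
            if s <= 0.0:
                logw[a] = -np.inf
                break
            v = v / s
            logw[a] += np.log(s)
            f[a, k] = v
        else:
            w_close = float(b[0, a] * (f[a, P - 1] @ O[0, :, a]))
            logw[a] += np.log(w_close) if w_close > 0 else -np.inf
    logw -= logw.max()
    pa = np.exp(logw)
    a = int(rng.choice(n, p=pa / pa.sum()))
    states = np.empty(P, dtype=int)
    states[0] = a
    p_last = f[a, P - 1] * O[0, :, a]
    states[P - 1] = int(rng.choice(n, p=p_last / p_last.sum()))
    for k in range(P - 2, 0, -1):
        p_k = f[a, k] * O[k + 1, :, states[k + 1]]
        states[k] = int(rng.choice(n, p=p_k / p_k.sum()))
    new = path.copy()
    new.states = states
    return new


# -- sweep ------------------------------------------------------------------

def _delta_pot_pseudo(old: PathConfiguration, new: PathConfiguration,
                      ctx: ThermoContext, model: System) -> float:
    """Potential + pseudopotential action difference (full recomputation).

    The pure-Python chain is used at desk scale, where clarity beats the
    cached delta evaluation implemented in the production kernels; the
    kernel deltas are validated against this full recomputation.
    """
    pn = pseudo_action(new, model)
    if not np.isfinite(pn):
        return INFINITE_ACTION
    po = pseudo_action(old, model)
    return (potential_action(new, model, ctx) - potential_action(old, model, ctx)
            + pn - po)


def sweep(path: PathConfiguration, schedule: MoveSchedule, ctx: ThermoContext,
          model: System, rng: np.random.Generator,
          stats: AcceptanceStats | None = None,
          sweep_index: int = 0) -> PathConfiguration:
    """Execute one Monte Carlo sweep of the per-sweep protocol."""
    if stats is None:
        stats = AcceptanceStats()
    atom = int(rng.integers(model.n_atoms))
    if rng.random() < schedule.staging_prob and 1 < schedule.alpha < path.P:
        j = int(rng.integers(path.P))
        prop = staging_move(path, atom, j, schedule.alpha, ctx, rng)
        kind = "staging"
    else:
        prop = com_move(path, atom, schedule.delta, rng)
        kind = "com"
    dS = _delta_pot_pseudo(path, prop, ctx, model)
    ok = metropolis_accept(dS, rng)
    stats.record(kind, ok)
    if ok:
        path = prop

    if schedule.poe_enabled and model.n_states >= 2:
        xi_state = XiState.from_path(path, model.n_states)
        prop, log_h = poe_move(path, xi_state, rng)
        if prop is not None:
            dS = _delta_pot_pseudo(path, prop, ctx, model)
            ok = metropolis_accept(dS, rng, log_hastings=log_h)
            stats.record("poe", ok)
            if ok:
                path = prop

    hb = schedule.heatbath_period
    if hb and model.coupled and (sweep_index + 1) % hb == 0:
        path = label_heatbath_move(path, ctx, model, rng)
        stats.record("heatbath", True)

    period = schedule.global_excitation_period
    if (period and model.n_states >= 2 and (sweep_index + 1) % period == 0
            and np.all(path.states == path.states[0])):
        # attempted only from uniform patterns (its adiabatic-limit domain);
        # proposing one new shared state is then exactly symmetric
        prop = global_excitation_move(path, rng, model.n_states)
        dS = _delta_pot_pseudo(path, prop, ctx, model)
        ok = metropolis_accept(dS, rng)
        stats.record("excitation", ok)
        if ok:
            path = prop
    return path


def run_chain(model: System, ctx: ThermoContext, schedule: MoveSchedule,
              n_sweeps: int, rng: np.random.Generator,
              initial_path: PathConfiguration | None = None,
              burn_in: float = 0.1, sample_stride: int = 10,
              recorders: dict | None = None, tune_delta: bool = True):
    """Drive the Markov chain and record estimator samples.

    ``recorders`` maps names to callables ``f(path) -> float`` evaluated
    every ``sample_stride`` sweeps after burn-in.  During burn-in the CoM
    displacement scale is re-tuned every 200 attempts toward a 40-60 %
    acceptance window, then frozen (detailed balance holds for the frozen
    production schedule).

    Returns (samples dict of arrays, AcceptanceStats, final path).
    """
    if initial_path is None:
        x0 = np.zeros((model.n_atoms, model.n_dim))
        initial_path = PathConfiguration.collapsed(ctx.P, x0)
    path = initial_path.copy()
    recorders = recorders or {}
    n_burn = int(burn_in * n_sweeps) if burn_in < 1 else int(burn_in)
    stats = AcceptanceStats()
    burn_stats = AcceptanceStats()
    samples: dict[str, list] = {name: [] for name in recorders}
    for i in range(n_sweeps):
        in_burn = i < n_burn
        path = sweep(path, schedule, ctx, model, rng,
                     burn_stats if in_burn else stats, sweep_index=i)
        if in_burn:
            if tune_delta and burn_stats.attempts.get("com", 0) >= 200:
                r = burn_stats.rate("com")
                if r < 0.4:
                    schedule.delta *= 0.8
                elif r > 0.6:
                    schedule.delta *= 1.25
                burn_stats.attempts["com"] = burn_stats.accepts["com"] = 0
        elif (i - n_burn) % sample_stride == 0:
            for name, f in recorders.items():
                samples[name].append(f(path))
    return ({k: np.asarray(v) for k, v in samples.items()}, stats, path)
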