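"""Equilibrium observables from sampled ring-polymer configurations.

Purely position-dependent operators are estimated bead-wise,

    <O> = < (1/P) sum_k O_{i_k}(R^k) >,

the total energy as <T> + <(1/P) sum_k E_{i_k}(R^k)>, with the kinetic part
given either by the thermodynamic (primitive) estimator

    T_t = N d P / (2 beta) - sum_{I,k} m_I P / (2 beta^2) |R_I^{k+1} - R_I^k|^2

or by the centroid-virial estimator

    T_v = N d / (2 beta)
        + (1/(2P)) sum_{I,k} (R_I^k - Rbar_I) . grad_I E_{i_k}(R^k),

with the centroid Rbar_I the average of atom I's P bead positions.  Both
have the same mean; the virial form typically has far lower variance.  The
pseudopotential carries no explicit beta dependence (the electronic
overlaps depend on geometry only), so it contributes no extra term to the
energy estimator.

Standard errors come from Flyvbjerg-Petersen blocking, which is robust to
the autocorrelation of the Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .action import PathConfiguration, ThermoContext, spring_action
from .potentials import System


# -- per-configuration estimator values ------------------------------------

def potential_sample(path: PathConfiguration, model: System) -> float:
    """(1/P) sum_k E_{i_k}(R^k) for one configuration."""
    tot = 0.0
    for k in range(path.P):
        tot += model.bead_energy(path.positions[k], int(path.states[k]))
    return tot / path.P


def kinetic_thermodynamic_sample(path: PathConfiguration,
                                 ctx: ThermoContext) -> float:
    N, d = path.positions.shape[1], path.positions.shape[2]
    const = N * d * ctx.P / (2.0 * ctx.beta)
    return const - spring_action(path, ctx) / ctx.beta


def kinetic_virial_sample(path: PathConfiguration, ctx: ThermoContext,
                          model: System) -> float:
    N, d = path.positions.shape[1], path.positions.shape[2]
    centroid = path.positions.mean(axis=0)
    acc = 0.0
    for k in range(path.P):
        grad = model.bead_gradient(path.positions[k], int(path.states[k]))
        acc += float(np.sum((path.positions[k] - centroid) * grad))
    return N * d / (2.0 * ctx.beta) + acc / (2.0 * ctx.P)


def observable_sample(path: PathConfiguration, observable) -> float:
    """Bead-averaged position observable; ``observable(x, state) -> float``."""
    tot = 0.0
    for k in range(path.P):
        tot += observable(path.positions[k], int(path.states[k]))
    return tot / path.P


def default_recorders(ctx: ThermoContext, model: System,
                      extra: dict | None = None) -> dict:
    from .action import path_sign
    rec = {
        "V": lambda p: potential_sample(p, model),
        "T_t": lambda p: kinetic_thermodynamic_sample(p, ctx),
        "T_v": lambda p: kinetic_virial_sample(p, ctx, model),
        "state": lambda p: float(np.mean(p.states)),
        "sign": lambda p: path_sign(p, model),
    }
    if extra:
        rec.update(extra)
    return rec


def reweighted_mean(values: np.ndarray, signs: np.ndarray,
                    n_blocks: int = 50) -> tuple[float, float]:
    """Sign-reweighted mean <A sgn>/<sgn> with a jackknife-over-blocks error.

    The discretized weight of a coupled model carries signed electronic
    overlap factors; the chain samples the magnitude, so every observable
    must be reweighted by the configuration sign.  For an all-positive
    series this reduces to the plain mean with a blocked standard error.
    """
    values = np.asarray(values, float)
    signs = np.asarray(signs, float)
    if values.size != signs.size or values.size == 0:
        raise ValueError("values and signs must be equal-length, non-empty")
    num, den = float((values * signs).mean()), float(signs.mean())
    if den == 0.0:
        raise RuntimeError("vanishing mean sign: reweighting is ill-defined")
    n_blocks = min(n_blocks, values.size)
    nb = values.size // n_blocks * n_blocks
    vb = (values * signs)[:nb].reshape(n_blocks, -1).mean(axis=1)
    sb = signs[:nb].reshape(n_blocks, -1).mean(axis=1)
    jack = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.arange(n_blocks) != b
        jack[b] = vb[keep].mean() / sb[keep].mean()
    err = np.sqrt((n_blocks - 1) / n_blocks * np.sum((jack - jack.mean()) ** 2))
    return num / den, float(err)


# -- series-level statistics ------------------------------------------------

def blocking_error(values: np.ndarray) -> float:
    """Standard error of the mean by Flyvbjerg-Petersen blocking.

    The series is repeatedly pair-averaged; the naive standard error is
    computed at every blocking level (while at least 16 blocks remain) and
    the plateau is taken conservatively as the maximum.  For i.i.d. data
    this reduces to sigma/sqrt(n); a constant series gives 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size == 1:
        return 0.0
    best = 0.0
    while x.size >= 16:
        se = np.std(x, ddof=1) / np.sqrt(x.size)
        best = max(best, se)
        if x.size % 2:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    if best == 0.0:
        best = np.std(x, ddof=1) / np.sqrt(x.size)
    return float(best)


@dataclass
class EstimatorSeries:
    """Tagged per-sample estimator values with blocking error analysis."""

    name: str
    values: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty estimator series")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def stderr(self) -> float:
        return blocking_error(self.values)

    def __add__(self, other: "EstimatorSeries") -> "EstimatorSeries":
        return EstimatorSeries(f"{self.name}+{other.name}",
                               self.values + other.values, self.stride)


# -- headline estimators ----------------------------------------------------

def position_average(samples: np.ndarray, name: str = "O") -> EstimatorSeries:
    """Mean +/- blocking error of a recorded bead-averaged observable."""
    return EstimatorSeries(name, samples)


def kinetic_thermodynamic(samples: dict) -> EstimatorSeries:
    return EstimatorSeries("T_t", samples["T_t"])


def kinetic_virial(samples: dict) -> EstimatorSeries:
    return EstimatorSeries("T_v", samples["T_v"])


def total_energy(samples: dict, kinetic: str = "virial") -> EstimatorSeries:
    """Energy estimator: kinetic part plus bead-averaged surface energy."""
    key = {"virial": "T_v", "thermodynamic": "T_t"}[kinetic]
    return EstimatorSeries("E", samples[key] + samples["V"])
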