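"""End-to-end production protocols for the benchmark systems.

These functions wire the compiled kernels, the estimator statistics and the
heat-capacity pipeline together exactly the way the shipped example
configurations describe, so tests, the CLI and the acceptance script all
run one code path.

Conventions (documented in docs/methods.md):

* Diatomic runs simulate both atoms in 3D (P beads per atom, CoM + staging
  moves).  The tabulated molecular internal energy U is the total energy
  estimator minus the exactly known free centre-of-mass translation
  3/2 k_B T; it therefore contains rotation + vibration.
* Temperature scans for heat capacities keep the imaginary-time step
  (near-)constant, P(T) = round(P_ref * T_ref / T): at fixed P the
  primitive-approximation error is strongly temperature dependent and
  differentiating E(T) would pick it up as a large spurious heat capacity.
* c_v comes from the TV-regularized derivative of the molar energy curve
  (regularization weight from the discrepancy principle against the
  blocking errors); c_p = c_v + R by Mayer's relation, with uncertainties
  by Gaussian resampling of the per-point energies.
"""

from __future__ import annotations

import numpy as np

from .estimators import EstimatorSeries, reweighted_mean
from .heatcap import EnergyCurve, cp_with_errors
from .kernels import simulate_diatomic, simulate_two_state_1d
from .potentials import MorseSurface, TwoStateGaussianModel
from .units import (EV_JMOL, HARTREE_EV, MASS_H, beta_from_temperature,
                    bohr_to_angstrom)


def beads_for_temperature(T: float, P_ref: int = 20,
                          T_ref: float = 300.0) -> int:
    """Bead count at fixed imaginary-time step, anchored at (P_ref, T_ref)."""
    return max(4, int(round(P_ref * T_ref / T)))


def diatomic_observables(surfaces: list[MorseSurface], masses, T: float,
                         P: int, n_sweeps: int, seed: int,
                         excite_period: int = 0, stride: int = 10,
                         alpha: int = 12) -> dict:
    """One diatomic PIMC run; headline observables with blocking errors.

    Returns bond length (Angstrom), total energy and internal energy
    U = E_total - 3/2 k_B T (eV), plus the excited-state occupation.
    """
    beta = beta_from_temperature(T)
    res = simulate_diatomic(surfaces, masses, beta, P, n_sweeps, seed,
                            excite_period=excite_period, stride=stride,
                            alpha=alpha)
    kT = 1.0 / beta
    r = EstimatorSeries("r", res["r"])
    E = EstimatorSeries("E_v", res["E_v"])
    Et = EstimatorSeries("E_t", res["E_t"])
    return {
        "T": T, "P": P,
        "r0_A": bohr_to_angstrom(r.mean), "r0_err_A": bohr_to_angstrom(r.stderr),
        "E_total_eV": E.mean * HARTREE_EV, "E_total_err_eV": E.stderr * HARTREE_EV,
        "E_total_thermo_eV": Et.mean * HARTREE_EV,
        "U_eV": (E.mean - 1.5 * kT) * HARTREE_EV,
        "U_err_eV": E.stderr * HARTREE_EV,
        "excited_fraction": float(np.mean(res["state"] > 0)),
        "acceptance": res["acceptance"],
    }


def diatomic_energy_scan(surfaces: list[MorseSurface], masses,
                         temperatures: np.ndarray, n_sweeps: int, seed: int,
                         P_ref: int = 20, T_ref: float = 300.0,
                         fixed_P: int | None = None,
                         excite_period: int = 0) -> EnergyCurve:
    """Independent seeded runs on a temperature grid -> molar energy curve.

    Energies are total (centre of mass included) in J/mol so that the
    TV-regularized derivative is directly a molar heat capacity.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    E = np.empty_like(temperatures)
    sig = np.empty_like(temperatures)
    for i, T in enumerate(temperatures):
        P = fixed_P if fixed_P is not None else beads_for_temperature(
            T, P_ref, T_ref)
        beta = beta_from_temperature(T)
        res = simulate_diatomic(surfaces, masses, beta, P, n_sweeps,
                                seed + 1000 * i, excite_period=excite_period)
        s = EstimatorSeries("E_v", res["E_v"])
        E[i] = s.mean * HARTREE_EV * EV_JMOL
        sig[i] = s.stderr * HARTREE_EV * EV_JMOL
    return EnergyCurve(temperatures, E, sig)


def heat_capacity_at(curve: EnergyCurve, T0: float, lam: float | None = None,
                     n_boot: int = 200,
                     rng: np.random.Generator | None = None) -> dict:
    """c_p (J/mol/K) at the grid point nearest T0, with resampled error."""
    cp, cp_err = cp_with_errors(curve, lam=lam, n_boot=n_boot, rng=rng)
    i = int(np.argmin(np.abs(curve.T - T0)))
    return {"T": float(curve.T[i]), "cp": float(cp[i]),
            "cp_err": float(cp_err[i]), "cp_curve": cp, "cp_err_curve": cp_err}


# -- H2 ---------------------------------------------------------------------

def h2_pimc_table(n_sweeps: int = 10_000_000, seed: int = 1,
                  T: float = 300.0, P: int = 20) -> dict:
    """The published-table protocol for H2: P=20/atom, CoM+staging, alpha=12."""
    from .io_cli import h2_surface
    return diatomic_observables([h2_surface()], [MASS_H, MASS_H], T, P,
                                n_sweeps, seed)


def commensurate_temperature_grid(P_ref: int = 20, T_ref: float = 300.0,
                                  P_max: int = 24, P_min: int = 17) -> np.ndarray:
    """Scan temperatures at which the fixed time step gives integer beads.

    T_i = P_ref T_ref / P_i for integer P_i keeps the imaginary-time step
    exactly constant across the grid; rounding P on an arbitrary grid would
    imprint a systematic zig-zag on E(T) that numerical differentiation
    amplifies.
    """
    return np.array([P_ref * T_ref / P for P in range(P_max, P_min - 1, -1)])


def h2_cp_pipeline(n_sweeps_per_T: int = 2_000_000, seed: int = 1,
                   n_boot: int = 200) -> dict:
    """PIMC energy scan bracketing 300 K -> TV derivative -> Mayer's relation.

    The grid (250-353 K) is commensurate with the fixed imaginary-time step
    anchored at P = 20 per atom, 300 K.
    """
    from .io_cli import h2_surface
    Ts = commensurate_temperature_grid()
    curve = diatomic_energy_scan([h2_surface()], [MASS_H, MASS_H], Ts,
                                 n_sweeps_per_T, seed)
    return heat_capacity_at(curve, 300.0, n_boot=n_boot,
                            rng=np.random.default_rng(seed))


# -- C2 ---------------------------------------------------------------------

def c2_cp_curves(n_sweeps_per_T: int = 1_000_000, seed: int = 1,
                 T_min: float = 300.0, T_max: float = 1100.0, n_T: int = 13,
                 n_boot: int = 200) -> dict:
    """Two-state vs ground-state-only c_p(T) for C2 (J/mol/K).

    Both electronic surfaces are sampled with a global excitation attempt
    every sweep in the two-state runs; the ground-only runs ignore the
    excited surface entirely.  Returns the temperature grid, both c_p
    curves with resampled standard errors, and the excited-state occupation
    of the two-state run at each temperature.
    """
    from .io_cli import c2_surfaces
    from .units import MASS_C
    surfaces = c2_surfaces()
    Ts = np.linspace(T_min, T_max, n_T)
    masses = [MASS_C, MASS_C]
    occ = np.empty(n_T)
    curves = {}
    for tag, surf, excite in (("two_state", surfaces, 1),
                              ("ground", surfaces[:1], 0)):
        E = np.empty(n_T)
        sig = np.empty(n_T)
        for i, T in enumerate(Ts):
            P = beads_for_temperature(T, P_ref=20, T_ref=700.0)
            beta = beta_from_temperature(T)
            res = simulate_diatomic(surf, masses, beta, P, n_sweeps_per_T,
                                    seed + 1000 * i + (0 if excite else 77),
                                    excite_period=excite)
            s = EstimatorSeries("E_v", res["E_v"])
            E[i] = s.mean * HARTREE_EV * EV_JMOL
            sig[i] = s.stderr * HARTREE_EV * EV_JMOL
            if excite:
                occ[i] = float(np.mean(res["state"] > 0))
        curve = EnergyCurve(Ts, E, sig)
        cp, cp_err = cp_with_errors(curve, n_boot=n_boot,
                                    rng=np.random.default_rng(seed))
        curves[tag] = {"cp": cp, "cp_err": cp_err, "E": E, "sigma": sig}
    return {"T": Ts, "excited_fraction": occ, **curves}


# -- two-state benchmark model ---------------------------------------------

def model_system_energy(T: float, n_sweeps: int = 1_000_000, seed: int = 1,
                        P: int = 20, variant: str = "coupled") -> dict:
    """Sign-reweighted total energy of the benchmark model at one T (Ha).

    The coupled variant uses the thermodynamic kinetic estimator (exact for
    signed-overlap sampling); uncoupled variants may use either.
    """
    model = TwoStateGaussianModel.benchmark()
    beta = beta_from_temperature(T)
    res = simulate_two_state_1d(model, beta, P, n_sweeps, seed,
                                variant=variant)
    E, err = reweighted_mean(res["E_t"], res["sign"], n_blocks=20)
    return {"T": T, "E": E, "E_err": err,
            "mean_sign": float(res["sign"].mean()),
            "ground_fraction": float(res["state"].mean())}
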