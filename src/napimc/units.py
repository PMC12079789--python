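"""Unit conversions.

Everything inside the package is computed in Hartree atomic units
(hbar = m_e = e = a0 = 1).  Temperatures enter only through
beta = 1/(k_B T) with k_B in Ha/K; lengths cross the I/O boundary in
Angstrom, energies in eV or cm^-1, molar heat capacities in J mol^-1 K^-1.
"""

from __future__ import annotations

# CODATA 2018
HARTREE_EV = 27.211386245988        # eV per Hartree
HARTREE_CM1 = 219474.6313632        # cm^-1 per Hartree
BOHR_ANGSTROM = 0.529177210903      # Angstrom per bohr
KB_HA = 3.166811563e-6              # Boltzmann constant, Ha/K
R_GAS = 8.314462618                 # molar gas constant, J mol^-1 K^-1
AMU_ME = 1822.888486209             # electron masses per unified amu
EV_JMOL = 96485.33212               # J/mol per eV

# Isotope masses (atomic, i.e. including electrons), in m_e
MASS_H = 1.00782503207 * AMU_ME
MASS_C = 12.0 * AMU_ME


def angstrom_to_bohr(x: float) -> float:
    return x / BOHR_ANGSTROM


def bohr_to_angstrom(x: float) -> float:
    return x * BOHR_ANGSTROM


def ev_to_hartree(e: float) -> float:
    return e / HARTREE_EV


def hartree_to_ev(e: float) -> float:
    return e * HARTREE_EV


def cm1_to_hartree(e: float) -> float:
    return e / HARTREE_CM1


def hartree_to_cm1(e: float) -> float:
    return e * HARTREE_CM1


def inv_angstrom_to_inv_bohr(a: float) -> float:
    return a * BOHR_ANGSTROM


def beta_from_temperature(T: float) -> float:
    """Inverse temperature 1/(k_B T) in 1/Ha for T in kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 1.0 / (KB_HA * T)


def reduced_mass(m1: float, m2: float) -> float:
    return m1 * m2 / (m1 + m2)
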