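# Methods

`napimc` computes finite-temperature equilibrium properties of small
molecules whose nuclei can thermally occupy several low-lying electronic
potential energy surfaces (PESs). This note records the model, the
estimators, the numerical choices, and the limits of what a green test
establishes. Everything is computed in Hartree atomic units internally;
conversions happen only at the I/O boundary.

## The discretized partition function

The canonical quantum partition function of N nuclei with n accessible
electronic states is discretized into P imaginary-time slices (beads). A
configuration is the set of bead positions R^k (k = 1..P, cyclic) plus one
electronic label i_k per bead. Its statistical weight is exp(−S) with the
dimensionless action

    S = Σ_{I,k} m_I P/(2β) |R_I^{k+1} − R_I^k|²        (spring)
      + (β/P) Σ_k E_{i_k}(R^k)                          (potential)
      − Σ_k ln ⟨Ψ_{i_k}(R^k) | Ψ_{i_{k−1}}(R^{k−1})⟩    (overlap factors)

where E_i and Ψ_i are the adiabatic energies and states at each geometry.
The overlap term is a temperature-dependent pseudopotential that carries
all nonadiabatic effects: with uncoupled surfaces the overlaps are
Kronecker deltas, any unlike-neighbour pair has zero weight, and the
partition function factorizes into one single-PES term per surface (the
adiabatic limit). With diabatic couplings the adiabatic states mix with
geometry and unlike-neighbour "kinks" acquire finite weight.

The primitive (lowest-order Trotter) factorization is used throughout;
its discretization error is O((β/P)²) and is quantified below.

### Signed overlaps and reweighting

The overlap factors in the discretized trace are *signed*. Sampling their
absolute value as if it were the weight changes the physics: a
position⊗state transfer-matrix evaluation of the discretized partition
function for the two-state benchmark shows the signed weight converging
to the exact spectrum as P grows while the magnitude-only weight diverges
from it. The chain therefore samples the magnitude weight |W| and every
expectation is sign-reweighted,

    ⟨A⟩ = ⟨A·sgn⟩_{|W|} / ⟨sgn⟩_{|W|},

with sgn the sign of the cyclic overlap product (gauge invariant). For
the benchmark model at P = 20 the mean sign is 0.4–0.7 — a mild sign
problem that inflates the variance but leaves the estimators exact.
Errors of reweighted means use jackknife over blocks.

The electronic basis is the adiabatic one obtained by diagonalizing the
diabatic matrix at each geometry; the diabatic basis is taken geometry
independent and orthonormal, so overlaps between adiabatic states at two
geometries are dot products of eigenvector coefficient vectors.
Eigenvector phases are fixed by making the first component of magnitude
above 1e-12 positive, which keeps overlaps continuous along a path for
models whose coupling does not change sign (the magnitude weight and the
cyclic sign are phase-convention independent in any case).

## The two-state benchmark model

Two harmonic diabats with a Gaussian coupling (one particle, 1D):

    V_ii(x) = k_ii (x − x_ii)² + ε_ii ,
    V_12(x) = c exp(−φ (x − x_12)²) .

The bare-k convention (no factor 1/2) is deliberate: with the published
parameter set the diabats then cross at x ≈ 8.74, i.e. the coupling
Gaussian (centred at x_12 = 8.75) sits exactly at the diabatic crossing,
which is clearly the intended construction. The harmonic frequencies are
ω_i = √(2 k_ii / m).

## Monte Carlo moves

One sweep attempts, in order:

* **centre-of-mass (CoM)**: all beads of one random atom translated by a
  vector uniform in [−δ, δ)^d. The spring action is exactly unchanged;
  acceptance uses the potential + pseudopotential change. δ is tuned
  toward a 40–60 % acceptance window during burn-in only, then frozen so
  the production chain satisfies detailed balance.
* **staging**: the interior of a segment of α beads of one atom is
  redrawn from the exact free-particle Gaussian bridge (Lévy
  construction), so the kinetic action is sampled exactly and only the
  potential change enters acceptance.
* **propagation of excitation (PoE)**, coupled models only: with equal
  probability either (a) the unlike-neighbour count ξ is redrawn
  uniformly from its allowed set (even values up to 2⌊P/2⌋ for two
  states) together with a uniformly random wall placement — each pattern
  in class ξ has proposal probability 1/(2 C(P,ξ)), so acceptance carries
  the Hastings factor C(P,ξ_new)/C(P,ξ_old) — or (b) one domain wall is
  shifted by one bead at fixed ξ (symmetric).
* **label heat bath** (every sweep by default, coupled models): all P
  labels are redrawn from their exact conditional distribution given the
  positions by forward filtering / backward sampling around the necklace.
  Always accepted. This move is essential in practice: blind PoE pattern
  proposals only accept when every proposed wall happens to sit where the
  path crosses the coupling region, and without an effective label move
  the chain cannot leave ξ = 0.
* **global excitation** (every 5th sweep by default): in the adiabatic
  limit, all beads move together to one new surface drawn uniformly from
  the others. For coupled models with mixed patterns this literal move is
  *irreversible* (there is no reverse proposal from a uniform pattern back
  to a mixed one) and measurably biases the chain; the coupled kernel
  instead flips every bead's label (an involution, exactly symmetric,
  identical to the surface flip on uniform patterns), and the pure-Python
  chain attempts the move only from uniform patterns.

The readable pure-Python chain (`napimc.moves.run_chain`) is the
reference implementation, used at desk scale and validated against
exhaustive enumeration and quadrature; numba kernels
(`napimc.kernels`) implement the identical moves with cached per-bead
energies, eigenvectors and overlaps for the 10^6–10^7-sweep production
runs, and are cross-checked against the same oracles.

## Estimators

Position observables are bead averages, ⟨O⟩ = ⟨(1/P) Σ_k O_{i_k}(R^k)⟩.
The total energy is a kinetic estimator plus the bead-averaged surface
energy. Two kinetic forms are provided:

* thermodynamic: T_t = N d P/(2β) − Σ_{I,k} m_I P/(2β²) |ΔR|²,
* centroid-virial: T_v = N d/(2β) + (1/2P) Σ_{I,k} (R_I^k − R̄_I)·∇_I E_{i_k},

with R̄_I the bead centroid of atom I. For uncoupled systems both have
the same mean and the virial form has far lower variance (used for all
diatomic production runs). Two subtleties, both verified against the
transfer matrix:

* the overlap factors carry no explicit β dependence, so the
  pseudopotential contributes no extra term to the energy estimator;
* the virial form ignores the geometry dependence of the overlap factors
  and is therefore *biased for coupled models*; coupled-model energies
  use the thermodynamic estimator.

Standard errors use Flyvbjerg–Petersen blocking (conservative plateau =
maximum over block levels); sign-reweighted means use jackknife over
blocks of the (A·sgn, sgn) pair.

## Heat capacity

c_V is the temperature derivative of the sampled energy curve E(T).
Plain central differences amplify Monte Carlo noise, so the derivative u
is obtained by total-variation-regularized differentiation: minimize
‖A u − (E − E_1)‖² + λ Σ|(D u)_i| with A the cumulative-trapezoid
antidifferentiation and D first-order forward differences, solved by
lagged-diffusivity IRLS (ε-smoothed absolute value, ε = 1e-8 of the data
scale; ≤100 iterations, tolerance 1e-10). λ defaults to the discrepancy
principle: bisected until the fidelity residual matches the known
per-point blocking errors. c_p = c_V + R (Mayer's relation, molar scale);
uncertainties by Gaussian resampling of the per-point energies and
re-solving. At λ = 0 the method returns the trapezoid-consistent
derivative, whose midpoint averages equal the plain finite differences
exactly.

**Bead policy on temperature grids.** At fixed P the primitive-action
energy deficit is strongly temperature dependent; for H2 at 300 K with
P = 20 it would add ≈ +18 J mol⁻¹ K⁻¹ of spurious heat capacity to
dE/dT. Scans therefore keep the imaginary-time step (nearly) constant,
P(T) = round(P_ref T_ref / T), and the shipped H2 scan uses temperatures
commensurate with that step (T_i = P_ref T_ref / P_i, P_i = 24…17,
i.e. 250–353 K anchored at P = 20, 300 K) so that P is exactly integer
and the residual Trotter deficit is a smooth, nearly constant function
of T that the derivative does not pick up.

## Reference solvers (the oracles)

* Two-state model: sinc-DVR (Colbert–Miller) diagonalization of the
  two-component 1D Hamiltonian on [2, 16] bohr (600 points by default,
  convergence checked by refinement: Boltzmann-weighted mean level shift
  < 1e-8 Ha under grid doubling). Variants: full diabatic, lowest adiabat
  only, and both adiabats uncoupled.
* Morse: closed-form bound spectrum E_n = ω(n+½) − (ω²/4D)(n+½)²,
  ω = ρ√(2D/μ), cross-checked against grid diagonalization to 1e-6 eV;
  bond-length expectations from grid eigenfunctions.
* Finite-P transfer matrix: exact energy of the P-bead discretized
  two-state weight (signed overlaps), the bead-matched oracle for the
  coupled sampler.
* Brute-force quadrature: exhaustive position-grid × label-pattern sum of
  the identical discretized weight at P ≤ 3, evaluating the very same
  estimator expressions used on MC samples — the oracle-equivalence
  anchor for the whole pipeline.

### H2 reference conventions

The published analytical column is reproduced with: vibrational levels
measured from the Morse potential minimum (U(300 K) = 0.2763 eV,
ZPE-dominated), classical translation (3/2 k_B), and quantum rigid-rotor
rotation (B = 1/(2μ r_e²)) with nuclear-spin statistical weights
para:ortho = 1:3, giving c_p = 28.82 J mol⁻¹ K⁻¹. Equal rotational
weights or classical rotation give 29.1 instead; the spin-weighted
quantum rotor is the documented default, switches are exposed.

The PIMC simulation treats the nuclei as distinguishable (no nuclear-spin
statistics) in full 3D, so its energy contains translation, rotation and
vibration. The tabulated molecular internal energy is
U = E_total − 3/2 k_B T (free centre-of-mass motion subtracted); at
P = 20 and 300 K the vibrational Trotter deficit (−0.033 eV, exact
transfer-matrix value) and the rotational content (+0.023 eV) nearly
cancel, which is why the simulated U ≈ 0.267 eV sits close to the
vibrational-only reference 0.276 eV. The simulated c_p ≈ 29.9 contains
equal-weight quantum rotation (≈ R at 300 K) rather than the
spin-weighted 0.966 R of equilibrium hydrogen — a physical difference
between distinguishable-nuclei PIMC and equilibrium-H2 statistics, not a
numerical artifact.

## C2

Both the X¹Σg⁺ ground state and the a³Πu state are thermally relevant
(separation 716 cm⁻¹ ≈ 1030 K). The fitted Morse parameters of the
original surfaces are not published; the shipped C2 surfaces are built
from standard spectroscopic constants (X: ω_e = 1855 cm⁻¹,
r_e = 1.2425 Å; a: ω_e = 1641 cm⁻¹, r_e = 1.3119 Å; common dissociation
asymptote, X-state well depth 6.33 eV) with the minima separation fixed
at the experimental 716 cm⁻¹. Electronic degeneracies are not included
(labels are surface indices). The two-state c_p comparison is therefore
qualitative by construction: what is asserted is the electronic
(Schottky-type) contribution — a significant two-state vs ground-only
difference in 400–1000 K that declines once the excited-state population
saturates — not any figure-read value.

## Synthetic data and scope of a green test

All test inputs are generated in-process: the benchmark model uses the
published parameter set verbatim, H2 the published Morse fit, C2 the
spectroscopic stand-in above, plus harmonic/free-particle fixtures with
closed-form expectations. Published protocols (P = 20, α = 12, move
schedules) are kept; sweep counts are reduced from 10^9 to 10^6–10^7,
with tolerances combining printed uncertainties and this run's own
3-sigma errors. A green suite establishes that the sampler targets the
discretized weight exactly (enumeration, quadrature, transfer matrix),
that estimators agree with closed forms and published values at the
stated tolerances, and that the TV pipeline recovers known derivatives —
it does not establish anything about ab initio surface quality, nor
about systems beyond 1D models and diatomics.

## Known limitations

* Primitive action only; no higher-order Trotter factorizations.
* The centroid-virial estimator is exact only for uncoupled models.
* PoE pattern proposals are kept exactly as specified but mix poorly at
  weak coupling; production coupled runs rely on the label heat bath.
* The sign problem worsens with P and with coupling strength; mean signs
  below ~0.1 would need smarter pairing/resummation than implemented.
* Identical-particle exchange is not sampled (distinguishable nuclei).
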