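# Methods

This note documents the models, numerical schemes and design choices behind
`icwflab`, in the spirit of a solver manual: what is computed, under which
assumptions, with which defaults, and what the bundled tests do and do not
demonstrate.

## Representation and units

All degrees of freedom live on uniform tensor-product real-space grids in
Hartree atomic units (lengths in bohr, energies in hartree, times in au;
1 au of time = 0.0241889 fs). Each particle ("DOF block") owns one or two
grid axes. Quadrature is the plain Riemann sum `prod(dx)`, appropriate for
bound or box-contained states that decay at the boundary; the quadrature
norm of an analytically normalized Gaussian is accurate to <1e-6 at 128
points over a few widths.

Kinetic operators are central finite differences (4th order by default) so
that conditional one-body Hamiltonians are explicit sparse matrices for
repeated small eigenproblems. The exact reference propagator instead uses
the spectral (FFT) kinetic operator inside a Strang splitting. The two
discretizations agree to O(dx^4); energy differences of order 1e-4 hartree
between finite-difference eigensolves and split-operator energies on the
default grids are this discretization difference, not a solver error, and
tests that compare the two use tolerances accordingly.

## Bundled model systems

All external fields enter in the length gauge through a per-block dipole
coefficient; vector potentials are not supported (every driven example in
this family of problems is formulated with an electric field or an
impulsive dipole kick).

* **1-D H₂** in internal coordinates (r1, r2, R): reduced masses
  mu_e = 2M/(2M+1), mu_n = M/2 with M = 1836 (config-exposed), soft-Coulomb
  electron–electron repulsion `1/sqrt(2 + (r1−r2)^2)`, electron–nuclear
  attraction `−1/sqrt(1 + (r ± R/2)^2)`, bare `1/R` internuclear repulsion
  (the R grid excludes 0). The vertical gap between the ground and second
  excited clamped-nucleus surfaces at the ground-state mean separation
  computes to 0.407 hartree on the default grids (R_mean = 1.97 a0), the
  resonant carrier frequency used by the driven example.
* **Impact ionization**: two 1-D electrons, a fixed soft-Coulomb well
  `−1/sqrt(1 + (r − 10)^2)` (target atom), soft e–e repulsion with
  softening 1. The target's first excitation is 0.395 hartree, so an
  incident packet with momentum p = 0.3 scatters elastically while p = 1.5
  ionizes. The initial state is the spin-singlet symmetrized product of the
  atomic ground state and a Gaussian packet (width parameter alpha = 0.1)
  at r = −10.
* **Shin–Metiu**: one electron and one mobile proton (M = 1836) between
  fixed ions at ±L/2, L = 19 a0. The mobile charges interact through
  erf-screened Coulomb terms `erf(|x|/Rc)/|x|` (R_f = 5 for
  electron–proton; R_l = 4 and R_r = 3.1 for the electron with the two
  fixed ions), the proton feels the bare fixed-ion repulsion. The
  orientation is chosen so the ground-state equilibrium lies at negative R.
  With these parameters the two lowest Born–Oppenheimer surfaces have an
  avoided crossing (minimum gap ~5e-3 hartree) at |R| ≈ 1.9 a0 and the
  full ground state sits at <R> = −2.58 a0 with a vertical gap of
  0.085 hartree. The published description of this parameter set quotes an
  equilibrium of −2 a0; extensive checks of alternative screening forms
  (documented in the test-time convergence scans) could not reproduce that
  value together with the known avoided-crossing location, so the canonical
  erf form is used and the computed −2.58 is reported as is.
* **Conical intersection**: a 2-D electron and a 2-D quantized proton in
  the plane of two clamped protons at (−0.4·sqrt 3, 1.2) and
  (+0.4·sqrt 3, 1.2). All Coulomb terms are softened with parameter
  a = 0.5; a steep circular wall `(|R|/R0)^b` (R0 = 1.5, b = 10) confines
  the proton. When the proton reaches the origin the three nuclei form an
  equilateral triangle and the two excited electronic sheets are degenerate
  by symmetry — the conical intersection is pinned to the origin. On a
  square grid the threefold symmetry is broken at the 1e-3 hartree level,
  which is the practical degeneracy floor of the discretized model. The
  confining-wall form is a reconstruction choice (only the parameter values
  a, b, R0 are fixed externally); all conclusions drawn from this model are
  comparisons between two solvers of the *same* Hamiltonian, so they do not
  depend on this choice.

The laser-driven proton-transfer example uses a sin²-envelope pulse with
E0 = 0.006 au and a 20 fs (826.8 au) duration; a 20 *au* reading of the
envelope window would be sub-cycle at the resonant carrier (0.085 au) and
transfers no population, so the femtosecond reading is adopted and exposed
as a config knob. The driven H₂ example uses E0 = 0.005 au, carrier
0.403 au, 20 optical cycles.

## Exact reference solvers

* **Eigenstates**: shift-invert Lanczos on the sparse finite-difference
  Hamiltonian for grids up to ~1.5e5 points (deterministic start vector,
  so runs are bitwise reproducible), imaginary-time split-operator
  relaxation with Gram–Schmidt deflation above that (or on request). The
  two agree to the kinetic-discretization difference.
* **Propagation**: Strang-split Fourier method; a time-dependent field is
  evaluated at the step midpoint. Norm is conserved to <1e-8 over the
  bundled runs; a smooth cos^(1/8) absorbing mask is available for outflow.
* **Born–Oppenheimer tables**: the clamped-nucleus electronic Hamiltonian
  is diagonalized per nuclear point (dense below 600 electronic points,
  shift-invert Lanczos above). Electronic states are given a continuous
  phase by sweeping the nuclear points outward from a reference point and
  phasing each state against its nearest processed neighbour. Around a
  conical intersection a global smooth gauge does not exist; the sweep
  places the unavoidable sign cut on the far side of the reference point,
  which is chosen at the nuclear packet centre so the cut carries little
  amplitude.
* **Conditional-slice diagnostics**: slices of exact eigenstates along one
  block, their kinetic-correlation potential eta (obtained by applying the
  complementary kinetic operators and dividing by the slice, with points
  below 1e-8 of the peak slice density masked), and the residual of the
  corresponding one-body eigenproblem. For exact eigenstates the residual
  is <1e-6; for separable models eta is constant; for correlated states it
  is not — this is the diagnostic that motivates using conditional
  *eigenstates* only as a variational basis.

## Stochastic ansatz

Conditioning points are drawn from |Psi|^2 of a reference state (exact
chain-rule inverse-CDF sampling of the joint density, or independent
per-axis marginals), continuously within grid cells, deterministically per
seed. For identical-particle pairs the ensemble can be closed under label
swap, which makes the reconstructed ground state exchange-symmetric to
better than 0.999 overlap with its swap image once the basis is converged.
Sampling happens once per run; imaginary-time convergence uses a frozen
basis. Where an exact reference density is available it is used for
sampling (importance sampling does not bias the variational solve); this
replaces the looser "initial guess density" a production calculation would
use, and is the one place the oracle feeds the stochastic solver.

Conditional eigenbases take the M lowest states of each conditional
Hamiltonian per block (banded/dense solvers in 1-D, shift-invert in 2-D),
with a deterministic phase (first significant component real positive) and
degenerate pairs ordered by <x>, then <x^2>. Basis rows are
quadrature-normalized.

## Matrix elements, pseudo-inverse, eigensolver

S, H, G factorize into per-block Gram matrices; pair interactions use a
truncated SVD of the interaction kernel (relative cutoff 5e-14), which
reduces every two-body quadrature to dense matrix products and is exact to
1e-10 against brute-force tensor contraction on small grids (asserted in
the tests at 16^2 and 16^3).

Near-singular overlaps are handled by canonical orthogonalization: S is
diagonalized, eigenvalues below `rcond` (default 1e-8) times the largest
are discarded, and all coefficient dynamics happen in the retained
subspace (equivalently, S⁺ = X X†). The effective rank is reported;
redundant configurations (e.g. duplicated sampling points) change nothing
but the rank.

The imaginary-time eigensolver propagates the coefficients with an
adaptive energy shift (the running Rayleigh quotient), renormalization
each step, step-halving whenever the energy would rise, and deflation of
converged states by projection in the orthogonalized space. The step is
initialized from a power-iteration estimate of the projected spectral
radius. Energy traces are monotone non-increasing and every converged
energy is a variational upper bound to the corresponding exact level
(asserted per model in the tests).

## Real-time propagation

* **Static basis**: RK4 on `i dC/dt = S⁺ H(t) C` with midpoint field
  values. The projected dynamics is unitary up to integrator error; the
  norm C†SC drifts <1e-8 per 1000 steps at the default steps. For
  field-free stretches (after a δ-kick) the closed-form solution through
  the projected eigenbasis is used instead of stepping — it is the exact
  solution of the same equations. A δ-kick multiplies every CWF of a
  dipole-coupled block by exp(i·kappa·coef·x), which represents the kicked
  state exactly in the kicked basis.
* **dyn mode**: per step, (a) half-step propagation of every CWF under its
  own conditional Hamiltonian — Crank–Nicolson banded solves for 1-D
  blocks, split-operator for 2-D blocks, both norm-preserving — (b) a Heun
  update of the trajectories along the Bohmian velocities of the
  reconstructed ansatz (local cubic interpolation of value and gradient;
  velocities zeroed where the reconstructed density falls below a 1e-12
  floor; trajectories clipped to the interpolation-safe interior), with
  refresh of the conditional potentials, (c) the second half-step, (d) RK4
  on `i dC/dt = S⁺ (H − G) C` with matrices rebuilt at the step endpoints
  and averaged for the internal stages. The conditional generator in G
  follows the ket index (the CWFs obey i d/dt psi^β = h^β psi^β); the
  opposite convention is available behind a switch and diverges on the
  scattering example, supporting this resolution. The field is included in
  the conditional Hamiltonians, so one-body terms — including the field —
  cancel exactly between H and G and the coefficients are driven purely by
  correlation terms.

In continuous time C†SC is conserved exactly in dyn mode (dS/dt =
−i(G − G†) cancels the equation-of-motion terms). Numerically two error
sources remain: RK4 amplitude error, which scales as (lambda·dt)^5, and
rank-truncation bleed when S is strongly singular, which is per-step and
dt-independent. With a well-conditioned basis at dt = 0.01 the measured
drift is ~2e-6 per 1000 steps; with the heavily redundant M = 1
conditional-ground bases of the proton-transfer example it is
~1e-4–1e-3 per 1000 steps and is tracked and reported rather than
suppressed.

## Mean-field baseline

The MTEF baseline samples classical nuclear phase-space points from a
Gaussian matched to the quantum position variance with minimum-uncertainty
momentum spread, starts each trajectory from the clamped electronic ground
state at its sampled geometry, propagates the electrons by split-operator
in the instantaneous mean field and the nuclei by velocity Verlet with
mean-field forces (central-difference derivatives of the clamped
potential). Its decoherence indicator uses Gaussian kernel-density
estimates (bandwidth 2·dx) of the per-surface nuclear densities carried by
the ensemble, since point trajectories have no nuclear density of their
own. A time-dependent Hartree propagation serves as the mean-field
comparison for the purely electronic scattering example.

## Observables

Expectation values and reduced densities use the same factorized algebra
as the Hamiltonian (and direct quadrature for grid states); electron
densities of two-identical-electron models integrate to 2 by convention.
Absorption spectra follow the impulsive-kick prescription: S(omega) ∝
omega · Im ∫ dt e^{i omega t} mask(t) [mu(t) − mu(0)]/kappa with a cos²
mask vanishing at the final time; the sign convention makes a kicked
harmonic oscillator's peak positive, with negative ringing below 3% of the
peak at the bundled run lengths. Peak positions, not absolute intensities,
are the tested quantities. Adiabatic populations project the full
wavefunction on the clamped-nucleus electronic states per nuclear point;
the decoherence indicator is the overlap of the nuclear probability
densities carried by two electronic surfaces, D_nm = ∫ dR |chi_n|^2
|chi_m|^2 — it vanishes when the packets separate. This definition is
deliberately isolated behind one function; it is the standard
density-overlap indicator and all conclusions drawn from it are
qualitative (rise-and-decay patterns).

## Study conditions and problem sizes

The bundled examples are deliberately desk-scale so the whole suite runs
on one CPU in tens of minutes; the scaled conditions are fixed in
`icwflab.experiments` and every knob is config-exposed:

* Born–Oppenheimer surrogate: (N_c, M) = (32, 5), 10 separations, 96²
  electronic grids — reproduces the five lowest surfaces to ~3e-4 hartree.
* δ-kick response: (512, 3) on a 72×72×56 grid over 1000 au. At this
  ensemble size the early-time response and the vibronic peak positions
  are reproduced, but the long-time dephasing of the electronic ringing is
  not (relative L2 error of order 1 over the full window); at M = 5 the
  error over 300 au drops to 7%, confirming a basis-size limitation rather
  than a defect. Converged published settings for this observable are an
  order of magnitude larger.
* Impact ionization: N_c = 64 symmetrized slices, 384² grid, t = 0.85 fs.
  Relative L2 density error 0.30 vs 0.65 for time-dependent Hartree;
  errors fall to 0.20 at doubled ensemble/refined step, consistent with
  quantitative accuracy at the published N_c = 256.
* Proton transfer: (64, 1) conditional-ground basis, 1000 au with a 20 fs
  pulse. Populations cross and the decoherence indicator rises and decays
  in agreement with the exact run; the mean-field indicator fails to
  decay.
* Conical intersection: N_c = 64 slices on a 32⁴ grid, snapshot at the
  first traversal (t = 30 au), relative L2 nuclear-density error 0.08.

What passing these tests shows: the factorized machinery is exact where it
can be checked exactly, the variational and conservation properties hold,
and the scaled stochastic solvers reproduce the physics (peak placement,
density shapes, population/decoherence patterns) that mean-field baselines
miss. What it does not show: convergence at production ensemble sizes,
behaviour for real molecular Hamiltonians (Coulomb singularities,
three-dimensional particles, fermionic antisymmetry beyond spatial
symmetrization), or performance of the dyn propagator over many
vibrational periods, where rank deficiency of the moving basis accumulates.

## Known limitations

* The non-Hermitian conditional equations (with the kinetic-correlation
  potentials) are implemented only as diagnostics on exact eigenstates,
  not as a propagator.
* Uniform grids only; one or two spatial dimensions per block.
* Antisymmetrization is handled by ensemble symmetrization of spatial
  orbitals (singlet sector), not Slater determinants.
* The dyn-mode norm drift under heavy overlap rank deficiency is reported,
  not eliminated; a rank-adaptive regularization would be the natural next
  step.
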