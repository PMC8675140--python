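# icwflab

Conditional-wave-function (ICWF) quantum dynamics on real-space grids.

`icwflab` is a research code for solving the correlated quantum dynamics of
small electron–nuclear model systems **without** Born–Oppenheimer surfaces
or nonadiabatic couplings as inputs. It implements the interacting
conditional wave function family of methods — a stochastic, multiconfigurational
sum-of-products ansatz over one-body *conditional* wave functions — together
with exact grid reference solvers and a multitrajectory Ehrenfest (MTEF)
mean-field baseline, so that every approximate result can be benchmarked
against a numerically exact calculation of the same model.

It is aimed at method developers in nonadiabatic molecular dynamics who want
a compact, fully testable implementation of:

* an **imaginary-time sta-ICWF eigensolver** for correlated ground and
  excited states (with projector deflation),
* its **real-time counterpart** (static conditional-eigenstate basis,
  time-dependent coefficients, Dirac–Frenkel projection) for δ-kick
  absorption spectra and laser-driven dynamics,
* the **dyn-ICWF propagator**, in which the conditional wave functions are
  themselves propagated under Hermitian conditional Hamiltonians while their
  conditioning points move along Bohmian velocity fields.

## The method in brief

A conditional wave function (CWF) is a one-body slice of the full many-body
wave function, `psi_i(x_i) ∝ Ψ(x_i, x̄_i^α)`, with all other degrees of
freedom clamped at a configuration-space point `x^α`. The ansatz is

```
Ψ(x) ≈ Σ_α C_α  Π_i ψ_i^α(x_i),     α = λ + N_c (ν − 1)
```

with `N_c` stochastically sampled conditioning points `x^λ` and, per point,
the `M` lowest eigenstates (ν = 1..M) of the Hermitian conditional
Hamiltonians `h_i^α = K_i + W_i^α(x_i)`. The coefficients obey

* imaginary time: `dC/dτ = −S⁺ (H − E(τ) S) C` with renormalization and
  deflation (variational eigensolver),
* real time (static basis): `i S dC/dt = H(t) C`,
* dyn mode: `i S dC/dt = (H − G) C`, where `G` collects the conditional
  one-body generators so that every pure one-body term cancels between `H`
  and `G`, while the CWFs evolve under `h_i^α(t)` and the trajectories move
  with the Bohmian velocities `v = Im[∇Ψ/Ψ]/m` of the reconstructed ansatz.

`S`, `H`, `G` factorize over degrees of freedom; pair interactions enter
through a truncated SVD of the interaction kernel, so all matrix elements are
dense matrix products. Overlaps may be numerically singular and are handled
by a Moore–Penrose pseudo-inverse with a configurable rank cutoff.

Four exactly solvable models are bundled (all in Hartree atomic units): a
1-D H₂ molecule with soft-Coulomb interactions, a 1-D electron–hydrogen
impact-ionization model, the Shin–Metiu proton-coupled electron-transfer
model, and a 2-D electron + 2-D proton model with a conical intersection
pinned to the origin by symmetry.

## Worked example

Ground and first excited state of the two-electron scattering model, exact
versus sta-ICWF with 32 symmetrized configurations and M = 3 conditional
excitations per degree of freedom:

```python
from icwflab import build_scattering_model
from icwflab.grids import Grid
from icwflab.oracle import exact_eigenstates
from icwflab.sampling import sample_configurations, symmetrize_ensemble
from icwflab.icwf import (conditional_eigenbasis, overlap_matrix,
                          hamiltonian_matrix, imag_time_solve)

model = build_scattering_model()
grid = Grid.from_specs([(-30.0, 50.0, 96), (-30.0, 50.0, 96)])
E_exact, states = exact_eigenstates(model, grid, k=2)

ens = sample_configurations(states[0], 16, seed=1, mode="joint")
ens = symmetrize_ensemble(ens, grid, (0, 1))
basis = conditional_eigenbasis(model, grid, ens, M=3)
results, info = imag_time_solve(overlap_matrix(basis),
                                hamiltonian_matrix(basis), k_states=2, seed=1)
```

which prints

```
exact ground energy : -0.730544 hartree
sta-ICWF ground     : -0.728742 hartree (N_c=32, M=3, rank 96/96)
exact first excited : -0.666884 hartree
sta-ICWF excited    : -0.666684 hartree
```

The stochastic variational energies sit ~1e-3 hartree above the exact values
from a 96-member basis, and never below them (the ansatz is variational).

Six end-to-end examples (Born–Oppenheimer surfaces of H₂, δ-kick vibronic
spectrum, laser-driven H₂, impact ionization, driven proton transfer,
conical-intersection interference) are available from the command line:

```bash
icwf-lab run bopes_h2 --outdir runs/bopes
icwf-lab oracle bopes --config config.yaml --k 5 --out bopes.csv
icwf-lab compare runs/a runs/b
```

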