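"""Interacting conditional wave function (ICWF) machinery.

The ansatz is a stochastic sum of products of one-body conditional wave
functions (CWFs), one factor per degree-of-freedom block::

    Psi(x) ~= sum_alpha C_alpha  prod_b  psi_b^alpha(x_b),
    alpha = lambda + N_c (nu - 1),  lambda = configuration, nu = excitation

The CWFs are eigenstates of Hermitian conditional one-body Hamiltonians
h_b^alpha = K_b + W_b^alpha (all other blocks clamped at the sampled
configuration x^alpha).  Three propagation modes share this module:

* imaginary time on the coefficients (variational eigensolver with
  projector deflation for excited states),
* real time on the coefficients with a static basis (Dirac-Frenkel
  projection, i S dC/dt = H(t) C),
* dyn mode: CWFs propagated under their own conditional Hamiltonians
  while the conditioning points move along Bohmian velocity fields and
  the coefficients obey i S dC/dt = (H - G) C.

Matrix elements of the overlap S, Hamiltonian H and conditional coupling
G factorize over blocks; pair interactions are evaluated through a
truncated SVD of the interaction kernel, which keeps every contraction a
dense matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import Grid, GridWavefunction, block_kinetic_matrix, interpolate_offgrid
from .models import LaserPulse, ModelSystem, field_value
from .sampling import ConfigurationEnsemble

__all__ = [
    "CWFBasis",
    "ICWFState",
    "conditional_hamiltonian",
    "conditional_eigenbasis",
    "overlap_matrix",
    "hamiltonian_matrix",
    "coupling_matrix",
    "pseudo_inverse_apply",
    "imag_time_solve",
    "prepare_sta_state",
    "apply_kick",
    "sta_real_time_step",
    "sta_evolve_field_free",
    "bohmian_velocities",
    "dyn_state_from_wavefunction",
    "dyn_state_from_sta",
    "dyn_time_step",
]


# ---------------------------------------------------------------------------
# conditional Hamiltonians and eigenbases


def _clamped_coords(model: ModelSystem, grid: Grid, config: np.ndarray):
    """Split a flat configuration vector into per-block coordinate tuples."""
    out = []
    for b in range(grid.n_blocks):
        out.append(tuple(np.atleast_1d(config[ax]) for ax in grid.block_axes[b]))
    return out


def conditional_hamiltonian(model: ModelSystem, grid: Grid, block: int,
                            config: np.ndarray, *, t: float = None,
                            pulse: LaserPulse = None, order: int = 4) -> sp.csr_matrix:
    """Hermitian one-body Hamiltonian h_b = K_b + W_b(x_b) (+ field) with
    all other blocks clamped at ``config`` (flat coordinate vector)."""
    clamped = _clamped_coords(model, grid, np.asarray(config, float))
    W = model.conditional_potential(grid, block, clamped).ravel()
    if pulse is not None and t is not None:
        coef = model.dipole.get(model.blocks[block].label, 0.0)
        e = float(field_value(pulse, t))
        if coef and e:
            x0 = np.broadcast_arrays(*grid.block_mesh(block))[0].ravel()
            W = W + coef * e * x0
    K = block_kinetic_matrix(grid, block, model.blocks[block].mass, order)
    return (K + sp.diags(W)).tocsr()


def _phase_fix(v: np.ndarray) -> np.ndarray:
    """First significant component made real positive (deterministic)."""
    a = np.abs(v)
    j = int(np.argmax(a > 0.05 * a.max()))
    ph = v[j] / a[j]
    return v / ph


def _lowest_eigvecs(h, M: int, w: float, xmean_op=None):
    """M lowest eigenvectors of a sparse Hermitian one-body Hamiltonian,
    quadrature-normalized, deterministic phase and degeneracy ordering."""
    n = h.shape[0]
    if n <= 700:
        vals, vecs = sla.eigh(h.toarray(), subset_by_index=(0, M - 1))
    else:
        sigma = float(h.diagonal().min()) - 1.0
        v0 = np.full(n, n ** -0.5)
        vals, vecs = spla.eigsh(h, k=M, sigma=sigma, which="LM", v0=v0)
        idx = np.argsort(vals)
        vals, vecs = vals[idx], vecs[:, idx]
    # degenerate ties: order by <x>, then <x^2> of the first coordinate
    if xmean_op is not None and M > 1:
        for i in range(M - 1):
            if abs(vals[i + 1] - vals[i]) < 1e-9 * max(1.0, abs(vals[i])):
                mom = [(np.vdot(vecs[:, j], xmean_op * vecs[:, j]).real,
                        np.vdot(vecs[:, j], xmean_op**2 * vecs[:, j]).real)
                       for j in (i, i + 1)]
                if mom[1] < mom[0]:
                    vecs[:, [i, i + 1]] = vecs[:, [i + 1, i]]
                    vals[[i, i + 1]] = vals[[i + 1, i]]
    out = np.empty((M, n), dtype=complex)
    for m in range(M):
        v = _phase_fix(vecs[:, m])
        out[m] = v / np.sqrt(np.sum(np.abs(v) ** 2) * w)
    return vals[:M], out


class CWFBasis:
    """Per-block CWF arrays plus the conditioning configurations.

    ``Psi[b]`` has shape ``(N_c*M, n_b)`` with rows quadrature-normalized
    on block b's axes; row ``alpha = lam + N_c*nu`` stems from
    configuration ``lam`` and conditional excitation ``nu``.
    """

    def __init__(self, model: ModelSystem, grid: Grid, Psi: list[np.ndarray],
                 configs: np.ndarray, n_configs: int, M: int,
                 cond_energies=None):
        self.model = model
        self.grid = grid
        self.Psi = [np.asarray(P, dtype=complex) for P in Psi]
        self.configs = np.asarray(configs, float)
        self.n_configs = n_configs
        self.M = M
        self.cond_energies = cond_energies
        self._svd_cache = {}

    @property
    def size(self) -> int:
        return self.Psi[0].shape[0]

    def block_weight(self, b: int) -> float:
        return self.grid.block_weight(b)

    def overlaps(self) -> list[np.ndarray]:
        """Per-block Gram matrices O_b[a, b] = <psi_b^a | psi_b^b>."""
        return [np.conj(P) @ P.T * self.grid.block_weight(b)
                for b, P in enumerate(self.Psi)]

    def pair_svd(self, pair_idx: int, rtol: float = 5e-14):
        """Truncated SVD (u * s, v) of a pair-interaction kernel."""
        if pair_idx not in self._svd_cache:
            kern = self.model.pair_kernel(self.grid, self.model.pairs[pair_idx])
            u, s, vt = np.linalg.svd(kern, full_matrices=False)
            keep = s > rtol * s[0]
            self._svd_cache[pair_idx] = (u[:, keep] * s[keep], vt[keep].T)
        return self._svd_cache[pair_idx]

    def kinetic_matrices(self, order: int = 4) -> list[sp.csr_matrix]:
        return [block_kinetic_matrix(self.grid, b, blk.mass, order)
                for b, blk in enumerate(self.model.blocks)]

    def copy(self) -> "CWFBasis":
        nb = CWFBasis(self.model, self.grid, [P.copy() for P in self.Psi],
                      self.configs.copy(), self.n_configs, self.M,
                      self.cond_energies)
        nb._svd_cache = self._svd_cache  # kernels are static
        return nb

    def reconstruct(self, C: np.ndarray) -> GridWavefunction:
        """Assemble the full-grid wavefunction sum_a C_a prod_b psi_b^a."""
        grid = self.grid
        psi = np.zeros(grid.shape, dtype=complex)
        for a in range(self.size):
            term = np.asarray(C[a])
            factor = None
            for b in range(grid.n_blocks):
                f = self.Psi[b][a].reshape(grid.block_shape(b))
                factor = f if factor is None else np.multiply.outer(factor, f)
            psi += term * factor
        return GridWavefunction(grid, psi)


def conditional_eigenbasis(model: ModelSystem, grid: Grid,
                           ensemble: ConfigurationEnsemble, M: int,
                           *, order: int = 4, pulse: LaserPulse = None,
                           t: float = None) -> CWFBasis:
    """Lowest-M conditional eigenstates per block and configuration."""
    if M < 1:
        raise ValueError("M >= 1 required")
    Nc = ensemble.n_configs
    Psi, energies = [], []
    for b in range(grid.n_blocks):
        n_b = grid.block_size(b)
        P = np.empty((Nc * M, n_b), dtype=complex)
        E = np.empty((Nc, M))
        x0 = np.broadcast_arrays(*grid.block_mesh(b))[0].ravel()
        for lam in range(Nc):
            h = conditional_hamiltonian(model, grid, b, ensemble.configs[lam],
                                        t=t, pulse=pulse, order=order)
            vals, vecs = _lowest_eigvecs(h, M, grid.block_weight(b), xmean_op=x0)
            E[lam] = vals
            for nu in range(M):
                P[lam + Nc * nu] = vecs[nu]
        Psi.append(P)
        energies.append(E)
    # trajectories: one per ansatz term, the sampled configuration repeated
    # across excitations
    configs = np.tile(ensemble.configs, (M, 1))
    return CWFBasis(model, grid, Psi, configs, Nc, M, cond_energies=energies)


# ---------------------------------------------------------------------------
# matrix elements


def _prod_except(mats: list[np.ndarray]):
    """All-block product and the leave-one-out products of Gram matrices."""
    n = mats[0].shape[0]
    full = np.ones((n, n), dtype=complex)
    for m in mats:
        full = full * m
    outs = []
    for b in range(len(mats)):
        o = np.ones((n, n), dtype=complex)
        for j, m in enumerate(mats):
            if j != b:
                o = o * m
        outs.append(o)
    return full, outs


def overlap_matrix(basis: CWFBasis) -> np.ndarray:
    """S_ab = prod_b <psi_b^a|psi_b^b>; Hermitian, unit diagonal."""
    S, _ = _prod_except(basis.overlaps())
    return 0.5 * (S + S.conj().T)


def _onebody_matrix(basis: CWFBasis, b: int, Hpsi: np.ndarray) -> np.ndarray:
    """<psi_b^a| A |psi_b^b> given A already applied columnwise (n_b, size)."""
    return np.conj(basis.Psi[b]) @ Hpsi * basis.grid.block_weight(b)


def _pair_matrix(basis: CWFBasis, pair_idx: int) -> np.ndarray:
    """<psi_i^a psi_j^a | W_ij | psi_i^b psi_j^b> via the kernel SVD."""
    p = basis.model.pairs[pair_idx]
    i = basis.model.block_index(p.block_i)
    j = basis.model.block_index(p.block_j)
    U, V = basis.pair_svd(pair_idx)
    Pi, Pj = basis.Psi[i], basis.Psi[j]
    wi, wj = basis.grid.block_weight(i), basis.grid.block_weight(j)
    out = np.zeros((basis.size, basis.size), dtype=complex)
    for kcol in range(U.shape[1]):
        A = (np.conj(Pi) * U[:, kcol]) @ Pi.T * wi
        B = (np.conj(Pj) * V[:, kcol]) @ Pj.T * wj
        out += A * B
    return out


def hamiltonian_matrix(basis: CWFBasis, *, t: float = None,
                       pulse: LaserPulse = None, order: int = 4,
                       kinetics=None) -> np.ndarray:
    """Full-Hamiltonian matrix in the CWF product basis.

    One-body terms are kinetic + one-body potentials (+ length-gauge field
    at time ``t``); pair terms use 2-D quadrature through the kernel SVD.
    """
    model, grid = basis.model, basis.grid
    O = basis.overlaps()
    _, O_except = _prod_except(O)
    kin = kinetics if kinetics is not None else basis.kinetic_matrices(order)
    e_field = float(field_value(pulse, t)) if (pulse is not None and t is not None) else 0.0
    H = np.zeros((basis.size, basis.size), dtype=complex)
    for b, blk in enumerate(model.blocks):
        v = np.zeros(grid.block_size(b))
        if blk.label in model.one_body:
            v = v + model.one_body[blk.label](grid.block_mesh(b)).ravel()
        if e_field and model.dipole.get(blk.label, 0.0):
            x0 = np.broadcast_arrays(*grid.block_mesh(b))[0].ravel()
            v = v + e_field * model.dipole[blk.label] * x0
        Hpsi = kin[b] @ basis.Psi[b].T + v[:, None] * basis.Psi[b].T
        H += O_except[b] * _onebody_matrix(basis, b, Hpsi)
    for pi, p in enumerate(model.pairs):
        i = model.block_index(p.block_i)
        j = model.block_index(p.block_j)
        o = np.ones((basis.size, basis.size), dtype=complex)
        for bb, m in enumerate(O):
            if bb not in (i, j):
                o = o * m
        H += o * _pair_matrix(basis, pi)
    return 0.5 * (H + H.conj().T)


def operator_matrix(basis: CWFBasis, terms) -> np.ndarray:
    """Matrix of a one-body/pair operator descriptor (see observables)."""
    model, grid = basis.model, basis.grid
    O = basis.overlaps()
    full, O_except = _prod_except(O)
    out = np.zeros((basis.size, basis.size), dtype=complex)
    for term in terms:
        if term[0] == "const":
            out += term[1] * full
        elif term[0] == "onebody":
            _, lbl, fn = term
            b = model.block_index(lbl)
            v = fn(grid.block_mesh(b)).ravel()
            out += O_except[b] * _onebody_matrix(basis, b, v[:, None] * basis.Psi[b].T)
        elif term[0] == "pair":
            _, li, lj, fn = term
            i, j = model.block_index(li), model.block_index(lj)
            ci = tuple(c.reshape(-1, 1) for c in np.broadcast_arrays(*grid.block_mesh(i)))
            cj = tuple(c.reshape(1, -1) for c in np.broadcast_arrays(*grid.block_mesh(j)))
            kern = fn(ci, cj)
            u, s, vt = np.linalg.svd(kern, full_matrices=False)
            keep = s > 5e-14 * s[0]
            U, V = u[:, keep] * s[keep], vt[keep].T
            o = np.ones((basis.size, basis.size), dtype=complex)
            for bb, m in enumerate(O):
                if bb not in (i, j):
                    o = o * m
            acc = np.zeros_like(out)
            wi, wj = grid.block_weight(i), grid.block_weight(j)
            for kcol in range(U.shape[1]):
                A = (np.conj(basis.Psi[i]) * U[:, kcol]) @ basis.Psi[i].T * wi
                B = (np.conj(basis.Psi[j]) * V[:, kcol]) @ basis.Psi[j].T * wj
                acc += A * B
            out += o * acc
        else:
            raise ValueError(f"unknown operator term {term[0]!r}")
    return out


def _conditional_potentials(basis: CWFBasis, trajectories: np.ndarray, *,
                            t: float = None, pulse: LaserPulse = None) -> list[np.ndarray]:
    """W_b^alpha stacked columnwise: one (n_b, size) array per block."""
    model, grid = basis.model, basis.grid
    e_field = float(field_value(pulse, t)) if (pulse is not None and t is not None) else 0.0
    out = []
    for b, blk in enumerate(model.blocks):
        Wcols = np.empty((grid.block_size(b), basis.size))
        dip = model.dipole.get(blk.label, 0.0)
        x0 = np.broadcast_arrays(*grid.block_mesh(b))[0].ravel() if (dip and e_field) else None
        for a in range(basis.size):
            clamped = _clamped_coords(model, grid, trajectories[a])
            W = model.conditional_potential(grid, b, clamped).ravel()
            if x0 is not None:
                W = W + e_field * dip * x0
            Wcols[:, a] = W
        out.append(Wcols)
    return out


def coupling_matrix(basis: CWFBasis, trajectories: np.ndarray, *,
                    t: float = None, pulse: LaserPulse = None,
                    order: int = 4, kinetics=None, Wcols=None,
                    generator_index: str = "ket") -> np.ndarray:
    """G_ab = sum_b (prod_{j!=b} O_j[ab]) <psi_b^a| h_b^beta |psi_b^b>.

    The conditional generator follows the ket index by default (the CWFs
    obey i d/dt psi^beta = h^beta psi^beta); ``generator_index='bra'``
    flips the convention for comparison.  G is not Hermitian in general.
    """
    model, grid = basis.model, basis.grid
    O = basis.overlaps()
    _, O_except = _prod_except(O)
    kin = kinetics if kinetics is not None else basis.kinetic_matrices(order)
    if Wcols is None:
        Wcols = _conditional_potentials(basis, trajectories, t=t, pulse=pulse)
    G = np.zeros((basis.size, basis.size), dtype=complex)
    for b in range(grid.n_blocks):
        Hpsi = kin[b] @ basis.Psi[b].T + Wcols[b] * basis.Psi[b].T
        M = _onebody_matrix(basis, b, Hpsi)
        if generator_index == "bra":
            M = M.conj().T
        G += O_except[b] * M
    return G


# ---------------------------------------------------------------------------
# pseudo-inverse of the overlap


def pseudo_inverse_apply(S: np.ndarray, vec: np.ndarray, rcond: float = 1e-8):
    """Moore-Penrose application S^+ vec for a Hermitian PSD overlap.

    Returns ``(result, effective_rank)``.
    """
    vals, U = sla.eigh(0.5 * (S + S.conj().T))
    keep = vals > rcond * vals.max()
    Uk = U[:, keep]
    return Uk @ ((Uk.conj().T @ vec) / vals[keep]), int(keep.sum())


class _Metric:
    """Canonical orthogonalization X of a (possibly singular) overlap:
    X^dag S X = I on the retained subspace; S^+ = X X^dag."""

    def __init__(self, S: np.ndarray, rcond: float = 1e-8, warn: bool = True):
        vals, U = sla.eigh(0.5 * (S + S.conj().T))
        keep = vals > rcond * max(vals.max(), 0.0)
        self.rank = int(keep.sum())
        if warn and self.rank < S.shape[0]:
            warnings.warn(f"overlap rank deficient: {self.rank}/{S.shape[0]}",
                          stacklevel=2)
        self.X = U[:, keep] / np.sqrt(vals[keep])

    def pinv_apply(self, v: np.ndarray) -> np.ndarray:
        return self.X @ (self.X.conj().T @ v)

    def project(self, H: np.ndarray) -> np.ndarray:
        Ht = self.X.conj().T @ H @ self.X
        return 0.5 * (Ht + Ht.conj().T)


# ---------------------------------------------------------------------------
# imaginary-time eigensolver (sta-ICWF)


def imag_time_solve(S: np.ndarray, H: np.ndarray, k_states: int = 1, *,
                    dtau: float = None, tol: float = 1e-11,
                    max_steps: int = 200_000, rcond: float = 1e-8,
                    seed: int = 0):
    """Lowest ``k_states`` of the projected problem H C = E S C by
    imaginary-time propagation of the coefficients with renormalization,
    an adaptive energy shift, and projector deflation of converged states.

    Returns ``(results, info)`` with ``results = [(E_0, C_0), ...]``
    (ascending energies, C normalized to C^dag S C = 1) and ``info``
    containing the effective overlap rank and iteration counts.
    """
    metric = _Metric(S, rcond)
    Ht = metric.project(H)
    r = Ht.shape[0]
    k_states = min(k_states, r)
    rng = np.random.default_rng(seed)
    # stable step from a spectral-radius estimate (a few power iterations)
    v = rng.standard_normal(r) + 1j * rng.standard_normal(r)
    for _ in range(20):
        v = Ht @ v
        v /= np.linalg.norm(v)
    lam_max = float(np.real(np.vdot(v, Ht @ v)))
    lam_min = float(np.min(np.diag(Ht).real))
    if dtau is None:
        dtau = 1.5 / max(lam_max - lam_min, 1e-6)
    results_t, iters, traces = [], [], []
    for g in range(k_states):
        c = rng.standard_normal(r) + 1j * rng.standard_normal(r)
        step = dtau
        for q in results_t:
            c -= q * np.vdot(q, c)
        c /= np.linalg.norm(c)
        e_prev = np.real(np.vdot(c, Ht @ c))
        trace = [e_prev]
        check = 25
        it = 0
        while it < max_steps:
            c_prev = c
            for _ in range(check):
                hc = Ht @ c
                e = np.real(np.vdot(c, hc))
                c = c - step * (hc - e * c)
                for q in results_t:
                    c -= q * np.vdot(q, c)
                c /= np.linalg.norm(c)
                it += 1
            e = np.real(np.vdot(c, Ht @ c))
            if e > e_prev + 1e-13 * max(1.0, abs(e_prev)):
                c = c_prev  # reject the stride and halve the step
                step *= 0.5
                if step < 1e-6 * dtau:
                    break
                continue
            trace.append(e)
            if abs(e - e_prev) < tol * check:
                break
            e_prev = e
        results_t.append(c)
        iters.append(it)
        traces.append(np.array(trace))
    results = []
    for c in results_t:
        C = metric.X @ c
        e = np.real(np.conj(C) @ H @ C) / np.real(np.conj(C) @ S @ C)
        results.append((float(e), C))
    results.sort(key=lambda t: t[0])
    info = {"rank": metric.rank, "iterations": iters, "dtau": dtau,
            "energy_traces": traces}
    return results, info


# ---------------------------------------------------------------------------
# ICWF state (shared by sta and dyn modes)


@dataclass
class ICWFState:
    basis: CWFBasis
    C: np.ndarray
    mode: str = "sta"  # "sta" | "dyn"
    time: float = 0.0
    trajectories: np.ndarray | None = None
    cache: dict = field(default_factory=dict)
    rcond: float = 1e-8

    @property
    def model(self) -> ModelSystem:
        return self.basis.model

    @property
    def grid(self) -> Grid:
        return self.basis.grid

    def norm2(self) -> float:
        S = self.cache.get("S")
        if S is None or self.mode == "dyn":
            S = overlap_matrix(self.basis)
        return float(np.real(np.conj(self.C) @ S @ self.C))

    def expectation(self, terms) -> float:
        Omat = operator_matrix(self.basis, terms)
        S = overlap_matrix(self.basis) if "S" not in self.cache or self.mode == "dyn" \
            else self.cache["S"]
        num = np.conj(self.C) @ Omat @ self.C
        den = np.conj(self.C) @ S @ self.C
        return float(np.real(num / den))

    def reduced_density(self, label: str, norm: float = 1.0) -> np.ndarray:
        b = self.model.block_index(label)
        O = self.basis.overlaps()
        T = np.multiply.outer(np.conj(self.C), self.C)
        for j, m in enumerate(O):
            if j != b:
                T = T * m
        P = self.basis.Psi[b]
        rho = np.einsum("ax,ax->x", np.conj(P), T @ P).real
        rho = rho.reshape(self.grid.block_shape(b))
        w = self.grid.block_weight(b)
        return rho * (norm / (rho.sum() * w))

    def reconstruct(self) -> GridWavefunction:
        return self.basis.reconstruct(self.C)


# ---------------------------------------------------------------------------
# sta mode: static basis, time-dependent coefficients


def prepare_sta_state(basis: CWFBasis, C: np.ndarray, *, rcond: float = 1e-8,
                      order: int = 4) -> ICWFState:
    """Cache S, field-free H, the dipole matrix and the overlap metric."""
    from .observables import dipole_operator

    state = ICWFState(basis=basis, C=np.asarray(C, complex).copy(), mode="sta",
                      rcond=rcond)
    kin = basis.kinetic_matrices(order)
    state.cache["kinetics"] = kin
    state.cache["S"] = overlap_matrix(basis)
    state.cache["H0"] = hamiltonian_matrix(basis, kinetics=kin)
    dip = dipole_operator(basis.model)
    state.cache["D"] = operator_matrix(basis, dip) if dip else None
    state.cache["metric"] = _Metric(state.cache["S"], rcond)
    return state


def apply_kick(state: ICWFState, kappa: float) -> ICWFState:
    """Impulsive dipole kick: multiply every CWF of each dipole-coupled
    block by exp(i kappa coef x) and refresh the cached Hamiltonian."""
    basis = state.basis.copy()
    model, grid = basis.model, basis.grid
    for b, blk in enumerate(model.blocks):
        coef = model.dipole.get(blk.label, 0.0)
        if coef:
            x0 = np.broadcast_arrays(*grid.block_mesh(b))[0].ravel()
            basis.Psi[b] = basis.Psi[b] * np.exp(1j * kappa * coef * x0)
    return prepare_sta_state(basis, state.C, rcond=state.rcond)


def _sta_rhs(state: ICWFState, C: np.ndarray, t: float, pulse: LaserPulse | None):
    H = state.cache["H0"]
    if pulse is not None and state.cache["D"] is not None:
        e = float(field_value(pulse, max(t, 0.0)))
        if e:
            H = H + e * state.cache["D"]
    return -1j * state.cache["metric"].pinv_apply(H @ C)


def sta_real_time_step(state: ICWFState, dt: float, *, pulse: LaserPulse = None) -> ICWFState:
    """One RK4 step of i dC/dt = S^+ H(t) C (static basis)."""
    t, C = state.time, state.C
    k1 = _sta_rhs(state, C, t, pulse)
    k2 = _sta_rhs(state, C + 0.5 * dt * k1, t + 0.5 * dt, pulse)
    k3 = _sta_rhs(state, C + 0.5 * dt * k2, t + 0.5 * dt, pulse)
    k4 = _sta_rhs(state, C + dt * k3, t + dt, pulse)
    state.C = C + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    state.time = t + dt
    return state


def sta_evolve_field_free(state: ICWFState, times: np.ndarray) -> list[np.ndarray]:
    """Exact field-free coefficient evolution via the projected eigenbasis
    (the closed-form solution of the Dirac-Frenkel equations when H is
    time independent).  Returns C at each requested time."""
    metric = state.cache["metric"]
    Ht = metric.project(state.cache["H0"])
    vals, W = sla.eigh(Ht)
    c0 = W.conj().T @ (metric.X.conj().T @ (state.cache["S"] @ state.C))
    out = []
    for t in np.atleast_1d(times):
        ct = W @ (np.exp(-1j * vals * (t - state.time)) * c0)
        out.append(metric.X @ ct)
    return out


# ---------------------------------------------------------------------------
# dyn mode: time-dependent CWFs guided by Bohmian trajectories


def bohmian_velocities(basis: CWFBasis, C: np.ndarray, trajectories: np.ndarray,
                       *, floor: float = 1e-12):
    """Conditional (Bohmian) velocities v = Im[grad Psi / Psi]/m at each
    trajectory, from the reconstructed ansatz via off-grid interpolation.

    Velocities are zeroed where |Psi|^2 falls below ``floor`` times the
    ensemble maximum (density-floor regularization).
    """
    model, grid = basis.model, basis.grid
    n = basis.size
    vals_b, grads_b = [], []
    for b in range(grid.n_blocks):
        axes = [grid.axes[i] for i in grid.block_axes[b]]
        pts = trajectories[:, list(grid.block_axes[b])]
        Pb = basis.Psi[b].reshape((n,) + grid.block_shape(b))
        v, g = interpolate_offgrid(Pb, axes, pts)
        vals_b.append(v)        # (n_basis, n_traj)
        grads_b.append(g)       # (n_basis, n_traj, ndim_b)
    prod_all = np.ones((n, len(trajectories)), dtype=complex)
    for v in vals_b:
        prod_all = prod_all * v
    psi_at = C @ prod_all
    dens = np.abs(psi_at) ** 2
    cutoff = floor * max(dens.max(), 1e-300)
    vel = np.zeros_like(trajectories)
    for b in range(grid.n_blocks):
        others = np.ones_like(prod_all)
        for bb, v in enumerate(vals_b):
            if bb != b:
                others = others * v
        mass = model.blocks[b].mass
        for d, ax in enumerate(grid.block_axes[b]):
            grad_at = C @ (grads_b[b][:, :, d] * others)
            with np.errstate(divide="ignore", invalid="ignore"):
                v_bd = np.imag(grad_at / psi_at) / mass
            v_bd = np.where(dens > cutoff, v_bd, 0.0)
            vel[:, ax] = np.nan_to_num(v_bd)
    return vel, psi_at


def _clip_trajectories(grid: Grid, X: np.ndarray) -> np.ndarray:
    """Keep trajectories inside the cubic-interpolation stencil range."""
    out = X.copy()
    for ax in range(grid.ndim):
        a = grid.axes[ax]
        dx = a[1] - a[0]
        out[:, ax] = np.clip(out[:, ax], a[0] + 1.01 * dx, a[-1] - 1.01 * dx)
    return out


def dyn_state_from_wavefunction(model: ModelSystem, grid: Grid,
                                psi: GridWavefunction,
                                ensemble: ConfigurationEnsemble, *,
                                rcond: float = 1e-8) -> ICWFState:
    """Initialize dyn-ICWF from a full wavefunction: the CWFs are its
    normalized conditional slices at the sampled configurations and the
    coefficients are the least-squares fit C = S^+ b, b_a = <prod psi^a|Psi>.

    Supports two-block models (every bundled dyn example)."""
    if grid.n_blocks != 2:
        raise NotImplementedError("slice initialization implemented for 2 blocks")
    n1 = grid.block_size(0)
    psi_mat = psi.psi.reshape(n1, -1)
    Nc = ensemble.n_configs
    P0 = np.empty((Nc, n1), dtype=complex)
    P1 = np.empty((Nc, psi_mat.shape[1]), dtype=complex)
    ax0, ax1 = grid.block_axes[0], grid.block_axes[1]
    for a in range(Nc):
        cfg = ensemble.configs[a]
        i1 = np.ravel_multi_index(
            tuple(int(np.argmin(np.abs(grid.axes[ax] - cfg[ax]))) for ax in ax1),
            grid.block_shape(1))
        i0 = np.ravel_multi_index(
            tuple(int(np.argmin(np.abs(grid.axes[ax] - cfg[ax]))) for ax in ax0),
            grid.block_shape(0))
        s0 = psi_mat[:, i1].copy()
        s1 = psi_mat[i0, :].copy()
        n0 = np.sqrt(np.sum(np.abs(s0) ** 2) * grid.block_weight(0))
        n1q = np.sqrt(np.sum(np.abs(s1) ** 2) * grid.block_weight(1))
        if n0 < 1e-14 or n1q < 1e-14:
            raise ValueError(f"degenerate slice at configuration {a}")
        P0[a] = s0 / n0
        P1[a] = s1 / n1q
    basis = CWFBasis(model, grid, [P0, P1], ensemble.configs.copy(), Nc, 1)
    w = grid.weight
    b_vec = np.array([np.conj(P0[a]) @ psi_mat @ np.conj(P1[a]) * w
                      for a in range(Nc)])
    S = overlap_matrix(basis)
    C, rank = pseudo_inverse_apply(S, b_vec, rcond)
    state = ICWFState(basis=basis, C=C, mode="dyn", time=0.0,
                      trajectories=_clip_trajectories(grid, ensemble.configs.copy()),
                      rcond=rcond)
    state.cache["rank0"] = rank
    return state


def dyn_state_from_sta(sta: ICWFState) -> ICWFState:
    """Hand an imaginary-time-converged sta state to the dyn propagator."""
    basis = sta.basis.copy()
    return ICWFState(basis=basis, C=sta.C.copy(), mode="dyn", time=sta.time,
                     trajectories=_clip_trajectories(basis.grid, basis.configs.copy()),
                     rcond=sta.rcond)


def _cwf_halfstep(basis: CWFBasis, Wcols: list[np.ndarray], dt_half: float,
                  kinetics, cn_bands: dict):
    """Propagate every CWF by dt_half under its own conditional Hamiltonian:
    Crank-Nicolson (banded) for 1-D blocks, split-operator for 2-D blocks.
    Both preserve the per-CWF norm exactly for Hermitian h."""
    grid = basis.grid
    for b in range(grid.n_blocks):
        nd = len(grid.block_axes[b])
        if nd == 1:
            ab = cn_bands[b]  # banded form of K_b (upper+lower), bandwidth 2
            n = grid.block_size(b)
            newP = np.empty_like(basis.Psi[b])
            for a in range(basis.size):
                h_diag = Wcols[b][:, a]
                A = ab.copy().astype(complex) * (0.5j * dt_half)
                A[2] += 0.5j * dt_half * h_diag + 1.0
                rhs = basis.Psi[b][a] - (0.5j * dt_half) * (
                    _banded_matvec(ab, basis.Psi[b][a]) + h_diag * basis.Psi[b][a])
                newP[a] = sla.solve_banded((2, 2), A, rhs)
            basis.Psi[b] = newP
        else:
            shape = grid.block_shape(b)
            mass = basis.model.blocks[b].mass
            ks = np.zeros(shape)
            for d, ax in enumerate(grid.block_axes[b]):
                k = 2 * np.pi * np.fft.fftfreq(shape[d], grid.dx(ax))
                sh = [1] * nd
                sh[d] = len(k)
                ks = ks + k.reshape(sh) ** 2 / (2 * mass)
            expK = np.exp(-1j * dt_half * ks)
            P = basis.Psi[b].reshape((basis.size,) + shape)
            expV = np.exp(-0.5j * dt_half * Wcols[b].T.reshape((basis.size,) + shape))
            P = P * expV
            P = np.fft.ifftn(expK[None] * np.fft.fftn(P, axes=(1, 2)), axes=(1, 2))
            P = P * expV
            basis.Psi[b] = P.reshape(basis.size, -1)


def _banded_matvec(ab: np.ndarray, x: np.ndarray) -> np.ndarray:
    """y = A x for a (2,2)-banded matrix in solve_banded upper storage."""
    n = len(x)
    y = ab[2] * x
    y[:-1] += ab[1][1:] * x[1:]
    y[:-2] += ab[0][2:] * x[2:]
    y[1:] += ab[3][:-1] * x[:-1]
    y[2:] += ab[4][:-2] * x[:-2]
    return y


def _kinetic_banded(basis: CWFBasis, b: int, order: int = 4) -> np.ndarray:
    K = block_kinetic_matrix(basis.grid, b, basis.model.blocks[b].mass, order)
    n = K.shape[0]
    ab = np.zeros((5, n))
    Kd = K.todia()
    for off, data in zip(Kd.offsets, Kd.data):
        ab[2 - off] = data
    return ab


def _dyn_matrices(basis: CWFBasis, trajectories: np.ndarray, t: float,
                  pulse, kinetics, order: int = 4):
    Wcols = _conditional_potentials(basis, trajectories, t=t, pulse=pulse)
    S = overlap_matrix(basis)
    H = hamiltonian_matrix(basis, t=t, pulse=pulse, kinetics=kinetics, order=order)
    G = coupling_matrix(basis, trajectories, t=t, pulse=pulse,
                        kinetics=kinetics, Wcols=Wcols)
    return S, H, G, Wcols


def dyn_time_step(state: ICWFState, dt: float, *, pulse: LaserPulse = None,
                  floor: float = 1e-12, order: int = 4) -> ICWFState:
    """One Strang-split dyn-ICWF step.

    (a) half-step Crank-Nicolson/split-operator propagation of every CWF
    under its conditional Hamiltonian, (b) Heun update of the trajectories
    along Bohmian velocities with refresh of the conditional potentials,
    (c) second CWF half-step, (d) RK4 update of the coefficients under
    i S dC/dt = (H - G) C with matrices rebuilt at the step endpoints.
    """
    basis, grid = state.basis, state.grid
    t = state.time
    if "kinetics" not in state.cache:
        state.cache["kinetics"] = basis.kinetic_matrices(order)
        state.cache["cn_bands"] = {
            b: _kinetic_banded(basis, b, order)
            for b in range(grid.n_blocks) if len(grid.block_axes[b]) == 1}
    kin = state.cache["kinetics"]
    if "matrices" not in state.cache:
        state.cache["matrices"] = _dyn_matrices(basis, state.trajectories, t,
                                                pulse, kin, order)
    S0, H0, G0, Wcols0 = state.cache["matrices"]

    # (a) first half-step at the current conditional potentials
    _cwf_halfstep(basis, Wcols0, 0.5 * dt, kin, state.cache["cn_bands"])

    # (b) trajectory update (Heun) and potential refresh
    X = state.trajectories
    v1, _ = bohmian_velocities(basis, state.C, X, floor=floor)
    Xp = _clip_trajectories(grid, X + dt * v1)
    v2, _ = bohmian_velocities(basis, state.C, Xp, floor=floor)
    Xn = _clip_trajectories(grid, X + 0.5 * dt * (v1 + v2))
    Wcols1 = _conditional_potentials(basis, Xn, t=t + dt, pulse=pulse)

    # (c) second half-step at the refreshed potentials
    _cwf_halfstep(basis, Wcols1, 0.5 * dt, kin, state.cache["cn_bands"])

    # (d) coefficient update with endpoint/averaged matrices
    S1 = overlap_matrix(basis)
    H1 = hamiltonian_matrix(basis, t=t + dt, pulse=pulse, kinetics=kin, order=order)
    G1 = coupling_matrix(basis, Xn, t=t + dt, pulse=pulse, kinetics=kin,
                         Wcols=Wcols1)
    M0 = _Metric(S0, state.rcond, warn=False)
    M1 = _Metric(S1, state.rcond, warn=False)
    state.cache["rank"] = M1.rank

    def f0(c):
        return -1j * M0.pinv_apply((H0 - G0) @ c)

    def fm(c):
        return -0.5j * (M0.pinv_apply((H0 - G0) @ c) + M1.pinv_apply((H1 - G1) @ c))

    def f1(c):
        return -1j * M1.pinv_apply((H1 - G1) @ c)

    C = state.C
    k1 = f0(C)
    k2 = fm(C + 0.5 * dt * k1)
    k3 = fm(C + 0.5 * dt * k2)
    k4 = f1(C + dt * k3)
    state.C = C + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    state.trajectories = Xn
    state.time = t + dt
    state.cache["matrices"] = (S1, H1, G1, Wcols1)
    return state
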