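"""Exact grid reference solvers: eigenstates, split-operator propagation,
Born-Oppenheimer surfaces, and conditional-slice diagnostics.

These are the ground-truth solvers every ICWF result is benchmarked
against.  Eigenstates come from sparse finite-difference Hamiltonians
(shift-invert Lanczos) or, for large grids, from imaginary-time
split-operator propagation with deflation; real-time propagation uses the
Strang-split Fourier method with the field in the length gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import CubicSpline

from .grids import Grid, GridWavefunction, kinetic_matrix, block_kinetic_matrix
from .models import LaserPulse, ModelSystem, field_value
from .observables import ObservableSeries, dipole_operator, expectation

__all__ = [
    "assemble_hamiltonian",
    "exact_eigenstates",
    "exact_propagate",
    "BOPESTable",
    "compute_bopes",
    "ConditionalSliceDiagnostic",
    "conditional_slice",
    "kinetic_correlation_potential",
    "scattering_initial_state",
]


# ---------------------------------------------------------------------------
# sparse Hamiltonian assembly


def assemble_hamiltonian(model: ModelSystem, grid: Grid, order: int = 4) -> sp.csr_matrix:
    """Full sparse H = sum_blocks K_b + diag(W) on the tensor grid."""
    shape = grid.shape
    H = sp.diags(model.potential_on_grid(grid).ravel()).tocsr()
    for b, blk in enumerate(model.blocks):
        for ax in grid.block_axes[b]:
            T = kinetic_matrix(shape[ax], grid.dx(ax), blk.mass, order)
            left = sp.identity(int(np.prod(shape[:ax])), format="csr")
            right = sp.identity(int(np.prod(shape[ax + 1:])), format="csr")
            H = H + sp.kron(sp.kron(left, T), right, format="csr")
    return H.tocsr()


def _fix_phase(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    ph = v[i] / abs(v[i])
    return v / ph


# ---------------------------------------------------------------------------
# split-operator engine


class SplitOperator:
    """Strang-split Fourier propagator for a model on a grid."""

    def __init__(self, model: ModelSystem, grid: Grid):
        self.model = model
        self.grid = grid
        self.V = model.potential_on_grid(grid)
        self.D = model.dipole_on_grid(grid) if model.dipole else None
        ksq = np.zeros(grid.shape)
        for b, blk in enumerate(model.blocks):
            for ax in grid.block_axes[b]:
                k = 2 * np.pi * np.fft.fftfreq(grid.shape[ax], grid.dx(ax))
                shape = [1] * grid.ndim
                shape[ax] = len(k)
                ksq = ksq + (k.reshape(shape) ** 2) / (2 * blk.mass)
        self.ksq = ksq

    def kinetic_apply(self, psi: np.ndarray) -> np.ndarray:
        return np.fft.ifftn(self.ksq * np.fft.fftn(psi))

    def energy(self, psi: np.ndarray, t: float = None, pulse: LaserPulse = None) -> float:
        w = self.grid.weight
        nrm = np.sum(np.abs(psi) ** 2) * w
        ek = np.real(np.vdot(psi, self.kinetic_apply(psi))) * w
        V = self.V
        if pulse is not None and self.D is not None and t is not None:
            e = float(field_value(pulse, t))
            if e:
                V = V + e * self.D
        ev = np.real(np.vdot(psi, V * psi)) * w
        return (ek + ev) / nrm

    # -- real time ---------------------------------------------------------
    def propagate(self, psi0: np.ndarray, dt: float, n_steps: int, *,
                  pulse: LaserPulse = None, mask: np.ndarray = None,
                  t0: float = 0.0, callback=None, stride: int = 1):
        """Propagate ``n_steps`` of size ``dt``; ``callback(psi, t, step)``
        is invoked at step 0 and then every ``stride`` steps (and at the
        final step)."""
        psi = np.asarray(psi0, dtype=complex).copy()
        expK = np.exp(-1j * dt * self.ksq)
        expVh = np.exp(-0.5j * dt * self.V)
        if callback is not None:
            callback(psi, t0, 0)
        for s in range(n_steps):
            t_mid = t0 + (s + 0.5) * dt
            half = expVh
            if pulse is not None and self.D is not None:
                e = float(field_value(pulse, max(t_mid, 0.0)))
                if e:
                    half = expVh * np.exp(-0.5j * dt * e * self.D)
            psi *= half
            psi = np.fft.ifftn(expK * np.fft.fftn(psi))
            psi *= half
            if mask is not None:
                psi *= mask
            nrm2 = np.sum(np.abs(psi) ** 2) * self.grid.weight
            if not np.isfinite(nrm2) or (mask is None and nrm2 > 4.0):
                raise FloatingPointError(
                    f"norm blow-up at step {s} (|psi|^2 = {nrm2:.3g}); reduce dt")
            if callback is not None and (s + 1) % stride == 0:
                callback(psi, t0 + (s + 1) * dt, s + 1)
        return psi

    # -- imaginary time ----------------------------------------------------
    def imaginary_time(self, guess: np.ndarray, dtau: float = 0.1, *,
                       tol: float = 1e-10, max_steps: int = 20000,
                       orthogonalize_to=()):
        """Relax a guess to the lowest state orthogonal to the given ones.

        Returns (energy, psi).  Convergence on the energy change per step.
        """
        w = self.grid.weight
        psi = np.asarray(guess, dtype=complex).copy()
        expK = np.exp(-dtau * self.ksq)
        expVh = np.exp(-0.5 * dtau * self.V)

        def project(p):
            for q in orthogonalize_to:
                p -= q * (np.vdot(q, p) * w)
            return p

        psi = project(psi)
        psi /= np.sqrt(np.sum(np.abs(psi) ** 2) * w)
        e_prev = self.energy(psi)
        check = max(1, int(1.0 / dtau))
        for s in range(1, max_steps + 1):
            psi *= expVh
            psi = np.fft.ifftn(expK * np.fft.fftn(psi))
            psi *= expVh
            psi = project(psi)
            psi /= np.sqrt(np.sum(np.abs(psi) ** 2) * w)
            if s % check == 0:
                e = self.energy(psi)
                if abs(e - e_prev) < tol * check:
                    return e, psi
                e_prev = e
        return self.energy(psi), psi


# ---------------------------------------------------------------------------
# eigenstates


def exact_eigenstates(model: ModelSystem, grid: Grid, k: int = 1, *,
                      method: str = "auto", order: int = 4, guesses=None,
                      dtau: float = 0.1, tol: float = 1e-10, seed: int = 0):
    """k lowest eigenpairs of the full molecular Hamiltonian.

    ``method='sparse'`` diagonalizes the finite-difference Hamiltonian by
    shift-invert Lanczos (small grids); ``'imag'`` uses imaginary-time
    split-operator relaxation with Gram-Schmidt deflation (any grid size,
    spectral kinetic operator).  ``'auto'`` picks by grid size.

    Returns ``(energies, [GridWavefunction, ...])`` with ascending energies
    and quadrature-orthonormal states.
    """
    if k < 1:
        raise ValueError("k >= 1 required")
    if method == "auto":
        method = "sparse" if grid.size <= 150_000 else "imag"
    if method == "sparse":
        H = assemble_hamiltonian(model, grid, order)
        sigma = float(model.potential_on_grid(grid).min()) - 0.5
        v0 = np.full(H.shape[0], H.shape[0] ** -0.5)
        vals, vecs = spla.eigsh(H, k=k, sigma=sigma, which="LM", v0=v0)
        idx = np.argsort(vals)
        vals, vecs = vals[idx], vecs[:, idx]
        states = []
        for i in range(k):
            v = _fix_phase(vecs[:, i]).reshape(grid.shape) / np.sqrt(grid.weight)
            states.append(GridWavefunction(grid, v))
        return vals, states
    if method == "imag":
        rng = np.random.default_rng(seed)
        engine = SplitOperator(model, grid)
        energies, states = [], []
        for i in range(k):
            if guesses is not None and i < len(guesses):
                g = np.asarray(guesses[i], dtype=complex)
            else:
                g = rng.standard_normal(grid.shape) + 0.1
            e, psi = engine.imaginary_time(
                g, dtau=dtau, tol=tol, orthogonalize_to=[s.psi for s in states])
            energies.append(e)
            states.append(GridWavefunction(grid, _fix_phase(psi)))
        order_idx = np.argsort(energies)
        return (np.array(energies)[order_idx],
                [states[i] for i in order_idx])
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# real-time propagation with observable recording


def exact_propagate(model: ModelSystem, psi0: GridWavefunction, dt: float,
                    t_final: float, *, pulse: LaserPulse = None,
                    mask: np.ndarray = None, stride: int = 10,
                    extra_channels: dict = None, snapshot_times=(),
                    energy: bool = False) -> tuple[ObservableSeries, dict]:
    """Split-operator propagation recording standard observables.

    Channels: ``norm``, ``autocorr`` (|<psi0|psi>|), ``dipole`` (if the
    model has dipole couplings), ``<label>`` mean first coordinate of every
    block, optional ``energy``, plus any ``extra_channels`` callables
    ``f(GridWavefunction, t) -> float``.  ``snapshot_times`` requests
    wavefunction copies at the nearest recorded times.
    """
    grid = psi0.grid
    engine = SplitOperator(model, grid)
    n_steps = int(round(t_final / dt))
    n_steps = ((n_steps + stride - 1) // stride) * stride  # uniform recording
    w = grid.weight
    psi0_flat = psi0.psi.ravel()
    has_dip = model.dipole and any(model.dipole.values())
    times, rec = [], {name: [] for name in
                      ["norm", "autocorr"]
                      + (["dipole"] if has_dip else [])
                      + [b.label for b in model.blocks]
                      + (["energy"] if energy else [])
                      + (list(extra_channels) if extra_channels else [])}
    snapshots = {}
    snap_left = sorted(snapshot_times)
    coord_ops = {b.label: model._bcast_block_mesh(grid, i)[0]
                 for i, b in enumerate(model.blocks)}

    def cb(psi, t, step):
        nrm2 = np.sum(np.abs(psi) ** 2) * w
        times.append(t)
        rec["norm"].append(np.sqrt(nrm2))
        rec["autocorr"].append(abs(np.vdot(psi0_flat, psi.ravel())) * w)
        dens = np.abs(psi) ** 2
        for lbl, X in coord_ops.items():
            rec[lbl].append(float(np.sum(dens * X)) * w / nrm2)
        if has_dip:
            rec["dipole"].append(float(np.sum(dens * engine.D)) * w / nrm2)
        if energy:
            rec["energy"].append(engine.energy(psi, t, pulse))
        if extra_channels:
            gw = GridWavefunction(grid, psi)
            for name, fn in extra_channels.items():
                rec[name].append(fn(gw, t))
        while snap_left and t >= snap_left[0] - 0.5 * dt * stride:
            snapshots[snap_left.pop(0)] = GridWavefunction(grid, psi.copy())

    engine.propagate(psi0.psi, dt, n_steps, pulse=pulse, mask=mask,
                     callback=cb, stride=stride)
    series = ObservableSeries(np.array(times),
                              {k2: np.array(v) for k2, v in rec.items()},
                              meta={"model": model.name, "dt": dt, "method": "exact"})
    return series, snapshots


# ---------------------------------------------------------------------------
# Born-Oppenheimer surfaces


@dataclass
class BOPESTable:
    """Adiabatic surfaces (and optionally electronic eigenstates) on a set
    of clamped nuclear configurations."""

    points: np.ndarray        # (N, nuc_ndim) clamped nuclear coordinates
    energies: np.ndarray      # (N, k), ascending at each point
    states: np.ndarray | None  # (N, k, n_elec) quadrature-normalized, or None
    elec_weight: float
    nuc_weight: float
    elec_shape: tuple

    @property
    def R(self) -> np.ndarray:
        """Nuclear axis for 1-D scans."""
        if self.points.shape[1] != 1:
            raise ValueError("R applies to 1-D nuclear scans")
        return self.points[:, 0]

    def surface(self, gamma: int) -> CubicSpline:
        return CubicSpline(self.R, self.energies[:, gamma])


def _electronic_hamiltonian(model: ModelSystem, grid: Grid, nuclear_block: int,
                            R_clamp: np.ndarray, order: int = 4):
    """Clamped-nucleus electronic Hamiltonian (sparse) and the clamped
    nuclear potential constant, on the electronic sub-axes of ``grid``."""
    elec_blocks = [b for b in range(grid.n_blocks) if b != nuclear_block]
    elec_axes = [ax for b in elec_blocks for ax in grid.block_axes[b]]
    sub = Grid(tuple(grid.axes[ax] for ax in elec_axes),
               tuple(tuple(elec_axes.index(ax) for ax in grid.block_axes[b])
                     for b in elec_blocks))
    shape = sub.shape
    V = np.zeros(shape)
    clamped = [None] * grid.n_blocks
    clamped[nuclear_block] = tuple(np.atleast_1d(x) for x in np.atleast_1d(R_clamp))

    def bmesh(snew):
        out = []
        for ax in sub.block_axes[snew]:
            sh = [1] * sub.ndim
            sh[ax] = shape[ax]
            out.append(sub.axes[ax].reshape(sh))
        return tuple(out)

    lbl_of = {model.blocks[bold].label: snew for snew, bold in enumerate(elec_blocks)}
    nuc_lbl = model.blocks[nuclear_block].label
    for lbl, fn in model.one_body.items():
        if lbl in lbl_of:
            V = V + fn(bmesh(lbl_of[lbl]))
    const = 0.0
    if nuc_lbl in model.one_body:
        const += float(model.one_body[nuc_lbl](clamped[nuclear_block]).ravel()[0])
    for p in model.pairs:
        i, j = p.block_i, p.block_j
        if i in lbl_of and j in lbl_of:
            V = V + p.fn(bmesh(lbl_of[i]), bmesh(lbl_of[j]))
        elif i in lbl_of:
            V = V + p.fn(bmesh(lbl_of[i]), clamped[nuclear_block])
        elif j in lbl_of:
            V = V + p.fn(clamped[nuclear_block], bmesh(lbl_of[j]))
    H = sp.diags(V.ravel()).tocsr()
    for snew, bold in enumerate(elec_blocks):
        for ax in sub.block_axes[snew]:
            T1 = kinetic_matrix(shape[ax], sub.dx(ax), model.blocks[bold].mass, order)
            left = sp.identity(int(np.prod(shape[:ax])), format="csr")
            right = sp.identity(int(np.prod(shape[ax + 1:])), format="csr")
            H = H + sp.kron(sp.kron(left, T1), right, format="csr")
    return H + const * sp.identity(int(np.prod(shape)), format="csr"), sub, float(V.min()) + const


def compute_bopes(model: ModelSystem, grid: Grid, k: int, *,
                  nuclear_block: str = None, points=None,
                  keep_states: bool = True, order: int = 4,
                  phase_origin=None) -> BOPESTable:
    """Adiabatic surfaces over a scan of clamped nuclear configurations.

    ``points`` defaults to the grid's nuclear axis (1-D) or the full nuclear
    mesh (2-D).  Electronic eigenstates get a continuous phase along the
    scan (each point phased against its nearest already-processed
    neighbour) so they can be used for projections.
    """
    if nuclear_block is None:
        nuclear_block = model.blocks[-1].label
    bn = model.block_index(nuclear_block)
    nuc_axes = grid.block_axes[bn]
    if points is None:
        if len(nuc_axes) == 1:
            points = grid.axes[nuc_axes[0]][:, None]
        else:
            mesh = np.meshgrid(*(grid.axes[a] for a in nuc_axes), indexing="ij")
            points = np.stack([m.ravel() for m in mesh], axis=1)
    points = np.atleast_2d(np.asarray(points, float))
    if points.ndim == 2 and points.shape[1] != len(nuc_axes):
        raise ValueError("points dimensionality mismatch with nuclear block")

    # processing order: nearest-neighbour sweep from the centroid outward,
    # so the phase reference is always an adjacent geometry
    center = points.mean(axis=0) if phase_origin is None else np.asarray(phase_origin, float)
    order_idx = np.argsort(np.linalg.norm(points - center, axis=1), kind="stable")

    N = len(points)
    energies = np.empty((N, k))
    states = None
    sub = None
    done = []
    for n in order_idx:
        H, sub, vmin = _electronic_hamiltonian(model, grid, bn, points[n], order)
        ne = H.shape[0]
        if ne <= 600:
            import scipy.linalg as la
            vals, vecs = la.eigh(H.toarray())
            vals, vecs = vals[:k], vecs[:, :k]
        else:
            v0 = np.full(ne, ne ** -0.5)
            vals, vecs = spla.eigsh(H, k=k, sigma=vmin - 0.5, which="LM", v0=v0)
            idx = np.argsort(vals)
            vals, vecs = vals[idx], vecs[:, idx]
        if states is None:
            states = np.empty((N, k, ne), dtype=float) if keep_states else None
        energies[n] = vals
        if keep_states:
            vecs = vecs / np.sqrt(sub.weight)
            if done:
                ref = done[np.argmin(np.linalg.norm(points[done] - points[n], axis=1))]
                for g in range(k):
                    if np.vdot(states[ref, g], vecs[:, g]).real < 0:
                        vecs[:, g] = -vecs[:, g]
            else:
                for g in range(k):
                    vecs[:, g] = _fix_phase(vecs[:, g]).real
            states[n] = vecs.T
        done.append(n)
    nuc_weight = float(np.prod([grid.dx(a) for a in nuc_axes]))
    return BOPESTable(points=points, energies=energies, states=states,
                      elec_weight=sub.weight, nuc_weight=nuc_weight,
                      elec_shape=sub.shape)


# ---------------------------------------------------------------------------
# conditional-slice diagnostics


@dataclass
class ConditionalSliceDiagnostic:
    block: int
    point: tuple              # snapped conditioning coordinates (other blocks)
    slice_raw: np.ndarray     # un-normalized slice on the block's axes
    slice_normalized: np.ndarray | None
    weight: float             # quadrature norm of the raw slice
    degenerate: bool
    eta: np.ndarray | None = None       # kinetic correlation potential
    eta_mask: np.ndarray | None = None  # where eta is defined
    residual: float | None = None       # Eq.-type eigenproblem residual


def _snap_indices(grid: Grid, block: int, point) -> tuple:
    """Nearest-node indices on all axes not belonging to ``block``."""
    other_axes = [a for a in range(grid.ndim) if a not in grid.block_axes[block]]
    point = np.atleast_1d(np.asarray(point, float))
    if len(point) != len(other_axes):
        raise ValueError("conditioning point dimensionality mismatch")
    idx = [slice(None)] * grid.ndim
    snapped = []
    for x, a in zip(point, other_axes):
        j = int(np.argmin(np.abs(grid.axes[a] - x)))
        idx[a] = j
        snapped.append(float(grid.axes[a][j]))
    return tuple(idx), tuple(snapped), other_axes


def conditional_slice(psi: GridWavefunction, model: ModelSystem, block_label: str,
                      point) -> ConditionalSliceDiagnostic:
    """One-body slice Psi(x_b, xbar) of a full wavefunction along one block."""
    grid = psi.grid
    b = model.block_index(block_label)
    idx, snapped, _ = _snap_indices(grid, b, point)
    raw = psi.psi[tuple(idx)].copy()
    wq = grid.block_weight(b)
    weight = float(np.sqrt(np.sum(np.abs(raw) ** 2) * wq))
    degenerate = weight < 1e-14 * float(np.max(np.abs(psi.psi)))
    normalized = None if degenerate else raw / weight
    return ConditionalSliceDiagnostic(block=b, point=snapped, slice_raw=raw,
                                      slice_normalized=normalized, weight=weight,
                                      degenerate=degenerate)


def kinetic_correlation_potential(psi: GridWavefunction, energy: float,
                                  model: ModelSystem, block_label: str, point,
                                  *, order: int = 4, floor: float = 1e-8
                                  ) -> ConditionalSliceDiagnostic:
    """Complex kinetic-correlation potential eta of a conditional slice of an
    exact eigenstate, and the residual of its one-body eigenproblem
    (K_b + W_b + eta) phi = E phi on points where the slice density is
    above ``floor`` times its maximum.

    eta is obtained by applying the kinetic operators of all *other* blocks
    to the full eigenstate, slicing, adding the clamped interaction terms
    that do not involve the sliced block, and dividing by the slice.
    """
    grid = psi.grid
    b = model.block_index(block_label)
    diag = conditional_slice(psi, model, block_label, point)
    if diag.degenerate:
        raise ValueError("slice amplitude is numerically zero at this point")
    idx, snapped, other_axes = _snap_indices(grid, b, point)

    # sum of other-block kinetic operators applied to the full state, sliced
    kin_other = np.zeros(grid.shape, dtype=complex)
    for j, blk in enumerate(model.blocks):
        if j == b:
            continue
        for ax in grid.block_axes[j]:
            T = kinetic_matrix(grid.shape[ax], grid.dx(ax), blk.mass, order)
            moved = np.moveaxis(psi.psi, ax, -1)
            out = (T @ moved.reshape(-1, grid.shape[ax]).T).T.reshape(moved.shape)
            kin_other += np.moveaxis(out, -1, ax)
    kin_slice = kin_other[tuple(idx)]

    # clamped coordinates per block, then the interaction terms not
    # involving the sliced block (constants of the one-body problem)
    clamped = [None] * grid.n_blocks
    pos = 0
    for j in range(grid.n_blocks):
        if j == b:
            continue
        nd = len(grid.block_axes[j])
        clamped[j] = tuple(np.atleast_1d(c) for c in snapped[pos:pos + nd])
        pos += nd
    w_rest = 0.0
    for lbl, fn in model.one_body.items():
        jj = model.block_index(lbl)
        if jj != b:
            w_rest += float(fn(clamped[jj]).ravel()[0])
    for p in model.pairs:
        i, j = model.block_index(p.block_i), model.block_index(p.block_j)
        if b not in (i, j):
            w_rest += float(p.fn(clamped[i], clamped[j]).ravel()[0])

    phi = diag.slice_raw
    dens = np.abs(phi) ** 2
    mask = dens > floor * dens.max()
    eta = np.full(phi.shape, np.nan + 0j)
    eta[mask] = (kin_slice[mask] + w_rest * phi[mask]) / phi[mask]

    # residual of (K_b + W_b + eta - E) phi on the unmasked points
    W_b = model.conditional_potential(grid, b, clamped)
    shape_b = grid.block_shape(b)
    phi_nd = phi.reshape(shape_b)
    kphi = np.zeros(shape_b, dtype=complex)
    for kk, ax in enumerate(grid.block_axes[b]):
        T = kinetic_matrix(grid.shape[ax], grid.dx(ax), model.blocks[b].mass, order)
        moved = np.moveaxis(phi_nd, kk, -1)
        out = (T @ moved.reshape(-1, shape_b[kk]).T).T.reshape(moved.shape)
        kphi += np.moveaxis(out, -1, kk)
    res_arr = (kphi + W_b * phi_nd + np.where(mask, eta, 0.0).reshape(shape_b) * phi_nd
               - energy * phi_nd)
    resid = float(np.sqrt(np.sum(np.abs(res_arr.ravel()[mask.ravel()]) ** 2)
                          * grid.block_weight(b)))
    scale = float(np.sqrt(np.sum(dens[mask]) * grid.block_weight(b))) * abs(energy)
    diag.eta = eta
    diag.eta_mask = mask
    diag.residual = resid / max(scale, 1e-300)
    return diag


# ---------------------------------------------------------------------------
# scattering initial state


def scattering_initial_state(model: ModelSystem, grid: Grid, p: float,
                             alpha: float = 0.1, center: float = -10.0,
                             order: int = 4) -> GridWavefunction:
    """Spin-singlet spatial state: symmetrized product of the target-atom
    ground state and an incident Gaussian wavepacket of momentum ``p``
    centred at ``center``."""
    r = grid.axes[0]
    h = kinetic_matrix(len(r), grid.dx(0), model.blocks[0].mass, order) \
        + sp.diags(model.one_body["r1"]((r,)))
    import scipy.linalg as la
    vals, vecs = la.eigh(h.toarray())
    phi_h = _fix_phase(vecs[:, 0]) / np.sqrt(grid.dx(0))
    phi_wp = (2 * alpha / np.pi) ** 0.25 * np.exp(-alpha * (r - center) ** 2 + 1j * p * r)
    psi = np.multiply.outer(phi_h, phi_wp) + np.multiply.outer(phi_wp, phi_h)
    return GridWavefunction(grid, psi, normalize=True)
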