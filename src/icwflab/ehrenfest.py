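"""Multitrajectory Ehrenfest (MTEF) mean-field baseline.

Nuclear blocks are treated as classical point particles sampled from a
Gaussian (Wigner-like) phase-space distribution matched to the quantum
position/momentum variances of the initial nuclear state; the electronic
blocks evolve as an exact grid wavefunction in the mean field of each
independent trajectory, and forces on the nuclei are mean-field
expectation values.  This is the standard comparison baseline whose
known failures (vibronic peak spacing, decoherence) the ICWF methods
correct.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .grids import Grid, kinetic_matrix
from .models import LaserPulse, ModelSystem, field_value
from .observables import ObservableSeries

__all__ = ["ehrenfest_baseline", "wigner_samples"]


def wigner_samples(R_mean, R_var, n_traj: int, seed: int):
    """Gaussian phase-space samples with minimum-uncertainty momentum
    spread sigma_P = 1/(2 sigma_R) per classical coordinate."""
    rng = np.random.default_rng(seed)
    R_mean = np.atleast_1d(np.asarray(R_mean, float))
    R_var = np.atleast_1d(np.asarray(R_var, float))
    sig_R = np.sqrt(R_var)
    sig_P = 1.0 / (2.0 * sig_R)
    R = R_mean + sig_R * rng.standard_normal((n_traj, len(R_mean)))
    P = sig_P * rng.standard_normal((n_traj, len(R_mean)))
    return R, P


class _ElectronicEngine:
    """Split-operator propagation of the electronic blocks of a model with
    the nuclear block(s) clamped at time-dependent classical positions."""

    def __init__(self, model: ModelSystem, grid: Grid, classical_blocks: list[int]):
        self.model = model
        self.grid = grid
        self.classical = classical_blocks
        self.quantum = [b for b in range(grid.n_blocks) if b not in classical_blocks]
        axes = [ax for b in self.quantum for ax in grid.block_axes[b]]
        self.sub = Grid(tuple(grid.axes[a] for a in axes),
                        tuple(tuple(axes.index(a) for a in grid.block_axes[b])
                              for b in self.quantum))
        ksq = np.zeros(self.sub.shape)
        for snew, bold in enumerate(self.quantum):
            for ax in self.sub.block_axes[snew]:
                k = 2 * np.pi * np.fft.fftfreq(self.sub.shape[ax], self.sub.dx(ax))
                sh = [1] * self.sub.ndim
                sh[ax] = len(k)
                ksq = ksq + k.reshape(sh) ** 2 / (2 * model.blocks[bold].mass)
        self.ksq = ksq
        # electron-only static terms
        self.V_e = np.zeros(self.sub.shape)
        for snew, bold in enumerate(self.quantum):
            lbl = model.blocks[bold].label
            if lbl in model.one_body:
                self.V_e = self.V_e + model.one_body[lbl](self._bmesh(snew))
        for p in model.pairs:
            bi, bj = model.block_index(p.block_i), model.block_index(p.block_j)
            if bi in self.quantum and bj in self.quantum:
                self.V_e = self.V_e + p.fn(self._bmesh(self.quantum.index(bi)),
                                           self._bmesh(self.quantum.index(bj)))
        self.D_e = np.zeros(self.sub.shape)
        for snew, bold in enumerate(self.quantum):
            c = model.dipole.get(model.blocks[bold].label, 0.0)
            if c:
                self.D_e = self.D_e + c * self._bmesh(snew)[0]

    def _bmesh(self, snew):
        out = []
        for ax in self.sub.block_axes[snew]:
            sh = [1] * self.sub.ndim
            sh[ax] = self.sub.shape[ax]
            out.append(self.sub.axes[ax].reshape(sh))
        return tuple(out)

    def coupling_potential(self, R: np.ndarray) -> np.ndarray:
        """Electron-nuclear interaction terms at clamped nuclear positions."""
        V = np.zeros(self.sub.shape)
        Rt = self._split_classical(R)
        for p in self.model.pairs:
            bi, bj = self.model.block_index(p.block_i), self.model.block_index(p.block_j)
            if bi in self.quantum and bj in self.classical:
                V = V + p.fn(self._bmesh(self.quantum.index(bi)), Rt[bj])
            elif bj in self.quantum and bi in self.classical:
                V = V + p.fn(Rt[bi], self._bmesh(self.quantum.index(bj)))
        return V

    def _split_classical(self, R: np.ndarray):
        out = {}
        k = 0
        for b in self.classical:
            nd = len(self.grid.block_axes[b])
            out[b] = tuple(np.atleast_1d(R[k + d]) for d in range(nd))
            k += nd
        return out

    def classical_potential(self, R: np.ndarray) -> float:
        """Nuclear one-body terms (and classical-classical pairs) at R."""
        Rt = self._split_classical(R)
        v = 0.0
        for b in self.classical:
            lbl = self.model.blocks[b].label
            if lbl in self.model.one_body:
                v += float(self.model.one_body[lbl](Rt[b]).ravel()[0])
        for p in self.model.pairs:
            bi, bj = self.model.block_index(p.block_i), self.model.block_index(p.block_j)
            if bi in self.classical and bj in self.classical:
                v += float(p.fn(Rt[bi], Rt[bj]).ravel()[0])
        return v

    def force(self, psi: np.ndarray, R: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Mean-field force -d/dR [ <psi|V_coup(R)|psi> + V_cl(R) ]."""
        w = self.sub.weight
        dens = np.abs(psi) ** 2
        nrm = dens.sum() * w
        F = np.empty(len(R))
        for k in range(len(R)):
            Rp, Rm = R.copy(), R.copy()
            Rp[k] += h
            Rm[k] -= h
            ep = float(np.sum(dens * self.coupling_potential(Rp))) * w / nrm \
                + self.classical_potential(Rp)
            em = float(np.sum(dens * self.coupling_potential(Rm))) * w / nrm \
                + self.classical_potential(Rm)
            F[k] = -(ep - em) / (2 * h)
        return F

    def bo_ground(self, R: np.ndarray) -> np.ndarray:
        """Clamped-nucleus electronic ground state (dense or Lanczos)."""
        from .grids import kinetic_matrix
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        V = self.V_e + self.coupling_potential(R)
        H = sp.diags(V.ravel()).tocsr()
        shape = self.sub.shape
        for snew, bold in enumerate(self.quantum):
            for ax in self.sub.block_axes[snew]:
                T1 = kinetic_matrix(shape[ax], self.sub.dx(ax),
                                    self.model.blocks[bold].mass)
                left = sp.identity(int(np.prod(shape[:ax])), format="csr")
                right = sp.identity(int(np.prod(shape[ax + 1:])), format="csr")
                H = H + sp.kron(sp.kron(left, T1), right, format="csr")
        if H.shape[0] <= 700:
            _, vecs = sla.eigh(H.toarray(), subset_by_index=(0, 0))
            v = vecs[:, 0]
        else:
            v0 = np.full(H.shape[0], H.shape[0] ** -0.5)
            _, vecs = spla.eigsh(H, k=1, sigma=float(V.min()) - 0.5, which="LM",
                                 v0=v0)
            v = vecs[:, 0]
        psi = v.reshape(self.sub.shape) / np.sqrt(self.sub.weight)
        return psi.astype(complex)


def ehrenfest_baseline(model: ModelSystem, grid: Grid, *, n_traj: int,
                       seed: int, dt: float, t_final: float,
                       classical_labels: list[str],
                       R_mean, R_var,
                       pulse: LaserPulse = None, kick: float = 0.0,
                       stride: int = 10, traj_channels: dict = None,
                       keep_trajectories: bool = False) -> ObservableSeries:
    """Mean-field Ehrenfest dynamics averaged over a Wigner-sampled
    ensemble of classical nuclear trajectories.

    Each trajectory starts from the clamped electronic ground state at its
    sampled nuclear position (optionally dipole-kicked), propagates the
    electrons by split-operator and the nuclei by velocity Verlet with
    mean-field forces.  ``traj_channels`` maps channel names to callables
    ``f(psi_elec, R, P, t) -> float`` evaluated per trajectory and averaged.

    Channels: ``dipole`` (electronic + classical dipole coupling), one mean
    coordinate per classical label, ``norm`` plus any ``traj_channels``.
    """
    classical_blocks = [model.block_index(l) for l in classical_labels]
    eng = _ElectronicEngine(model, grid, classical_blocks)
    n_steps = int(round(t_final / dt))
    n_rec = n_steps // stride + 1
    times = np.arange(n_rec) * dt * stride
    names = ["dipole", "norm"] + classical_labels + (list(traj_channels) if traj_channels else [])
    acc = {k: np.zeros(n_rec) for k in names}
    per_traj = ({k: np.zeros((n_traj, n_rec)) for k in
                 ["R_traj"] + (list(traj_channels) if traj_channels else [])}
                if keep_trajectories else None)
    R0s, P0s = wigner_samples(R_mean, R_var, n_traj, seed)
    masses = np.array([model.blocks[b].mass for b in classical_blocks
                       for _ in grid.block_axes[b]])
    d_cl = np.array([model.dipole.get(model.blocks[b].label, 0.0)
                     for b in classical_blocks for _ in grid.block_axes[b]])
    w = eng.sub.weight
    expK = np.exp(-1j * dt * eng.ksq)

    for tr in range(n_traj):
        R, P = R0s[tr].copy(), P0s[tr].copy()
        psi = eng.bo_ground(R)
        if kick:
            psi = psi * np.exp(1j * kick * eng.D_e)
        F = eng.force(psi, R)
        rec_i = 0
        for s in range(n_steps + 1):
            if s % stride == 0 and rec_i < n_rec:
                dens = np.abs(psi) ** 2
                nrm2 = dens.sum() * w
                acc["norm"][rec_i] += np.sqrt(nrm2) / n_traj
                dip = float(np.sum(dens * eng.D_e)) * w / nrm2 + float(d_cl @ R)
                acc["dipole"][rec_i] += dip / n_traj
                k = 0
                for b, lbl in zip(classical_blocks, classical_labels):
                    acc[lbl][rec_i] += R[k] / n_traj
                    k += len(grid.block_axes[b])
                if traj_channels:
                    for nm, fn in traj_channels.items():
                        val = fn(psi, R, P, s * dt)
                        acc[nm][rec_i] += val / n_traj
                        if per_traj is not None:
                            per_traj[nm][tr, rec_i] = val
                if per_traj is not None:
                    per_traj["R_traj"][tr, rec_i] = R[0]
                rec_i += 1
            if s == n_steps:
                break
            t = s * dt
            # velocity Verlet half-kick + drift
            P = P + 0.5 * dt * F
            R = R + dt * P / masses
            # electronic Strang step in the new nuclear field
            V = eng.V_e + eng.coupling_potential(R)
            if pulse is not None:
                e = float(field_value(pulse, max(t + 0.5 * dt, 0.0)))
                if e:
                    V = V + e * eng.D_e
            half = np.exp(-0.5j * dt * V)
            psi = half * np.fft.ifftn(expK * np.fft.fftn(half * psi))
            F = eng.force(psi, R)
            P = P + 0.5 * dt * F
    series = ObservableSeries(times, acc,
                              meta={"model": model.name, "method": "mtef",
                                    "n_traj": n_traj, "seed": seed, "dt": dt})
    if per_traj is not None:
        series.meta["per_traj"] = per_traj
    return series
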