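"""Model electron-nuclear systems and external-field pulses.

Four exactly solvable low-dimensional molecular models are bundled, all in
Hartree atomic units:

* a 1-D hydrogen molecule (two soft-Coulomb electrons + internuclear
  separation) in internal coordinates,
* a 1-D electron-hydrogen impact-ionization model (two electrons, fixed
  target atom),
* the Shin-Metiu proton-coupled electron-transfer model (one electron,
  one mobile proton between two fixed ions),
* a 2-D electron + 2-D quantized proton model with a conical intersection
  fixed at the origin by a D3h arrangement of two clamped protons.

A model is a declarative :class:`ModelSystem`: per-block masses and
dimensionalities, one-body potentials, pairwise interaction terms and
length-gauge dipole couplings.  External fields enter exclusively through
:class:`LaserPulse` (vector potentials are not supported; every driven
example uses the length gauge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from .grids import Grid

__all__ = [
    "DOFBlock",
    "PairTerm",
    "ModelSystem",
    "LaserPulse",
    "field_value",
    "build_h2_model",
    "build_h2_electronic_model",
    "build_scattering_model",
    "build_shin_metiu_model",
    "build_ci_model",
    "build_model",
    "AU_TIME_FS",
]

AU_TIME_FS = 0.02418884254  # 1 atomic time unit in femtoseconds


@dataclass(frozen=True)
class DOFBlock:
    label: str
    ndim: int
    mass: float
    charge: float = 0.0

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"block {self.label}: mass must be positive")
        if self.ndim not in (1, 2):
            raise ValueError("blocks are 1-D or 2-D")


@dataclass(frozen=True)
class PairTerm:
    """Interaction between two distinct blocks.

    ``fn(ci, cj)`` receives one coordinate-array tuple per block (length =
    block ndim, mutually broadcastable) and returns the interaction energy.
    """

    block_i: str
    block_j: str
    fn: Callable

    def __post_init__(self):
        if self.block_i == self.block_j:
            raise ValueError("pair term must reference two distinct blocks")


@dataclass(frozen=True)
class ModelSystem:
    name: str
    blocks: tuple[DOFBlock, ...]
    one_body: dict  # label -> fn(coords tuple) -> potential
    pairs: tuple[PairTerm, ...]
    dipole: dict  # label -> coefficient of E(t)*x (axis 0 of the block)
    default_grid_specs: tuple = ()  # ((lo, hi, n), ...) per axis
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate block labels")
        for p in self.pairs:
            if p.block_i not in labels or p.block_j not in labels:
                raise ValueError("pair term references unknown block")

    # -- helpers -----------------------------------------------------------
    def block_index(self, label: str) -> int:
        for i, b in enumerate(self.blocks):
            if b.label == label:
                return i
        raise KeyError(label)

    def block(self, label: str) -> DOFBlock:
        return self.blocks[self.block_index(label)]

    @property
    def block_ndims(self) -> list[int]:
        return [b.ndim for b in self.blocks]

    def default_grid(self) -> Grid:
        if not self.default_grid_specs:
            raise ValueError(f"model {self.name} has no default grid")
        return Grid.from_specs(self.default_grid_specs, self.block_ndims)

    def _bcast_block_mesh(self, grid: Grid, b: int):
        """Block-b coordinate arrays reshaped to broadcast over the full grid."""
        out = []
        for ax in grid.block_axes[b]:
            shape = [1] * grid.ndim
            shape[ax] = len(grid.axes[ax])
            out.append(grid.axes[ax].reshape(shape))
        return tuple(out)

    def potential_on_grid(self, grid: Grid) -> np.ndarray:
        """Full static potential W(x) on the tensor grid."""
        V = np.zeros(grid.shape)
        for i, blk in enumerate(self.blocks):
            if blk.label in self.one_body:
                V = V + self.one_body[blk.label](self._bcast_block_mesh(grid, i))
        for p in self.pairs:
            ci = self._bcast_block_mesh(grid, self.block_index(p.block_i))
            cj = self._bcast_block_mesh(grid, self.block_index(p.block_j))
            V = V + p.fn(ci, cj)
        return V

    def dipole_on_grid(self, grid: Grid) -> np.ndarray:
        """Length-gauge dipole-coupling operator D(x) with H'(t) = E(t) D."""
        D = np.zeros(grid.shape)
        for i, blk in enumerate(self.blocks):
            c = self.dipole.get(blk.label, 0.0)
            if c:
                D = D + c * self._bcast_block_mesh(grid, i)[0]
        return D

    def conditional_potential(self, grid: Grid, b: int, clamped: Sequence[np.ndarray]) -> np.ndarray:
        """W_b(x_b) with all other blocks clamped.

        ``clamped[j]`` is the coordinate tuple (length ndim_j) of block j;
        entry ``b`` is ignored.  Returns the potential on block b's mesh.
        """
        mesh = grid.block_mesh(b)
        label = self.blocks[b].label
        W = np.zeros(grid.block_shape(b))
        if label in self.one_body:
            W = W + self.one_body[label](mesh)
        for p in self.pairs:
            i, j = self.block_index(p.block_i), self.block_index(p.block_j)
            if i == b:
                W = W + p.fn(mesh, tuple(np.atleast_1d(c) for c in clamped[j]))
            elif j == b:
                W = W + p.fn(tuple(np.atleast_1d(c) for c in clamped[i]), mesh)
        return W

    def pair_kernel(self, grid: Grid, p: PairTerm) -> np.ndarray:
        """Interaction kernel W[x_i, x_j] over the flattened meshes of the
        two blocks of a pair term."""
        i, j = self.block_index(p.block_i), self.block_index(p.block_j)
        ci = tuple(c.reshape(-1, 1) for c in np.broadcast_arrays(*grid.block_mesh(i)))
        cj = tuple(c.reshape(1, -1) for c in np.broadcast_arrays(*grid.block_mesh(j)))
        return p.fn(ci, cj)


# ---------------------------------------------------------------------------
# laser pulses


@dataclass(frozen=True)
class LaserPulse:
    """sin^2-envelope pulse E(t) = E0 * sin^2(pi t / T) * sin(w t) on [0, T],
    plus an optional impulsive dipole kick of strength ``kick`` at t = 0."""

    E0: float = 0.0
    omega: float = 0.0
    duration: float = 0.0
    envelope: str = "sin2"
    kick: float = 0.0

    @classmethod
    def n_cycles(cls, E0: float, omega: float, cycles: float, **kw) -> "LaserPulse":
        return cls(E0=E0, omega=omega, duration=cycles * 2 * np.pi / omega, **kw)


def field_value(pulse: LaserPulse, t) -> np.ndarray:
    """Electric field amplitude at time(s) t >= 0 (au)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("field is defined for t >= 0")
    if pulse.E0 == 0.0 or pulse.duration == 0.0:
        return np.zeros_like(t)
    if pulse.envelope != "sin2":
        raise ValueError(f"unknown envelope {pulse.envelope!r}")
    env = np.where(
        t <= pulse.duration, np.sin(np.pi * np.clip(t, 0, pulse.duration) / pulse.duration) ** 2, 0.0
    )
    return pulse.E0 * env * np.sin(pulse.omega * t)


# ---------------------------------------------------------------------------
# soft interactions


def soft_coulomb(d, eps):
    """+-1/sqrt(eps + d^2) soft-Coulomb magnitude (sign applied by caller)."""
    return 1.0 / np.sqrt(eps + np.asarray(d) ** 2)


def erf_screened(d, Rc):
    """erf(|d|/Rc)/|d|, continuous at d = 0 (value 2/(Rc sqrt(pi)))."""
    d = np.abs(np.asarray(d, dtype=float))
    dd = np.where(d < 1e-10, 1.0, d)
    return np.where(d < 1e-10, 2.0 / (Rc * np.sqrt(np.pi)), erf(dd / Rc) / dd)


# ---------------------------------------------------------------------------
# model builders


def build_h2_model(M: float = 1836.0, eps_ee: float = 2.0, eps_en: float = 1.0) -> ModelSystem:
    """1-D hydrogen molecule in internal coordinates (r1, r2, R).

    Reduced masses mu_e = 2M/(2M+1), mu_n = M/2.  Soft-Coulomb
    electron-electron repulsion (softening ``eps_ee``), electron-nuclear
    attraction to nuclei at +-R/2 (softening ``eps_en``), and bare 1/R
    internuclear repulsion (the R grid excludes R = 0).
    """
    mu_e = 2 * M / (2 * M + 1)
    mu_n = M / 2
    blocks = (
        DOFBlock("r1", 1, mu_e, -1.0),
        DOFBlock("r2", 1, mu_e, -1.0),
        DOFBlock("R", 1, mu_n, +1.0),
    )

    def v_nn(c):
        return 1.0 / c[0]

    def w_ee(ci, cj):
        return soft_coulomb(ci[0] - cj[0], eps_ee)

    def w_en(ce, cn):
        R = cn[0]
        return -(soft_coulomb(ce[0] - R / 2, eps_en) + soft_coulomb(ce[0] + R / 2, eps_en))

    pairs = (
        PairTerm("r1", "r2", w_ee),
        PairTerm("r1", "R", w_en),
        PairTerm("r2", "R", w_en),
    )
    return ModelSystem(
        name="h2",
        blocks=blocks,
        one_body={"R": v_nn},
        pairs=pairs,
        dipole={"r1": 1.0, "r2": 1.0},
        default_grid_specs=((-40.0, 40.0, 256), (-40.0, 40.0, 256), (0.2, 12.0, 128)),
        params=dict(M=M, mu_e=mu_e, mu_n=mu_n, eps_ee=eps_ee, eps_en=eps_en),
    )


def build_h2_electronic_model(R: float, M: float = 1836.0, eps_ee: float = 2.0,
                              eps_en: float = 1.0) -> ModelSystem:
    """Clamped-R electronic subproblem of the 1-D H2 model (two electron
    blocks); energies include the 1/R internuclear constant."""
    mu_e = 2 * M / (2 * M + 1)
    blocks = (DOFBlock("r1", 1, mu_e, -1.0), DOFBlock("r2", 1, mu_e, -1.0))

    def v_en(c):
        return (-soft_coulomb(c[0] - R / 2, eps_en)
                - soft_coulomb(c[0] + R / 2, eps_en)
                + 0.5 / R)  # split the n-n constant across the two electrons

    def w_ee(ci, cj):
        return soft_coulomb(ci[0] - cj[0], eps_ee)

    return ModelSystem(
        name="h2_electronic",
        blocks=blocks,
        one_body={"r1": v_en, "r2": v_en},
        pairs=(PairTerm("r1", "r2", w_ee),),
        dipole={"r1": 1.0, "r2": 1.0},
        default_grid_specs=((-40.0, 40.0, 256), (-40.0, 40.0, 256)),
        params=dict(R=R, M=M, mu_e=mu_e, eps_ee=eps_ee, eps_en=eps_en),
    )


def build_scattering_model(r_atom: float = 10.0, eps: float = 1.0) -> ModelSystem:
    """1-D electron-hydrogen scattering model: two electrons, a fixed
    soft-Coulomb target atom at ``r_atom``."""
    blocks = (DOFBlock("r1", 1, 1.0, -1.0), DOFBlock("r2", 1, 1.0, -1.0))

    def v0(c):
        return -soft_coulomb(c[0] - r_atom, eps)

    def w_ee(ci, cj):
        return soft_coulomb(ci[0] - cj[0], eps)

    return ModelSystem(
        name="scattering",
        blocks=blocks,
        one_body={"r1": v0, "r2": v0},
        pairs=(PairTerm("r1", "r2", w_ee),),
        dipole={"r1": 1.0, "r2": 1.0},
        default_grid_specs=((-100.0, 160.0, 512), (-100.0, 160.0, 512)),
        params=dict(r_atom=r_atom, eps=eps),
    )


def build_shin_metiu_model(M: float = 1836.0, L: float = 19.0, Rf: float = 5.0,
                           Rl: float = 4.0, Rr: float = 3.1) -> ModelSystem:
    """Shin-Metiu proton-coupled electron transfer model.

    One electron (r) and one mobile proton (R) on the line joining two
    fixed ions at +-L/2.  The mobile charges attract via erf-screened
    Coulomb terms (screening lengths Rf for electron-proton, Rl/Rr for the
    electron with the two fixed ions); the proton feels the bare Coulomb
    repulsion of the fixed ions.  The orientation places the ground-state
    equilibrium on the negative-R side.
    """
    blocks = (DOFBlock("r", 1, 1.0, -1.0), DOFBlock("R", 1, M, +1.0))

    def v_e(c):
        r = c[0]
        return -erf_screened(r - L / 2, Rl) - erf_screened(r + L / 2, Rr)

    def v_n(c):
        R = c[0]
        return 1.0 / np.abs(L / 2 - R) + 1.0 / np.abs(L / 2 + R)

    def w_en(ce, cn):
        return -erf_screened(cn[0] - ce[0], Rf)

    return ModelSystem(
        name="shin_metiu",
        blocks=blocks,
        one_body={"r": v_e, "R": v_n},
        pairs=(PairTerm("r", "R", w_en),),
        dipole={"r": -1.0, "R": 1.0},
        default_grid_specs=((-25.0, 25.0, 256), (-9.0, 9.0, 128)),
        params=dict(M=M, L=L, Rf=Rf, Rl=Rl, Rr=Rr),
    )


def build_ci_model(a: float = 0.5, b: float = 10.0, R0: float = 1.5,
                   M: float = 1836.0) -> ModelSystem:
    """2-D conical-intersection model: a quantized electron and proton in
    the plane of two clamped protons at R1 = (-0.4*sqrt(3), 1.2) and
    R2 = (+0.4*sqrt(3), 1.2).

    All Coulomb terms are softened with parameter ``a``; a steep circular
    wall (|R|/R0)^b confines the quantized proton.  When the proton sits at
    the origin the three nuclei form an equilateral (D3h) triangle and the
    two lowest excited electronic surfaces are degenerate: the conical
    intersection is pinned to the origin by symmetry.
    """
    R1 = np.array([-0.4 * np.sqrt(3.0), 1.2])
    R2 = np.array([+0.4 * np.sqrt(3.0), 1.2])
    blocks = (DOFBlock("r", 2, 1.0, -1.0), DOFBlock("R", 2, M, +1.0))

    def _d2(c, P):
        return (c[0] - P[0]) ** 2 + (c[1] - P[1]) ** 2

    def v_e(c):
        return -(1.0 / np.sqrt(a + _d2(c, R1)) + 1.0 / np.sqrt(a + _d2(c, R2)))

    def v_n(c):
        rep = 1.0 / np.sqrt(a + _d2(c, R1)) + 1.0 / np.sqrt(a + _d2(c, R2))
        conf = (np.sqrt(c[0] ** 2 + c[1] ** 2) / R0) ** b
        return rep + conf

    def w_en(ce, cn):
        return -1.0 / np.sqrt(a + (ce[0] - cn[0]) ** 2 + (ce[1] - cn[1]) ** 2)

    return ModelSystem(
        name="ci",
        blocks=blocks,
        one_body={"r": v_e, "R": v_n},
        pairs=(PairTerm("r", "R", w_en),),
        dipole={},
        default_grid_specs=(
            (-6.0, 6.0, 48), (-6.0, 6.0, 48), (-2.2, 2.2, 32), (-2.2, 2.2, 32)),
        params=dict(a=a, b=b, R0=R0, M=M, R1=tuple(R1), R2=tuple(R2)),
    )


_BUILDERS = {
    "h2": build_h2_model,
    "h2_electronic": build_h2_electronic_model,
    "scattering": build_scattering_model,
    "shin_metiu": build_shin_metiu_model,
    "ci": build_ci_model,
}


def build_model(name: str, **overrides) -> ModelSystem:
    """Build a bundled model by name with optional parameter overrides."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; have {sorted(_BUILDERS)}") from None
    return builder(**overrides)


def model_from_config(cfg: dict) -> ModelSystem:
    """Construct a model from a config mapping: ``{"name": ..., "overrides": {...}}``."""
    return build_model(cfg["name"], **cfg.get("overrides", {}))


def pulse_from_config(cfg: dict) -> LaserPulse:
    """Pulse from config keys E0/omega plus either ``cycles`` or ``duration``."""
    E0 = float(cfg.get("E0", 0.0))
    omega = float(cfg.get("omega", 0.0))
    kick = float(cfg.get("kick", 0.0))
    if "cycles" in cfg:
        return LaserPulse.n_cycles(E0, omega, float(cfg["cycles"]), kick=kick)
    return LaserPulse(E0=E0, omega=omega, duration=float(cfg.get("duration", 0.0)), kick=kick)
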