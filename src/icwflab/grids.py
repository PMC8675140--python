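"""Tensor-product real-space grids and grid wavefunctions.

All solvers in this package share one spatial representation: a uniform
tensor-product grid in Hartree atomic units (lengths in bohr).  Each
degree-of-freedom block of a model owns one or two grid axes, in block
declaration order, so the flattened axis list of a :class:`Grid` maps
one-to-one onto the dimensions of a full wavefunction array.

Quadrature is the plain Riemann sum ``prod(dx)`` appropriate for
wavefunctions that decay to (numerically) zero at the box boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Grid",
    "GridWavefunction",
    "kinetic_matrix",
    "apply_kinetic",
    "interpolate_offgrid",
    "absorbing_mask",
    "save_wavefunction",
    "load_wavefunction",
]


def _axis(lo: float, hi: float, n: int) -> np.ndarray:
    if n < 8:
        raise ValueError(f"grid axes need >= 8 points, got {n}")
    if not hi > lo:
        raise ValueError("axis bounds must be strictly increasing")
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class Grid:
    """Uniform tensor-product grid.

    Parameters
    ----------
    axes
        One strictly increasing, uniformly spaced coordinate array per
        spatial dimension (bohr).
    block_axes
        For each DOF block, the tuple of axis indices it owns.  Defaults
        to one 1-D block per axis.
    """

    axes: tuple[np.ndarray, ...]
    block_axes: tuple[tuple[int, ...], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        object.__setattr__(self, "axes", axes)
        for a in axes:
            if a.ndim != 1 or len(a) < 8:
                raise ValueError("each axis must be 1-D with >= 8 points")
            d = np.diff(a)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9):
                raise ValueError("axes must be strictly increasing and uniform")
        if self.block_axes is None:
            object.__setattr__(
                self, "block_axes", tuple((i,) for i in range(len(axes)))
            )

    @classmethod
    def from_specs(cls, specs, block_ndims=None) -> "Grid":
        """Build from ``[(lo, hi, n), ...]`` axis specs.

        ``block_ndims`` optionally groups consecutive axes into blocks,
        e.g. ``[2, 2]`` for two 2-D particles.
        """
        axes = tuple(_axis(*s) for s in specs)
        if block_ndims is None:
            return cls(axes)
        blocks, k = [], 0
        for nd in block_ndims:
            blocks.append(tuple(range(k, k + nd)))
            k += nd
        if k != len(axes):
            raise ValueError("block_ndims inconsistent with number of axes")
        return cls(axes, tuple(blocks))

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def dx(self, i: int) -> float:
        return float(self.axes[i][1] - self.axes[i][0])

    @property
    def weight(self) -> float:
        """Full-grid quadrature volume element."""
        return float(np.prod([self.dx(i) for i in range(self.ndim)]))

    def block_weight(self, b: int) -> float:
        return float(np.prod([self.dx(i) for i in self.block_axes[b]]))

    def block_shape(self, b: int) -> tuple[int, ...]:
        return tuple(len(self.axes[i]) for i in self.block_axes[b])

    def block_size(self, b: int) -> int:
        return int(np.prod(self.block_shape(b)))

    @property
    def n_blocks(self) -> int:
        return len(self.block_axes)

    def meshgrid(self):
        return np.meshgrid(*self.axes, indexing="ij")

    def block_mesh(self, b: int):
        """Coordinate mesh arrays over a single block's own axes."""
        ax = [self.axes[i] for i in self.block_axes[b]]
        if len(ax) == 1:
            return (ax[0],)
        return tuple(np.meshgrid(*ax, indexing="ij"))

    def contains(self, point: np.ndarray) -> bool:
        point = np.atleast_1d(point)
        return all(
            self.axes[i][0] <= point[i] <= self.axes[i][-1]
            for i in range(self.ndim)
        )


class GridWavefunction:
    """Complex amplitudes on a full tensor-product grid."""

    def __init__(self, grid: Grid, psi: np.ndarray, normalize: bool = False):
        psi = np.asarray(psi, dtype=complex)
        if psi.shape != grid.shape:
            raise ValueError(f"amplitude shape {psi.shape} != grid shape {grid.shape}")
        if not (np.all(np.isfinite(psi.real)) and np.all(np.isfinite(psi.imag))):
            raise ValueError("non-finite amplitudes")
        self.grid = grid
        self.psi = psi
        if normalize:
            self.normalize()

    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.psi) ** 2) * self.grid.weight))

    def normalize(self) -> "GridWavefunction":
        n = self.norm()
        if n == 0.0:
            raise ZeroDivisionError("cannot normalize a zero wavefunction")
        self.psi /= n
        return self

    def inner(self, other: "GridWavefunction") -> complex:
        """Quadrature inner product <self|other>."""
        return complex(np.vdot(self.psi, other.psi) * self.grid.weight)

    def density(self) -> np.ndarray:
        return np.abs(self.psi) ** 2

    def copy(self) -> "GridWavefunction":
        return GridWavefunction(self.grid, self.psi.copy())


# ---------------------------------------------------------------------------
# kinetic energy by central finite differences

_STENCILS = {
    2: ([-1, 0, 1], [1.0, -2.0, 1.0]),
    4: ([-2, -1, 0, 1, 2], [-1 / 12, 4 / 3, -5 / 2, 4 / 3, -1 / 12]),
}


def kinetic_matrix(n: int, dx: float, mass: float, order: int = 4) -> sp.csr_matrix:
    """Sparse -(1/2m) d^2/dx^2 on a uniform axis (one-sided truncation
    at the box ends, consistent with hard-wall boundaries)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if n < 5:
        raise ValueError("kinetic stencil needs >= 5 points")
    offs, coef = _STENCILS[order]
    diags = [np.full(n - abs(o), c) for o, c in zip(offs, coef)]
    d2 = sp.diags(diags, offs, format="csr") / dx**2
    return (-0.5 / mass) * d2


def apply_kinetic(psi: np.ndarray, mass: float, dx: float, order: int = 4) -> np.ndarray:
    """Apply -(1/2m) d^2/dx^2 along the last axis of ``psi``."""
    n = psi.shape[-1]
    T = kinetic_matrix(n, dx, mass, order)
    flat = psi.reshape(-1, n)
    return (T @ flat.T).T.reshape(psi.shape)


def block_kinetic_matrix(grid: Grid, b: int, mass: float, order: int = 4) -> sp.csr_matrix:
    """Kinetic operator of one DOF block on its own (possibly 2-D) axes."""
    axs = grid.block_axes[b]
    ns = [len(grid.axes[i]) for i in axs]
    T = None
    for k, i in enumerate(axs):
        t1 = kinetic_matrix(ns[k], grid.dx(i), mass, order)
        left = sp.identity(int(np.prod(ns[:k])), format="csr")
        right = sp.identity(int(np.prod(ns[k + 1:])), format="csr")
        term = sp.kron(sp.kron(left, t1), right, format="csr")
        T = term if T is None else T + term
    return T.tocsr()


# ---------------------------------------------------------------------------
# off-grid interpolation (local Lagrange cubic, 4-point stencil)


def _cubic_weights(u: np.ndarray):
    """Lagrange weights and derivative weights at fractional position u in
    [0,1] relative to the second node of a 4-point stencil {-1,0,1,2}."""
    w = np.empty(u.shape + (4,))
    dw = np.empty_like(w)
    w[..., 0] = -u * (u - 1) * (u - 2) / 6
    w[..., 1] = (u + 1) * (u - 1) * (u - 2) / 2
    w[..., 2] = -(u + 1) * u * (u - 2) / 2
    w[..., 3] = (u + 1) * u * (u - 1) / 6
    dw[..., 0] = -(3 * u**2 - 6 * u + 2) / 6
    dw[..., 1] = (3 * u**2 - 4 * u - 1) / 2
    dw[..., 2] = -(3 * u**2 - 2 * u - 2) / 2
    dw[..., 3] = (3 * u**2 - 1) / 6
    return w, dw


def _stencil_1d(axis: np.ndarray, x: np.ndarray):
    """Start indices and fractional offsets of the 4-point stencils."""
    x = np.asarray(x, dtype=float)
    lo, hi = axis[0], axis[-1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("interpolation point outside grid bounds")
    dx = axis[1] - axis[0]
    t = (x - lo) / dx
    j = np.clip(np.floor(t).astype(int), 1, len(axis) - 3)
    u = t - j
    return j - 1, u, dx


def interpolate_offgrid(values: np.ndarray, axes, points: np.ndarray):
    """Cubic local interpolation of value and gradient at off-grid points.

    Parameters
    ----------
    values
        Array sampled on the tensor grid of ``axes`` (1-D or 2-D here);
        leading dimensions are broadcast (a batch of functions).
    axes
        Sequence of the coordinate axes spanning the trailing dims of
        ``values``.
    points
        ``(npts, ndim)`` query coordinates inside the grid bounds.

    Returns
    -------
    vals : ``(..., npts)`` interpolated values
    grads : ``(..., npts, ndim)`` interpolated first derivatives
    """
    axes = [np.asarray(a) for a in axes]
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ndim = len(axes)
    if points.shape[1] != ndim:
        raise ValueError("points dimensionality mismatch")
    idx, wgt, dwgt = [], [], []
    for d in range(ndim):
        j0, u, dx = _stencil_1d(axes[d], points[:, d])
        w, dw = _cubic_weights(u)
        idx.append(j0)
        wgt.append(w)
        dwgt.append(dw / dx)
    batch = values.shape[: values.ndim - ndim]
    npts = points.shape[0]
    vals = np.zeros(batch + (npts,), dtype=values.dtype)
    grads = np.zeros(batch + (npts, ndim), dtype=values.dtype)
    if ndim == 1:
        for a in range(4):
            col = values[..., idx[0] + a]
            vals += col * wgt[0][:, a]
            grads[..., 0] += col * dwgt[0][:, a]
    elif ndim == 2:
        for a in range(4):
            for b in range(4):
                col = values[..., idx[0] + a, idx[1] + b]
                vals += col * (wgt[0][:, a] * wgt[1][:, b])
                grads[..., 0] += col * (dwgt[0][:, a] * wgt[1][:, b])
                grads[..., 1] += col * (wgt[0][:, a] * dwgt[1][:, b])
    else:  # pragma: no cover - blocks are 1-D or 2-D by construction
        raise NotImplementedError("interpolation supports 1-D and 2-D blocks")
    return vals, grads


# ---------------------------------------------------------------------------
# absorbing boundaries


def absorbing_mask(grid: Grid, width_fraction: float = 0.1, power: float = 0.125):
    """Smooth multiplicative damping mask, 1 in the interior and
    ``cos^power`` tapering to the box edges.

    Returns the full-grid mask array (outer product of per-axis masks).
    """
    if not 0.0 < width_fraction < 0.5:
        raise ValueError("width fraction must be in (0, 0.5)")
    per_axis = []
    for a in grid.axes:
        lo, hi = a[0], a[-1]
        w = width_fraction * (hi - lo)
        m = np.ones_like(a)
        left = a < lo + w
        right = a > hi - w
        m[left] = np.cos(0.5 * np.pi * (lo + w - a[left]) / w) ** power
        m[right] = np.cos(0.5 * np.pi * (a[right] - (hi - w)) / w) ** power
        per_axis.append(m)
    full = per_axis[0]
    for m in per_axis[1:]:
        full = np.multiply.outer(full, m)
    return full


# ---------------------------------------------------------------------------
# HDF5 checkpoints


def save_wavefunction(path, wf: GridWavefunction, **meta):
    with h5py.File(path, "w") as f:
        for i, a in enumerate(wf.grid.axes):
            f.create_dataset(f"axes/{i}", data=a)
        f.create_dataset("block_axes", data=np.array(
            [list(b) + [-1] * (2 - len(b)) for b in wf.grid.block_axes]))
        f.create_dataset("real", data=wf.psi.real)
        f.create_dataset("imag", data=wf.psi.imag)
        f.attrs["norm"] = wf.norm()
        for k, v in meta.items():
            f.attrs[k] = v


def load_wavefunction(path) -> tuple[GridWavefunction, dict]:
    with h5py.File(path, "r") as f:
        axes = [f[f"axes/{i}"][...] for i in range(len(f["axes"]))]
        ba = tuple(tuple(int(x) for x in row if x >= 0) for row in f["block_axes"][...])
        grid = Grid(tuple(axes), ba)
        psi = f["real"][...] + 1j * f["imag"][...]
        meta = dict(f.attrs)
    return GridWavefunction(grid, psi), meta
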