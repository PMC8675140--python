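"""Seeded stochastic selection of conditioning configurations.

The ICWF ansatz is anchored at an ensemble of configuration-space points
x^alpha.  They are drawn from reduced densities: either independently per
axis from marginals (``mode='marginals'``) or from the joint density via
sequential conditional inverse-CDF sampling (``mode='joint'``), both
deterministic for a given seed.  Within-cell positions are linearly
interpolated from the cumulative distribution so draws are continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, GridWavefunction

__all__ = ["ConfigurationEnsemble", "sample_configurations", "symmetrize_ensemble"]


@dataclass(frozen=True)
class ConfigurationEnsemble:
    """N_c full-coordinate tuples, one column per grid axis."""

    configs: np.ndarray  # (N_c, ndim)
    seed: int | None
    source: str

    @property
    def n_configs(self) -> int:
        return len(self.configs)


def _inverse_cdf_draw(axis: np.ndarray, density: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Continuous inverse-CDF draws from a tabulated 1-D density."""
    d = np.clip(np.asarray(density, float), 0.0, None)
    tot = d.sum()
    if tot <= 0:
        raise ValueError("cannot sample from an identically zero density")
    cdf = np.concatenate([[0.0], np.cumsum(d)]) / tot
    dx = axis[1] - axis[0]
    edges = np.concatenate([[axis[0] - dx / 2], axis + dx / 2])
    return np.interp(u, cdf, edges)


def sample_configurations(density, n_configs: int, seed: int, *,
                          mode: str = "joint", grid: Grid = None) -> ConfigurationEnsemble:
    """Draw ``n_configs`` i.i.d. configurations from a density.

    Parameters
    ----------
    density
        Either a :class:`GridWavefunction` (its |psi|^2 is the joint
        density) or a sequence of per-axis ``(axis, marginal)`` pairs.
    mode
        ``'joint'``: exact sampling from the joint density by chaining
        conditional inverse CDFs axis by axis.  ``'marginals'``: sample
        each axis independently from its marginal.
    """
    if n_configs < 1:
        raise ValueError("n_configs >= 1 required")
    rng = np.random.default_rng(seed)
    if isinstance(density, GridWavefunction):
        grid = density.grid
        rho = density.density()
        src = "wavefunction"
    elif grid is not None:
        rho = np.clip(np.asarray(density, float), 0.0, None)
        if rho.shape != grid.shape:
            raise ValueError("density shape does not match grid")
        src = "array"
    else:
        # per-axis (axis, marginal) pairs: only marginals mode is possible
        pairs = list(density)
        u = rng.random((n_configs, len(pairs)))
        cols = [_inverse_cdf_draw(np.asarray(a, float), m, u[:, i])
                for i, (a, m) in enumerate(pairs)]
        return ConfigurationEnsemble(np.stack(cols, axis=1), seed, "marginals:pairs")

    ndim = grid.ndim
    u = rng.random((n_configs, ndim))
    out = np.empty((n_configs, ndim))
    if mode == "marginals":
        for d in range(ndim):
            marg = rho.sum(axis=tuple(i for i in range(ndim) if i != d))
            out[:, d] = _inverse_cdf_draw(grid.axes[d], marg, u[:, d])
    elif mode == "joint":
        # chain rule: draw axis d from the density conditioned on the cells
        # of the axes already drawn
        for n in range(n_configs):
            cond = rho
            for d in range(ndim):
                marg = cond.sum(axis=tuple(range(1, cond.ndim))) if cond.ndim > 1 else cond
                x = _inverse_cdf_draw(grid.axes[d], marg, u[n, d])
                out[n, d] = x
                if cond.ndim > 1:
                    j = int(np.argmin(np.abs(grid.axes[d] - x)))
                    cond = cond[j]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return ConfigurationEnsemble(out, seed, f"{mode}:{src}")


def symmetrize_ensemble(ens: ConfigurationEnsemble, grid: Grid,
                        blocks: tuple[int, int], tol: float = 1e-12) -> ConfigurationEnsemble:
    """Close an ensemble under the swap of two identical-particle blocks.

    Each configuration whose label-swapped twin is absent gets the twin
    appended, at most doubling the ensemble.
    """
    ax_i, ax_j = grid.block_axes[blocks[0]], grid.block_axes[blocks[1]]
    if len(ax_i) != len(ax_j):
        raise ValueError("swap blocks must have equal dimensionality")
    configs = [c.copy() for c in ens.configs]
    have = {tuple(np.round(c / tol).astype(np.int64)) for c in configs}
    for c in ens.configs:
        t = c.copy()
        t[list(ax_i)], t[list(ax_j)] = c[list(ax_j)], c[list(ax_i)]
        key = tuple(np.round(t / tol).astype(np.int64))
        if key not in have:
            have.add(key)
            configs.append(t)
    return ConfigurationEnsemble(np.array(configs), ens.seed, ens.source + "+sym")
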