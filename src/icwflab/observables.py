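"""Expectation values, reduced densities, spectra, adiabatic populations.

All observables are computed uniformly from either a :class:`GridWavefunction`
(direct quadrature) or an ICWF state (factorized matrix elements; the state
object provides ``expectation``/``reduced_density`` with the same operator
algebra).  Operators are declared as lists of terms::

    [("onebody", label, fn), ("pair", label_i, label_j, fn), ("const", c)]

with the same callable conventions as model potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .grids import Grid, GridWavefunction
from .models import AU_TIME_FS, ModelSystem

__all__ = [
    "ObservableSeries",
    "SpectrumResult",
    "position_operator",
    "dipole_operator",
    "expectation",
    "reduced_density",
    "absorption_spectrum",
    "adiabatic_populations",
    "decoherence_indicator",
]


@dataclass
class ObservableSeries:
    """Time-stamped expectation values with shared time axis (au)."""

    time: np.ndarray
    channels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, name: str, values) -> None:
        values = np.asarray(values)
        if len(values) != len(self.time):
            raise ValueError(f"channel {name}: length mismatch")
        self.channels[name] = values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_au": self.time, "time_fs": self.time * AU_TIME_FS})
        for k, v in self.channels.items():
            v = np.asarray(v)
            if np.iscomplexobj(v):
                v = v.real
            if v.ndim == 1:
                df[k] = v
            else:  # vector channel -> one column per component
                for j in range(v.shape[1]):
                    df[f"{k}_{j}"] = v[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SpectrumResult:
    """Dipole-strength spectrum from a finite-time masked transform."""

    omega: np.ndarray  # au
    strength: np.ndarray
    kick: float
    mask: str = "cos2"
    meta: dict = field(default_factory=dict)

    @property
    def omega_ev(self) -> np.ndarray:
        return self.omega * 27.211386245988

    def peaks(self, prominence_frac: float = 0.05, omega_max: float = None):
        """Peak positions and heights, ordered by frequency."""
        s = self.strength
        sel = slice(None)
        if omega_max is not None:
            sel = self.omega <= omega_max
        idx, _ = find_peaks(np.where(sel, s, 0.0) if omega_max is not None else s,
                            prominence=prominence_frac * np.max(np.abs(s)))
        return self.omega[idx], s[idx]

    def to_csv(self, path) -> None:
        pd.DataFrame({"omega_au": self.omega, "omega_eV": self.omega_ev,
                      "strength": self.strength}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operator algebra


def position_operator(label: str, axis: int = 0):
    return [("onebody", label, lambda c, _ax=axis: c[_ax])]


def dipole_operator(model: ModelSystem):
    """Length-gauge dipole coupling operator of a model (sum of per-block
    coefficients times the block's first coordinate)."""
    return [("onebody", lbl, lambda c, _k=coef: _k * c[0])
            for lbl, coef in model.dipole.items() if coef]


def _operator_on_grid(model: ModelSystem, grid: Grid, terms) -> np.ndarray:
    O = np.zeros(grid.shape)
    for term in terms:
        if term[0] == "const":
            O = O + term[1]
        elif term[0] == "onebody":
            _, lbl, fn = term
            O = O + fn(model._bcast_block_mesh(grid, model.block_index(lbl)))
        elif term[0] == "pair":
            _, li, lj, fn = term
            ci = model._bcast_block_mesh(grid, model.block_index(li))
            cj = model._bcast_block_mesh(grid, model.block_index(lj))
            O = O + fn(ci, cj)
        else:
            raise ValueError(f"unknown operator term {term[0]!r}")
    return O


def expectation(state, terms, model: ModelSystem = None):
    """<O> for a grid state (quadrature) or an ICWF state (factorized)."""
    if isinstance(state, GridWavefunction):
        if model is None:
            raise ValueError("grid-state expectation needs the model")
        O = _operator_on_grid(model, state.grid, terms)
        p = state.psi
        num = np.sum(np.conj(p) * O * p) * state.grid.weight
        den = np.sum(np.abs(p) ** 2) * state.grid.weight
        return (num / den).real
    return state.expectation(terms)


def reduced_density(state, label: str, model: ModelSystem = None, norm: float = 1.0):
    """Marginal density on one block's axes, normalized to ``norm``.

    For the electron density of a two-identical-electron model pass
    ``norm=2`` (the particle-count convention)."""
    if isinstance(state, GridWavefunction):
        if model is None:
            raise ValueError("grid-state reduced density needs the model")
        b = model.block_index(label)
        grid = state.grid
        keep = set(grid.block_axes[b])
        other = tuple(i for i in range(grid.ndim) if i not in keep)
        rho = np.sum(np.abs(state.psi) ** 2, axis=other)
        w_keep = grid.block_weight(b)
        rho = rho * (grid.weight / w_keep)  # integrate out the others
        total = rho.sum() * w_keep
        return rho * (norm / total)
    return state.reduced_density(label, norm=norm)


# ---------------------------------------------------------------------------
# delta-kick absorption spectrum


def absorption_spectrum(time: np.ndarray, dmu: np.ndarray, kick: float,
                        mask: str = "cos2", pad_factor: int = 8) -> SpectrumResult:
    """Linear absorption from the dipole response after an impulsive kick.

    S(w) = w * Im[ integral dt e^{iwt} mask(t) (mu(t) - mu(0))] / kick,
    with a cos^2 mask vanishing smoothly at the final time.
    """
    time = np.asarray(time, float)
    dmu = np.asarray(dmu, float)
    dt = time[1] - time[0]
    if not np.allclose(np.diff(time), dt, rtol=1e-8):
        raise ValueError("spectrum requires a uniform time grid")
    if kick <= 0:
        raise ValueError("kick strength must be positive")
    if mask == "cos2":
        m = np.cos(0.5 * np.pi * (time - time[0]) / (time[-1] - time[0])) ** 2
    elif mask == "none":
        m = np.ones_like(time)
    else:
        raise ValueError(f"unknown mask {mask!r}")
    x = dmu * m
    n = int(pad_factor * len(x))
    amp = np.conj(np.fft.rfft(x, n=n)) * dt  # = integral e^{+iwt} x(t) dt
    omega = 2 * np.pi * np.fft.rfftfreq(n, dt)
    strength = omega * amp.imag / kick
    return SpectrumResult(omega=omega, strength=strength, kick=kick, mask=mask)


# ---------------------------------------------------------------------------
# adiabatic populations and the decoherence indicator
#
# Conventions: electronic blocks precede nuclear blocks in every bundled
# model, so the full wavefunction reshapes to (n_elec, n_nuc).


def _nuclear_projections(psi: GridWavefunction, bopes) -> np.ndarray:
    """chi_n(R) = <Phi_n(.;R)|Psi(.,R)>_elec for every computed surface."""
    if bopes.states is None:
        raise ValueError("BOPES table was computed without electronic states")
    n_e = bopes.states.shape[2]
    p = psi.psi.reshape(n_e, -1)  # (elec, nuc)
    if p.shape[1] != bopes.states.shape[0]:
        raise ValueError("wavefunction / BOPES nuclear grids differ")
    # chi[k, R] = sum_e conj(Phi[R,k,e]) psi[e,R] * w_e
    return np.einsum("rke,er->kr", np.conj(bopes.states), p) * bopes.elec_weight


def adiabatic_populations(psi: GridWavefunction, bopes, n_states: int = None) -> np.ndarray:
    """P_n = integral dR |<Phi_n(.;R)|Psi>|^2 for the lowest surfaces."""
    chi = _nuclear_projections(psi, bopes)
    P = np.sum(np.abs(chi) ** 2, axis=1) * bopes.nuc_weight
    nrm = psi.norm() ** 2
    P = P / nrm
    return P[:n_states] if n_states else P


def coherence_overlap(psi: GridWavefunction, bopes, n: int, m: int) -> float:
    """Normalized overlap (cosine) of the nuclear densities on two surfaces:
    D_nm / sqrt(int rho_n^2 int rho_m^2).  Stays ~1 while the packets ride
    together and drops as they separate, independent of packet spreading."""
    chi = _nuclear_projections(psi, bopes)
    rn = np.abs(chi[n]) ** 2
    rm = np.abs(chi[m]) ** 2
    denom = np.sqrt((rn ** 2).sum() * (rm ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float((rn * rm).sum() / denom)


def decoherence_indicator(psi: GridWavefunction, bopes, n: int, m: int) -> float:
    """Overlap of the nuclear probability densities carried by two adiabatic
    electronic states: D_nm = integral dR |chi_n|^2 |chi_m|^2.

    Vanishes once the nuclear packets on the two surfaces separate."""
    chi = _nuclear_projections(psi, bopes)
    return float(np.sum(np.abs(chi[n]) ** 2 * np.abs(chi[m]) ** 2) * bopes.nuc_weight)
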