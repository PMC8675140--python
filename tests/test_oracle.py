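"""Exact reference solvers: eigenstates, propagation, BOPES, slices."""

import numpy as np
import pytest

from icwflab.grids import Grid, GridWavefunction
from icwflab.models import DOFBlock, LaserPulse, ModelSystem
from icwflab.oracle import (
    SplitOperator,
    compute_bopes,
    conditional_slice,
    exact_eigenstates,
    exact_propagate,
    kinetic_correlation_potential,
)


def harmonic_model(omega=1.0, mass=1.0, label="x"):
    return ModelSystem(
        "ho", (DOFBlock(label, 1, mass),),
        {label: lambda c: 0.5 * mass * omega ** 2 * c[0] ** 2}, (), {label: 1.0})


@pytest.fixture(scope="module")
def ho_grid():
    return Grid.from_specs([(-10.0, 10.0, 160)])


class TestEigenstates:
    def test_harmonic_ladder(self):
        g = Grid.from_specs([(-10.0, 10.0, 640)])
        E, _ = exact_eigenstates(harmonic_model(), g, k=4)
        assert np.allclose(E, [0.5, 1.5, 2.5, 3.5], atol=1e-6)

    def test_separable_2d_energies_add(self):
        m = ModelSystem(
            "ho2", (DOFBlock("x", 1, 1.0), DOFBlock("y", 1, 1.0)),
            {"x": lambda c: 0.5 * c[0] ** 2, "y": lambda c: 2.0 * c[0] ** 2},
            (), {})
        g = Grid.from_specs([(-8.0, 8.0, 256), (-6.0, 6.0, 256)])
        E, _ = exact_eigenstates(m, g, k=3)
        # omega_x = 1, omega_y = 2: levels 1.5, 2.5, 3.5
        assert np.allclose(E, [1.5, 2.5, 3.5], atol=2e-6)

    def test_orthonormal_states(self, ho_grid):
        _, st = exact_eigenstates(harmonic_model(), ho_grid, k=3)
        for i in range(3):
            for j in range(3):
                ov = st[i].inner(st[j])
                assert abs(ov - (i == j)) < 1e-8

    def test_imag_time_agrees_with_sparse(self, ho_grid):
        E_s, _ = exact_eigenstates(harmonic_model(), ho_grid, k=2)
        E_i, _ = exact_eigenstates(harmonic_model(), ho_grid, k=2,
                                   method="imag", tol=1e-12)
        assert np.allclose(E_s, E_i, atol=1e-5)


class TestPropagation:
    def test_stationary_eigenstate_autocorrelation(self, ho_grid):
        m = harmonic_model()
        # spectral-kinetic eigenstate so the propagator sees a true eigenstate
        E, st = exact_eigenstates(m, ho_grid, k=1, method="imag", tol=1e-13)
        series, _ = exact_propagate(m, st[0], 0.02, 10.0, stride=50)
        assert np.all(np.abs(series["autocorr"] - 1.0) < 1e-6)
        assert np.all(np.abs(series["norm"] - 1.0) < 1e-8)

    def test_free_gaussian_spreading_law(self):
        m = ModelSystem("free", (DOFBlock("x", 1, 1.0),),
                        {"x": lambda c: 0.0 * c[0]}, (), {})
        g = Grid.from_specs([(-60.0, 60.0, 512)])
        x = g.axes[0]
        sigma = 1.0
        psi = np.exp(-x ** 2 / (4 * sigma ** 2)).astype(complex)
        wf = GridWavefunction(g, psi, normalize=True)

        def width2(w, t):
            d = w.density()
            d /= d.sum() * g.dx(0)
            m1 = (d * x).sum() * g.dx(0)
            return float((d * (x - m1) ** 2).sum() * g.dx(0))

        series, snaps = exact_propagate(m, wf, 0.01, 6.0, stride=100,
                                        snapshot_times=(6.0,))
        w2 = width2(snaps[6.0], 6.0)
        expected = sigma ** 2 + 6.0 ** 2 / (4 * sigma ** 2)
        assert abs(w2 - expected) < 1e-4 * expected

    def test_kicked_harmonic_dipole_frequency(self, ho_grid):
        m = harmonic_model()
        E, st = exact_eigenstates(m, ho_grid, k=1, method="imag", tol=1e-13)
        kicked = GridWavefunction(ho_grid, st[0].psi * np.exp(1j * 0.05 * ho_grid.axes[0]))
        series, _ = exact_propagate(m, kicked, 0.01, 4 * np.pi, stride=5)
        x_t = series["x"]
        # <x>(t) = (kappa/m omega) sin(omega t): zero crossings at pi, 2pi ...
        assert abs(x_t[0]) < 1e-5
        ref = 0.05 * np.sin(series.time)
        assert np.max(np.abs(x_t - ref)) < 1e-4


class TestBOPES:
    @pytest.fixture(scope="class")
    def sm_small(self):
        from icwflab.models import build_shin_metiu_model
        m = build_shin_metiu_model()
        g = Grid.from_specs([(-22.0, 22.0, 128), (-7.0, 7.0, 32)])
        return m, g, compute_bopes(m, g, k=3, nuclear_block="R")

    def test_surfaces_ordered(self, sm_small):
        _, _, tab = sm_small
        assert np.all(np.diff(tab.energies, axis=1) >= -1e-12)

    def test_states_orthonormal_per_point(self, sm_small):
        _, _, tab = sm_small
        for n in (0, 10, 31):
            ov = tab.states[n] @ tab.states[n].T * tab.elec_weight
            assert np.allclose(ov, np.eye(3), atol=1e-8)

    def test_h2_dissociation_limit(self):
        # eps0(R large) -> 2x the 1D soft-Coulomb atom energy plus the
        # residual soft e-e and bare n-n tails at separation R
        from icwflab.models import build_h2_model
        import scipy.linalg as sla
        import scipy.sparse as sp
        from icwflab.grids import kinetic_matrix

        m = build_h2_model()
        g = Grid.from_specs([(-30.0, 30.0, 96), (-30.0, 30.0, 96), (0.5, 14.0, 16)])
        R = 14.0
        tab = compute_bopes(m, g, k=1, nuclear_block="R",
                            points=np.array([[R]]), keep_states=False)
        # independent-atom reference on the same axis: one electron bound to
        # a single soft-Coulomb well, same reduced mass.  The residual tail
        # terms at separation R: soft e-e and bare n-n repulsion minus the
        # attraction of each electron to the far nucleus.
        x = g.axes[0]
        h = kinetic_matrix(96, g.dx(0), m.block("r1").mass) + sp.diags(
            -1 / np.sqrt(1 + x ** 2))
        e_atom = sla.eigh(h.toarray(), eigvals_only=True,
                          subset_by_index=(0, 0))[0]
        residual = 1 / np.sqrt(2 + R ** 2) + 1 / R - 2 / np.sqrt(1 + R ** 2)
        assert abs(tab.energies[0, 0] - (2 * e_atom + residual)) < 5e-3


class TestConditionalSlices:
    def test_product_state_slice(self):
        g = Grid.from_specs([(-6.0, 6.0, 32), (-6.0, 6.0, 32)])
        m = ModelSystem("toy", (DOFBlock("a", 1, 1.0), DOFBlock("b", 1, 1.0)),
                        {}, (), {})
        x = g.axes[0]
        f = np.exp(-0.5 * x ** 2)
        gfun = np.exp(-0.5 * (x - 1.0) ** 2) * (1 + 0.3 * x)
        wf = GridWavefunction(g, np.multiply.outer(f, gfun), normalize=True)
        d = conditional_slice(wf, m, "a", [0.8])
        j = int(np.argmin(np.abs(x - 0.8)))
        ratio = d.slice_raw / f
        assert np.allclose(ratio, ratio[0])
        # weight equals |g(x_b)| times the norm of f
        expect = abs(gfun[j]) * np.sqrt((f ** 2).sum() * g.dx(0))
        nrm = wf.psi[0, 0] / (f[0] * gfun[0])  # normalization constant
        assert np.isclose(d.weight, abs(nrm) * expect, rtol=1e-10)

    def test_rank1_reassembly(self):
        g = Grid.from_specs([(-6.0, 6.0, 24), (-6.0, 6.0, 24)])
        m = ModelSystem("toy", (DOFBlock("a", 1, 1.0), DOFBlock("b", 1, 1.0)),
                        {}, (), {})
        x = g.axes[0]
        wf = GridWavefunction(
            g, np.multiply.outer(np.exp(-0.5 * x ** 2),
                                 np.exp(-0.5 * (x + 0.5) ** 2)), normalize=True)
        sa = conditional_slice(wf, m, "a", [0.25])
        sb = conditional_slice(wf, m, "b", [0.25])
        ja = int(np.argmin(np.abs(x - 0.25)))
        rebuilt = np.multiply.outer(sa.slice_raw, sb.slice_raw) / wf.psi[ja, ja]
        assert np.allclose(rebuilt, wf.psi, atol=1e-12)

    def test_slice_weights_integrate_to_one(self):
        # Monte-Carlo consistency: E[w^2 / p] = 1 when sampling from |Psi|^2
        from icwflab.models import build_scattering_model
        from icwflab.sampling import sample_configurations

        m = build_scattering_model()
        g = Grid.from_specs([(-4.0, 24.0, 32), (-4.0, 24.0, 32)])
        _, st = exact_eigenstates(m, g, k=1)
        ens = sample_configurations(st[0], 400, seed=9, mode="joint")
        x2 = g.axes[1]
        vals = []
        for cfg in ens.configs:
            d = conditional_slice(st[0], m, "r1", [cfg[1]])
            j = int(np.argmin(np.abs(x2 - cfg[1])))
            marg = (st[0].density()[:, j].sum() * g.dx(0))  # p(x2)/dx2 density
            vals.append(d.weight ** 2 / marg)
        assert abs(np.mean(vals) - 1.0) < 0.05


class TestKineticCorrelation:
    def test_separable_model_eta_constant(self):
        m = ModelSystem(
            "ho2", (DOFBlock("x", 1, 1.0), DOFBlock("y", 1, 1.0)),
            {"x": lambda c: 0.5 * c[0] ** 2, "y": lambda c: 0.5 * c[0] ** 2},
            (), {})
        g = Grid.from_specs([(-7.0, 7.0, 96), (-7.0, 7.0, 96)])
        E, st = exact_eigenstates(m, g, k=1)
        d = kinetic_correlation_potential(st[0], E[0], m, "x", [0.4])
        eta = d.eta[d.eta_mask]
        assert np.max(np.abs(eta - eta[0])) < 1e-5

    def test_exact_eigenstate_residual_small(self):
        from icwflab.models import build_scattering_model
        m = build_scattering_model()
        g = Grid.from_specs([(-6.0, 26.0, 64), (-6.0, 26.0, 64)])
        E, st = exact_eigenstates(m, g, k=1)
        d = kinetic_correlation_potential(st[0], E[0], m, "r1", [11.0])
        assert d.residual < 1e-6

    def test_correlated_state_eta_varies(self):
        from icwflab.models import build_scattering_model
        m = build_scattering_model()
        g = Grid.from_specs([(-6.0, 26.0, 64), (-6.0, 26.0, 64)])
        E, st = exact_eigenstates(m, g, k=1)
        d = kinetic_correlation_potential(st[0], E[0], m, "r1", [11.0])
        eta = d.eta[d.eta_mask]
        assert np.max(np.abs(eta - eta[0])) > 1e-3


class TestEhrenfest:
    def test_harmonic_ensemble_matches_quantum_mean(self):
        # uncoupled harmonic nucleus: Ehrenfest is exact, and the ensemble
        # average of classical trajectories reproduces the quantum <R>(t)
        from icwflab.ehrenfest import ehrenfest_baseline

        m = ModelSystem(
            "e-ho", (DOFBlock("x", 1, 1.0), DOFBlock("R", 1, 100.0)),
            {"x": lambda c: 0.5 * c[0] ** 2,
             "R": lambda c: 0.5 * 100.0 * 0.25 ** 2 * (c[0] - 1.0) ** 2},
            (), {"x": 1.0})
        g = Grid.from_specs([(-8.0, 8.0, 64), (-2.0, 4.0, 32)])
        # displaced nuclear Gaussian: mean starts at 1.4, oscillates at 0.25
        series = ehrenfest_baseline(
            m, g, n_traj=64, seed=3, dt=0.05, t_final=20.0,
            classical_labels=["R"], R_mean=[1.4], R_var=[0.02], stride=20)
        expected = 1.0 + 0.4 * np.cos(0.25 * series.time)
        assert np.max(np.abs(series["R"] - expected)) < 0.4 / np.sqrt(64) * 3

    def test_heavy_mass_limit_is_clamped(self):
        from icwflab.ehrenfest import ehrenfest_baseline
        from icwflab.models import build_shin_metiu_model

        m = build_shin_metiu_model(M=1e12)
        g = Grid.from_specs([(-20.0, 20.0, 96), (-6.0, 6.0, 24)])
        series = ehrenfest_baseline(
            m, g, n_traj=1, seed=1, dt=0.1, t_final=5.0,
            classical_labels=["R"], R_mean=[-2.5], R_var=[1e-12], stride=10)
        assert np.max(np.abs(series["R"] - series["R"][0])) < 1e-5
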