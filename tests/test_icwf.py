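"""ICWF core: conditional bases, matrix elements, eigensolver, propagators."""

import numpy as np
import pytest
import scipy.linalg as sla

from icwflab.grids import Grid, GridWavefunction
from icwflab.icwf import (
    CWFBasis,
    bohmian_velocities,
    conditional_eigenbasis,
    conditional_hamiltonian,
    dyn_state_from_wavefunction,
    dyn_time_step,
    hamiltonian_matrix,
    imag_time_solve,
    overlap_matrix,
    prepare_sta_state,
    pseudo_inverse_apply,
    sta_real_time_step,
)
from icwflab.models import DOFBlock, ModelSystem, build_h2_model, build_scattering_model
from icwflab.oracle import assemble_hamiltonian, exact_eigenstates
from icwflab.sampling import ConfigurationEnsemble, sample_configurations


def noninteracting_model():
    return ModelSystem(
        "sep", (DOFBlock("x", 1, 1.0), DOFBlock("y", 1, 2.0)),
        {"x": lambda c: 0.5 * c[0] ** 2, "y": lambda c: c[0] ** 2}, (), {})


@pytest.fixture(scope="module")
def tiny_scatt():
    m = build_scattering_model()
    g = Grid.from_specs([(-4.0, 24.0, 16), (-4.0, 24.0, 16)])
    E, st = exact_eigenstates(m, g, k=2)
    ens = sample_configurations(st[0], 8, seed=3, mode="joint")
    basis = conditional_eigenbasis(m, g, ens, M=3)
    return m, g, E, st, basis


class TestConditionalHamiltonian:
    def test_symmetric(self, tiny_scatt):
        m, g, *_ = tiny_scatt
        h = conditional_hamiltonian(m, g, 0, np.array([1.0, 3.0])).toarray()
        assert np.max(np.abs(h - h.T)) < 1e-12

    def test_alpha_independent_for_noninteracting(self):
        m = noninteracting_model()
        g = Grid.from_specs([(-6.0, 6.0, 32), (-6.0, 6.0, 32)])
        h1 = conditional_hamiltonian(m, g, 0, np.array([0.0, -2.0]))
        h2 = conditional_hamiltonian(m, g, 0, np.array([0.0, +1.7]))
        assert abs((h1 - h2).toarray()).max() < 1e-14

    def test_clamped_partner_far_away(self):
        # electron block of the H2 model with the partner electron far out:
        # the conditional potential approaches the two-well e-n attraction
        m = build_h2_model()
        g = Grid.from_specs([(-10.0, 10.0, 64), (-10.0, 10.0, 64), (0.5, 4.0, 16)])
        R = 2.0
        W = m.conditional_potential(g, 0, [None, (np.array(500.0),), (np.array(R),)])
        x = g.axes[0]
        two_well = -(1 / np.sqrt(1 + (x - R / 2) ** 2) + 1 / np.sqrt(1 + (x + R / 2) ** 2))
        assert np.max(np.abs(W - two_well)) < 3e-3


class TestConditionalEigenbasis:
    def test_harmonic_nodal_counts(self):
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 96), (-8.0, 8.0, 96)])
        ens = ConfigurationEnsemble(np.array([[0.0, 0.0]]), 0, "manual")
        basis = conditional_eigenbasis(m, g, ens, M=4)
        for nu in range(4):
            v = basis.Psi[0][nu].real
            signs = np.sign(v[np.abs(v) > 1e-3 * np.abs(v).max()])
            nodes = int(np.sum(signs[1:] != signs[:-1]))
            assert nodes == nu

    def test_basis_size(self, tiny_scatt):
        *_, basis = tiny_scatt
        assert basis.size == 8 * 3
        assert basis.Psi[0].shape == (24, 16)

    def test_rows_normalized(self, tiny_scatt):
        *_, basis = tiny_scatt
        for b in range(2):
            n = np.sum(np.abs(basis.Psi[b]) ** 2, axis=1) * basis.grid.block_weight(b)
            assert np.allclose(n, 1.0, atol=1e-12)


class TestMatrices:
    def test_overlap_unit_diagonal_psd(self, tiny_scatt):
        *_, basis = tiny_scatt
        S = overlap_matrix(basis)
        assert np.allclose(np.diag(S).real, 1.0, atol=1e-12)
        assert sla.eigvalsh(S).min() > -1e-10

    def test_orthogonal_factor_zeroes_entry(self):
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 64), (-8.0, 8.0, 64)])
        ens = ConfigurationEnsemble(np.array([[0.0, 0.0]]), 0, "manual")
        basis = conditional_eigenbasis(m, g, ens, M=2)
        S = overlap_matrix(basis)
        # alpha=0 and alpha=1 differ in both factors (nu=0 vs nu=1 states,
        # orthogonal within each block), so S_01 = 0
        assert abs(S[0, 1]) < 1e-10

    def test_brute_force_2block(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        S = overlap_matrix(basis)
        H = hamiltonian_matrix(basis)
        Hfull = assemble_hamiltonian(m, g)
        prods = np.array([np.multiply.outer(basis.Psi[0][a], basis.Psi[1][a]).ravel()
                          for a in range(basis.size)])
        S_bf = np.conj(prods) @ prods.T * g.weight
        H_bf = np.conj(prods) @ (Hfull @ prods.T) * g.weight
        assert np.max(np.abs(S - S_bf)) < 1e-10
        assert np.max(np.abs(H - H_bf)) < 1e-10

    def test_brute_force_3block_h2(self):
        m = build_h2_model()
        g = Grid.from_specs([(-6.0, 6.0, 16), (-6.0, 6.0, 16), (0.5, 4.0, 16)])
        E, st = exact_eigenstates(m, g, k=1)
        ens = sample_configurations(st[0], 6, seed=1, mode="joint")
        basis = conditional_eigenbasis(m, g, ens, M=2)
        S = overlap_matrix(basis)
        H = hamiltonian_matrix(basis)
        Hfull = assemble_hamiltonian(m, g)
        prods = np.array([
            np.multiply.outer(np.multiply.outer(
                basis.Psi[0][a], basis.Psi[1][a]), basis.Psi[2][a]).ravel()
            for a in range(basis.size)])
        S_bf = np.conj(prods) @ prods.T * g.weight
        H_bf = np.conj(prods) @ (Hfull @ prods.T) * g.weight
        assert np.max(np.abs(S - S_bf)) < 1e-10
        assert np.max(np.abs(H - H_bf)) < 1e-10

    def test_hamiltonian_hermitian(self, tiny_scatt):
        *_, basis = tiny_scatt
        H = hamiltonian_matrix(basis)
        assert np.max(np.abs(H - H.conj().T)) < 1e-10

    def test_single_configuration_rayleigh(self):
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 96), (-8.0, 8.0, 96)])
        ens = ConfigurationEnsemble(np.array([[0.3, -0.2]]), 0, "manual")
        basis = conditional_eigenbasis(m, g, ens, M=1)
        H = hamiltonian_matrix(basis)
        # product of the two ground conditional states; the y block has
        # V = y^2 and mass 2, i.e. omega_y = 1: E = 0.5 + 0.5
        assert abs(H[0, 0].real - 1.0) < 1e-4


class TestCouplingMatrix:
    def test_onebody_cancellation_noninteracting(self):
        from icwflab.icwf import coupling_matrix

        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 64), (-8.0, 8.0, 64)])
        ens = ConfigurationEnsemble(
            np.array([[0.0, 0.5], [0.7, -0.4], [1.1, 0.2]]), 0, "manual")
        basis = conditional_eigenbasis(m, g, ens, M=2)
        H = hamiltonian_matrix(basis)
        G = coupling_matrix(basis, basis.configs)
        assert np.max(np.abs(H - G)) < 1e-10
        assert np.all(np.isfinite(G))

    def test_single_term_pure_phase(self):
        # N_c M = 1: i dC/dt = S^+(H-G) C with any interacting model leaves
        # |C| constant (the coupled part reduces to a number)
        m = build_scattering_model()
        g = Grid.from_specs([(-4.0, 24.0, 32), (-4.0, 24.0, 32)])
        _, st = exact_eigenstates(m, g, k=1)
        ens = sample_configurations(st[0], 1, seed=5, mode="joint")
        state = dyn_state_from_wavefunction(m, g, st[0], ens)
        c0 = abs(state.C[0])
        for _ in range(40):
            dyn_time_step(state, 0.02)
        assert abs(abs(state.C[0]) - c0) < 1e-8


class TestPseudoInverse:
    def test_identity(self):
        v = np.arange(4.0) + 1j
        out, rank = pseudo_inverse_apply(np.eye(4), v)
        assert np.allclose(out, v) and rank == 4

    def test_rank_one(self):
        u = np.array([1.0, 1.0]) / np.sqrt(2)
        S = np.outer(u, u)
        out, rank = pseudo_inverse_apply(S, np.array([1.0, 0.0]))
        assert rank == 1
        assert np.allclose(out, u * (u @ [1.0, 0.0]))

    def test_duplicate_configuration_energy_invariant(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        S, H = overlap_matrix(basis), hamiltonian_matrix(basis)
        res, _ = imag_time_solve(S, H, 1, seed=0)
        # duplicate the first configuration's CWFs
        Psi_dup = [np.vstack([P, P[:1]]) for P in basis.Psi]
        basis2 = CWFBasis(basis.model, g, Psi_dup,
                          np.vstack([basis.configs, basis.configs[:1]]),
                          basis.n_configs, basis.M)
        with pytest.warns(UserWarning):
            res2, _ = imag_time_solve(overlap_matrix(basis2),
                                      hamiltonian_matrix(basis2), 1, seed=0)
        assert abs(res[0][0] - res2[0][0]) < 1e-8


class TestImagTime:
    def test_in_span_exactness(self):
        # basis containing the exact ground state: variational exactness
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 96), (-8.0, 8.0, 96)])
        E, st = exact_eigenstates(m, g, k=1)
        ens = ConfigurationEnsemble(np.array([[0.0, 0.0], [0.5, 0.5]]), 0, "m")
        basis = conditional_eigenbasis(m, g, ens, M=1)
        res, _ = imag_time_solve(overlap_matrix(basis), hamiltonian_matrix(basis),
                                 1, seed=0)
        assert res[0][0] - E[0] < 1e-8  # and >= by the variational bound
        assert res[0][0] >= E[0] - 1e-8

    def test_energies_nondecreasing(self, tiny_scatt):
        *_, basis = tiny_scatt
        res, _ = imag_time_solve(overlap_matrix(basis), hamiltonian_matrix(basis),
                                 4, seed=1)
        es = [e for e, _ in res]
        assert np.all(np.diff(es) >= -1e-10)

    def test_variational_bound(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        res, _ = imag_time_solve(overlap_matrix(basis), hamiltonian_matrix(basis),
                                 1, seed=1)
        assert res[0][0] >= E[0] - 1e-8


class TestStaRealTime:
    def test_eigenvector_stationary(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        state = prepare_sta_state(basis, np.ones(basis.size, complex))
        metric = state.cache["metric"]
        Ht = metric.project(state.cache["H0"])
        vals, W = sla.eigh(Ht)
        C = metric.X @ W[:, 0]
        state.C = C
        S = state.cache["S"]
        ref = np.conj(C) @ S @ C
        for _ in range(200):
            sta_real_time_step(state, 0.02)
        ov = abs(np.conj(state.C) @ S @ C) / abs(ref)
        assert abs(ov - 1.0) < 1e-8

    def test_norm_conserved_1000_steps(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        res, _ = imag_time_solve(overlap_matrix(basis), hamiltonian_matrix(basis),
                                 1, seed=1)
        state = prepare_sta_state(basis, res[0][1])
        from icwflab.icwf import apply_kick
        state = apply_kick(state, 0.01)
        n0 = state.norm2()
        for _ in range(1000):
            sta_real_time_step(state, 0.02)
        assert abs(state.norm2() - n0) < 1e-8


class TestBohmianVelocities:
    def test_plane_wave(self):
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 128), (-8.0, 8.0, 128)])
        x = g.axes[0]
        p1, p2 = 0.7, -0.3
        P0 = (np.exp(-0.25 * x ** 2 + 1j * p1 * x))[None, :]
        P1 = (np.exp(-0.25 * x ** 2 + 1j * p2 * x))[None, :]
        basis = CWFBasis(m, g, [P0 / np.sqrt((abs(P0) ** 2).sum() * g.dx(0)),
                                P1 / np.sqrt((abs(P1) ** 2).sum() * g.dx(1))],
                         np.array([[0.0, 0.0]]), 1, 1)
        v, _ = bohmian_velocities(basis, np.array([1.0 + 0j]),
                                  np.array([[0.0, 0.0]]))
        assert abs(v[0, 0] - p1 / 1.0) < 1e-5
        assert abs(v[0, 1] - p2 / 2.0) < 1e-5

    def test_real_state_zero_velocity(self, tiny_scatt):
        m, g, E, st, basis = tiny_scatt
        C = np.ones(basis.size, complex)
        # conditional eigenstates of a real Hamiltonian are real: v = 0
        pts = basis.configs[:4]
        v, _ = bohmian_velocities(basis, C, pts)
        assert np.max(np.abs(v)) < 1e-10

    def test_free_gaussian_ensemble_spreading(self):
        # trajectories transported by the Bohmian flow of a spreading free
        # Gaussian reproduce the analytic growth of the position variance
        m = ModelSystem("free2", (DOFBlock("x", 1, 1.0), DOFBlock("y", 1, 1.0)),
                        {"x": lambda c: 0.0 * c[0], "y": lambda c: 0.0 * c[0]},
                        (), {})
        g = Grid.from_specs([(-40.0, 40.0, 256), (-40.0, 40.0, 256)])
        x = g.axes[0]
        sigma = 1.0
        psi = np.exp(-x ** 2 / (4 * sigma ** 2)).astype(complex)
        psi0 = GridWavefunction(g, np.multiply.outer(psi, psi), normalize=True)
        ens = sample_configurations(psi0, 300, seed=2, mode="joint")
        state = dyn_state_from_wavefunction(m, g, psi0, ens)
        T = 3.0
        for _ in range(int(T / 0.05)):
            dyn_time_step(state, 0.05)
        var = state.trajectories[:, 0].var()
        expected = sigma ** 2 * (1 + T ** 2 / (4 * sigma ** 4))
        assert abs(var - expected) / expected < 0.2  # Monte-Carlo tolerance


class TestDynMode:
    def test_noninteracting_product_matches_oracle(self):
        # mean-field-separable dynamics: a single configuration is exact
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 256), (-8.0, 8.0, 256)])
        x = g.axes[0]
        # displaced Gaussians evolving in their harmonic wells
        f = np.exp(-0.5 * (x - 0.7) ** 2).astype(complex)
        h = np.exp(-np.sqrt(2) / 2 * (x + 0.4) ** 2).astype(complex)
        psi0 = GridWavefunction(g, np.multiply.outer(f, h), normalize=True)
        ens = ConfigurationEnsemble(np.array([[0.7, -0.4]]), 0, "manual")
        state = dyn_state_from_wavefunction(m, g, psi0, ens)
        from icwflab.oracle import exact_propagate
        T, dt = 2.0, 0.005
        series, snaps = exact_propagate(m, psi0, dt, T, stride=50,
                                        snapshot_times=(T,))
        for _ in range(int(T / dt)):
            dyn_time_step(state, dt)
        from icwflab.observables import reduced_density
        rho_ex = reduced_density(snaps[T], "x", model=m)
        rho_ic = state.reduced_density("x")
        assert np.max(np.abs(rho_ex - rho_ic)) < 1e-5

    def test_field_free_eigenstate_static(self):
        # eigenstate of a separable model (the regime where the Hermitian
        # conditional propagation is exact): observables stay put
        m = noninteracting_model()
        g = Grid.from_specs([(-8.0, 8.0, 96), (-8.0, 8.0, 96)])
        E, st = exact_eigenstates(m, g, k=1)
        ens = ConfigurationEnsemble(np.array([[0.0, 0.0], [0.4, -0.3]]), 0, "m")
        state = dyn_state_from_wavefunction(m, g, st[0], ens)
        x0 = state.expectation([("onebody", "x", lambda c: c[0])])
        rho0 = state.reduced_density("x")
        for _ in range(1000):
            dyn_time_step(state, 0.01)
        x1 = state.expectation([("onebody", "x", lambda c: c[0])])
        assert abs(x1 - x0) < 1e-4
        assert np.max(np.abs(state.reduced_density("x") - rho0)) < 1e-4
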