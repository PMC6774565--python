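"""Latent-dynamics identification and reduced-order simulation."""

import warnings

import numpy as np
import pytest

from ecmdfl.adhesion import AdhesionState, build_mapping_matrix, fa_forces
from ecmdfl.augmented import LatentBasis
from ecmdfl.latent import LatentDynamicsModel, LatentDynamicsResults, assemble_Dk


def _planted_data(rng, m_c=10, m_e=10, nu=6, n=4000, dt=0.0):
    """Stable planted linear system with exact derivatives (no integration)."""
    A = -np.eye(m_c) + 0.1 * rng.normal(size=(m_c, m_c))
    B = rng.normal(size=(m_c, nu))
    C = 0.5 * rng.normal(size=(m_c, m_e))
    G = -np.eye(m_e) + 0.1 * rng.normal(size=(m_e, m_e))
    z_c = rng.normal(size=(n, m_c))
    u = rng.normal(size=(n, nu))
    z_e = rng.normal(size=(n, m_e))
    dz_c = z_c @ A.T + u @ B.T + z_e @ C.T
    dz_e_resid = z_e @ G.T
    return (A, B, C, G), LatentDynamicsModel(
        z_c=z_c, u=u, z_e_cell=z_e, dz_c=dz_c, z_e=z_e, dz_e_resid=dz_e_resid,
    )


def test_planted_parameters_recovered_exactly(rng):
    """Exact-derivative data from a stable planted system: entrywise 1e-6."""
    (A, B, C, G), model = _planted_data(rng)
    res = model.fit(ridge=0.0)
    np.testing.assert_allclose(res.A, A, atol=1e-6)
    np.testing.assert_allclose(res.B, B, atol=1e-6)
    np.testing.assert_allclose(res.C, C, atol=1e-6)
    np.testing.assert_allclose(res.G, G, atol=1e-6)
    np.testing.assert_allclose(res.a0, 0.0, atol=1e-8)
    assert res.resid_rms_cell < 1e-10 and res.resid_rms_ecm < 1e-10


def test_sample_duplication_leaves_estimate_unchanged(rng):
    _, model = _planted_data(rng, n=500)
    res1 = model.fit(ridge=0.0)
    dup = LatentDynamicsModel(
        z_c=np.vstack([model.z_c] * 2), u=np.vstack([model.u] * 2),
        z_e_cell=np.vstack([model.z_e_cell] * 2), dz_c=np.vstack([model.dz_c] * 2),
        z_e=np.vstack([model.z_e] * 2), dz_e_resid=np.vstack([model.dz_e_resid] * 2),
    )
    res2 = dup.fit(ridge=0.0)
    np.testing.assert_allclose(res1.A, res2.A, atol=1e-9)
    np.testing.assert_allclose(res1.G, res2.G, atol=1e-9)


def test_unexcited_input_warns_and_ridge_kills_B(rng):
    _, model = _planted_data(rng, n=800)
    model.u[:] = 0.0
    model.dz_c = model.z_c @ (-np.eye(10)).T  # consistent with zero input
    model.z_e_cell[:] = 0.0
    model.dz_e_resid = model.z_e @ (-np.eye(10)).T
    with pytest.warns(UserWarning, match="identically zero"):
        res = model.fit(ridge=1e-6)
    assert np.abs(res.B).max() < 1e-6


def test_spectral_abscissa_warning_on_expansive_fit(rng):
    (A, B, C, G), model = _planted_data(rng, n=2000)
    model.dz_c = model.z_c @ (+0.5 * np.eye(10)).T  # plant an unstable A
    model.u[:] = 0.0
    model.z_e_cell[:] = 0.0
    with pytest.warns(UserWarning):
        res = model.fit(ridge=1e-9)
    sa, _ = res.spectral_abscissa()
    assert sa > 0


def _toy_basis(N_c, N_e, m_c=None, m_e=None, rng=None):
    """Orthonormal random bases over the full augmented dimensions."""
    rng = rng or np.random.default_rng(0)
    dc, de = 9 * N_c, 6 * N_e
    m_c = m_c or dc
    m_e = m_e or de
    Qc, _ = np.linalg.qr(rng.normal(size=(dc, m_c)))
    Qe, _ = np.linalg.qr(rng.normal(size=(de, m_e)))
    return LatentBasis(
        V_c=Qc, V_e=Qe, evals_c=np.ones(m_c), evals_e=np.ones(m_e),
        mean_c=np.zeros(dc), mean_e=np.zeros(de), N_c=N_c, N_e=N_e,
    )


def test_assemble_Dk_no_bonds_zero():
    basis = _toy_basis(3, 5, m_c=4, m_e=4)
    st = AdhesionState(bonds={0: {}})
    P = build_mapping_matrix(st, 0, 5, 3)
    np.testing.assert_array_equal(assemble_Dk(P, basis, 10.0), 0.0)


def test_assemble_Dk_full_rank_matches_physical_injection(rng):
    """With full-rank bases, D^k z_c equals the projected per-bond FA scatter."""
    N_c, N_e, D_e = 3, 5, 7.0
    basis = _toy_basis(N_c, N_e, rng=rng)
    st = AdhesionState(bonds={0: {0: (2, 4, 0.0), 1: (4, 2, 0.0)}})
    P = build_mapping_matrix(st, 0, N_e, N_c)
    Dk = assemble_Dk(P, basis, D_e)

    cell = rng.normal(size=(N_c, 3))
    ecm = rng.normal(size=(N_e, 3))
    Fc, Fe = fa_forces(st, [cell], ecm)
    zeta_c = np.concatenate([cell.ravel(), np.zeros(3 * N_c), Fc[0].ravel()])
    z_c = basis.V_c.T @ zeta_c
    expected = basis.V_x_e.T @ Fe.ravel() / D_e
    np.testing.assert_allclose(Dk @ z_c, expected, atol=1e-10)


def test_bond_change_is_low_rank_update():
    basis = _toy_basis(4, 6)
    st0 = AdhesionState(bonds={0: {0: (1, 3, 0.0)}})
    st1 = AdhesionState(bonds={0: {0: (1, 3, 0.0), 2: (5, 3, 0.0)}})
    D0 = assemble_Dk(build_mapping_matrix(st0, 0, 6, 4), basis, 1.0)
    D1 = assemble_Dk(build_mapping_matrix(st1, 0, 6, 4), basis, 1.0)
    assert np.linalg.matrix_rank(D1 - D0, tol=1e-10) <= 3


def test_zero_intercept_model_keeps_zero_state(linear_world):
    """z = 0 with u = 0 and zero intercepts is an equilibrium of the rollout."""
    rng = np.random.default_rng(5)
    m_c, m_e = 4, 4
    world, cfg = linear_world
    N_c = world.cells[0].n_nodes
    N_e = world.net.n_nodes
    basis = _toy_basis(N_c, N_e, m_c=m_c, m_e=m_e, rng=rng)
    # a stable model with zero intercepts and no coupling (no bonds)
    model = LatentDynamicsModel(
        z_c=np.zeros((2, m_c)), u=np.zeros((2, 3 * N_c)), z_e_cell=np.zeros((2, m_e)),
        dz_c=np.zeros((2, m_c)), z_e=np.zeros((2, m_e)), dz_e_resid=np.zeros((2, m_e)),
        basis=basis,
    )
    res = LatentDynamicsResults(
        model=model, A=-np.eye(m_c), B=np.zeros((m_c, 3 * N_c)), C=np.zeros((m_c, m_e)),
        G=-np.eye(m_e), a0=np.zeros(m_c), g0=np.zeros(m_e), ridge=0.0,
        resid_rms_cell=0.0, resid_rms_ecm=0.0, data_rms_cell=0.0, data_rms_ecm=0.0,
    )
    w = world.copy()
    w.adhesions = AdhesionState(bonds={0: {}}, p_on=0.0, d_break=1e9)
    # make the stored mean the exact initial augmented state so z(0) = 0
    from ecmdfl.simulate import compute_forces

    forces = compute_forces(w)
    basis.mean_c = np.concatenate([
        w.cell_coords[0].ravel(), forces["f_ce"][0].ravel(), forces["f_fa_c"][0].ravel()
    ])
    basis.mean_e = np.concatenate([w.ecm_coords.ravel(), forces["f_elas_e"].ravel()])
    traj = res.simulate(w, cfg, t_end=5.0)
    np.testing.assert_allclose(traj.cell_xs[-1], traj.cell_xs[0], atol=1e-10)


def test_divergence_detector_raises(linear_world):
    world, cfg = linear_world
    N_c = world.cells[0].n_nodes
    N_e = world.net.n_nodes
    basis = _toy_basis(N_c, N_e, m_c=3, m_e=3)
    model = LatentDynamicsModel(
        z_c=np.zeros((2, 3)), u=np.zeros((2, 3 * N_c)), z_e_cell=np.zeros((2, 3)),
        dz_c=np.zeros((2, 3)), z_e=np.zeros((2, 3)), dz_e_resid=np.zeros((2, 3)),
        basis=basis,
    )
    res = LatentDynamicsResults(
        model=model, A=50.0 * np.eye(3), B=np.zeros((3, 3 * N_c)), C=np.zeros((3, 3)),
        G=50.0 * np.eye(3), a0=np.ones(3), g0=np.ones(3), ridge=0.0,
        resid_rms_cell=0.0, resid_rms_ecm=0.0, data_rms_cell=0.0, data_rms_ecm=0.0,
    )
    with pytest.raises(FloatingPointError, match="diverged"):
        res.simulate(world, cfg, t_end=40.0, divergence_norm=1e6)


def test_summary_reports_dimensions(rng):
    _, model = _planted_data(rng, n=300)
    model.basis = _toy_basis(2, 3, m_c=10, m_e=10)
    res = model.fit(ridge=1e-9)
    s = res.summary()
    assert "m_c = 10" in s and "ridge" in s and "spectral abscissa" in s
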