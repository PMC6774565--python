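"""Augmented-state assembly, covariance, PCA bases, projection."""

import numpy as np
import pytest

from ecmdfl.augmented import (
    build_augmented_cell,
    build_augmented_ecm,
    build_basis,
    covariance,
    pca_basis,
    project,
    reconstruct,
    split_augmented_cell,
    split_augmented_ecm,
)
from ecmdfl.config import SimulationConfig
from ecmdfl.fixtures import make_fixture
from ecmdfl.simulate import simulate


@pytest.fixture(scope="module")
def short_traj():
    world, cfg = make_fixture("tiny_cylinder", seed=0)
    cfg.t_end = 40.0
    return simulate(world, cfg)


def test_augmented_roundtrip_bit_exact(short_traj):
    Nc = short_traj.cell_xs.shape[2]
    Ne = short_traj.ecm_xs.shape[1]
    zc = build_augmented_cell(short_traj)
    x, fce, ffa = split_augmented_cell(zc, Nc)
    np.testing.assert_array_equal(x.reshape(short_traj.cell_xs.shape), short_traj.cell_xs)
    np.testing.assert_array_equal(fce.reshape(short_traj.f_ce.shape), short_traj.f_ce)
    np.testing.assert_array_equal(ffa.reshape(short_traj.f_fa_c.shape), short_traj.f_fa_c)
    ze = build_augmented_ecm(short_traj)
    xe, fel = split_augmented_ecm(ze, Ne)
    np.testing.assert_array_equal(xe.reshape(short_traj.ecm_xs.shape), short_traj.ecm_xs)
    np.testing.assert_array_equal(fel.reshape(short_traj.f_elas_e.shape), short_traj.f_elas_e)


def test_two_cells_share_one_ecm_vector():
    world, cfg = make_fixture("two_cell_cylinder", seed=0)
    cfg.t_end = 5.0
    traj = simulate(world, cfg)
    zc = build_augmented_cell(traj)
    ze = build_augmented_ecm(traj)
    assert zc.shape[1] == 2            # one augmented vector per cell
    assert ze.ndim == 2                # a single shared ECM vector per frame


def test_covariance_identical_samples_zero():
    X = np.tile([1.0, 2.0, 3.0], (6, 1))
    np.testing.assert_allclose(covariance(X), 0.0, atol=1e-15)


def test_covariance_matches_direct_summation(rng):
    X = rng.normal(size=(3, 5))
    C = covariance(X)
    mu = X.mean(axis=0)
    expect = sum(np.outer(x - mu, x - mu) for x in X) / 3
    np.testing.assert_allclose(C, expect, atol=1e-12)
    # symmetric PSD
    np.testing.assert_allclose(C, C.T, atol=1e-14)
    assert np.linalg.eigvalsh(C).min() > -1e-12


def test_covariance_rank_equals_excited_linear_modes(rng):
    """Linear observables add no rank: [x; Kx] has the rank of x alone."""
    n, d = 200, 6
    modes = rng.normal(size=(3, d))
    coeff = rng.normal(size=(n, 3))
    x = coeff @ modes
    K = rng.normal(size=(d, d))
    zeta = np.hstack([x, x @ K.T])
    C = covariance(zeta)
    ev = np.linalg.eigvalsh(C)
    rank = (ev > ev.max() * 1e-10).sum()
    assert rank == 3


def test_pca_identity_covariance():
    V, lam = pca_basis(np.eye(3), 3)
    np.testing.assert_allclose(lam, 1.0)
    np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-12)


def test_pca_diagonal_top_mode():
    V, lam = pca_basis(np.diag([4.0, 1.0, 0.0]), 1)
    assert lam[0] == pytest.approx(4.0)
    np.testing.assert_allclose(np.abs(V[:, 0]), [1, 0, 0], atol=1e-12)


def test_pca_matches_full_eigendecomposition(rng):
    A = rng.normal(size=(20, 20))
    C = A @ A.T / 20
    V, lam = pca_basis(C, 5)
    full = np.sort(np.linalg.eigvalsh(C))[::-1]
    np.testing.assert_allclose(lam, full[:5], rtol=1e-10)
    retained = lam.sum() / np.trace(C)
    assert retained == pytest.approx(full[:5].sum() / full.sum())
    # best rank-m approximation property (Eckart-Young)
    approx = V @ np.diag(lam) @ V.T
    assert np.linalg.norm(C - approx) <= np.linalg.norm(C) + 1e-12


def test_pca_m_exceeding_rank_raises():
    C = np.diag([1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="rank"):
        pca_basis(C, 3)


def test_retained_variance_monotone_in_m(rng):
    A = rng.normal(size=(15, 15))
    C = A @ A.T
    fracs = []
    for m in range(1, 10):
        _, lam = pca_basis(C, m)
        fracs.append(lam.sum() / np.trace(C))
    assert (np.diff(fracs) >= -1e-14).all()


def test_project_reconstruct_identities(rng):
    d, m = 12, 4
    Q, _ = np.linalg.qr(rng.normal(size=(d, m)))
    mean = rng.normal(size=d)
    # vector in span reconstructs exactly
    zeta = mean + Q @ rng.normal(size=m)
    z = project(zeta, Q, mean)
    np.testing.assert_allclose(reconstruct(z, Q, mean), zeta, atol=1e-10)
    # zero latent vector gives the stored mean
    np.testing.assert_allclose(reconstruct(np.zeros(m), Q, mean), mean, atol=1e-14)
    # residual orthogonal to the basis
    zeta2 = rng.normal(size=d)
    resid = zeta2 - reconstruct(project(zeta2, Q, mean), Q, mean)
    np.testing.assert_allclose(Q.T @ resid, 0.0, atol=1e-10)


def test_full_rank_basis_reconstruction_rmse(short_traj):
    """At full data rank the basis reconstructs every frame to numerical zero."""
    Nc = short_traj.cell_xs.shape[2]
    Ne = short_traj.ecm_xs.shape[1]
    zc = build_augmented_cell(short_traj).reshape(-1, 9 * Nc)
    ze = build_augmented_ecm(short_traj)

    def rank(X):
        Xc = X - X.mean(axis=0)
        ev = np.linalg.eigvalsh(Xc.T @ Xc / len(Xc))
        return int((ev > ev.max() * 1e-15).sum())

    basis = build_basis(zc, ze, rank(zc), rank(ze), Nc, Ne)
    zhat = reconstruct(project(zc, basis.V_c, basis.mean_c), basis.V_c, basis.mean_c)
    rmse = np.sqrt(np.mean((zhat - zc) ** 2))
    assert rmse < 1e-8


def test_gram_trick_matches_direct_covariance_path(rng):
    """Thin-data eigen-solve (n < d) agrees with the dense covariance route."""
    n, dc, de = 30, 9 * 6, 6 * 8  # fewer samples than dimensions
    Xc_data = rng.normal(size=(n, dc))
    Xe_data = rng.normal(size=(n, de))
    basis = build_basis(Xc_data, Xe_data, 5, 5, N_c=6, N_e=8)
    np.testing.assert_allclose(basis.V_c.T @ basis.V_c, np.eye(5), atol=1e-10)
    Xcc = Xc_data - Xc_data.mean(axis=0)
    ev_dense = np.sort(np.linalg.eigvalsh(Xcc.T @ Xcc / n))[::-1][:5]
    np.testing.assert_allclose(basis.evals_c[:5], ev_dense, rtol=1e-8)
    # retained spans agree: projections of the data coincide up to sign
    Vd = np.linalg.eigh(Xcc.T @ Xcc / n)[1][:, ::-1][:, :5]
    overlap = np.abs(np.linalg.svd(basis.V_c.T @ Vd, compute_uv=False))
    np.testing.assert_allclose(overlap, 1.0, atol=1e-8)
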