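"""Augmented-state assembly, covariance and PCA bases for model reduction.

The nonlinear force channels are promoted to auxiliary state variables:
each cell's augmented vector stacks membrane coordinates, cortical-elastic
forces and adhesion forces (9*Nc entries); the ECM's stacks node
coordinates and fiber elastic forces (6*Ne entries).  Lamellipodial forces
stay outside as inputs, and the ECM-side adhesion forces are excluded
because they are determined by the cells through the mapping matrices.
PCA of the pooled, mean-centred samples yields orthonormal bases onto
which the linear latent dynamics are projected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrajectoryDataset

__all__ = [
    "build_augmented_cell",
    "build_augmented_ecm",
    "split_augmented_cell",
    "split_augmented_ecm",
    "covariance",
    "pca_basis",
    "LatentBasis",
    "build_basis",
    "project",
    "reconstruct",
]


def build_augmented_cell(traj: TrajectoryDataset) -> np.ndarray:
    """Cell augmented vectors (x; F_cort-elas; F_fa), shape (F, K, 9*Nc)."""
    F, K, Nc, _ = traj.cell_xs.shape
    out = np.concatenate(
        [traj.cell_xs.reshape(F, K, -1), traj.f_ce.reshape(F, K, -1), traj.f_fa_c.reshape(F, K, -1)],
        axis=2,
    )
    return out


def build_augmented_ecm(traj: TrajectoryDataset) -> np.ndarray:
    """ECM augmented vectors (x; F_elas), shape (F, 6*Ne)."""
    F = traj.n_frames
    return np.concatenate([traj.ecm_xs.reshape(F, -1), traj.f_elas_e.reshape(F, -1)], axis=1)


def split_augmented_cell(zeta: np.ndarray, Nc: int):
    """Inverse of :func:`build_augmented_cell` for a single vector or batch."""
    zeta = np.asarray(zeta)
    if zeta.shape[-1] != 9 * Nc:
        raise ValueError(f"expected last dimension {9 * Nc}")
    x = zeta[..., : 3 * Nc]
    f_ce = zeta[..., 3 * Nc : 6 * Nc]
    f_fa = zeta[..., 6 * Nc :]
    return x, f_ce, f_fa


def split_augmented_ecm(zeta: np.ndarray, Ne: int):
    zeta = np.asarray(zeta)
    if zeta.shape[-1] != 6 * Ne:
        raise ValueError(f"expected last dimension {6 * Ne}")
    return zeta[..., : 3 * Ne], zeta[..., 3 * Ne :]


def covariance(samples: np.ndarray) -> np.ndarray:
    """Data covariance C = (1/n) sum of outer products of mean-centred rows.

    ``samples`` is (n, d) with n >= 2; the centring mean is the global mean
    over the same rows (pooled over cells, runs and time by the caller).
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D (n, d) array")
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / n


def pca_basis(C: np.ndarray, m: int, *, variance_warn: float = 0.95):
    """Top-m eigenpairs of a symmetric PSD matrix with a fixed sign convention.

    Returns (V, evals) with orthonormal columns, eigenvalues sorted
    descending and clipped at zero, and each eigenvector oriented so its
    largest-magnitude entry is positive.  Raises if ``m`` exceeds the
    numerical rank; warns (via ``warnings``) when the retained variance
    fraction is below ``variance_warn``.
    """
    import warnings

    C = np.asarray(C, dtype=float)
    d = C.shape[0]
    if C.shape != (d, d):
        raise ValueError("covariance must be square")
    if not (1 <= m <= d):
        raise ValueError(f"m must be in [1, {d}]")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    tol = max(d, 1) * np.finfo(float).eps * max(evals[0], 1e-300)
    rank = int(np.sum(evals > tol))
    if m > max(rank, 1):
        raise ValueError(f"m = {m} exceeds numerical rank {rank} of the covariance")
    V = evecs[:, :m].copy()
    lam = evals[:m].copy()
    # deterministic sign: largest-|entry| positive
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(m)])
    signs[signs == 0] = 1.0
    V *= signs
    tot = evals.sum()
    retained = lam.sum() / tot if tot > 0 else 1.0
    if retained < variance_warn:
        warnings.warn(
            f"retained variance {retained:.3f} below {variance_warn:.2f} with m = {m}",
            stacklevel=2,
        )
    return V, lam


@dataclass
class LatentBasis:
    """PCA bases and centring statistics for cell and ECM augmented states."""

    V_c: np.ndarray       # (9*Nc, m_c)
    V_e: np.ndarray       # (6*Ne, m_e)
    evals_c: np.ndarray   # all eigenvalues (descending)
    evals_e: np.ndarray
    mean_c: np.ndarray    # (9*Nc,)
    mean_e: np.ndarray    # (6*Ne,)
    N_c: int
    N_e: int

    @property
    def m_c(self) -> int:
        return self.V_c.shape[1]

    @property
    def m_e(self) -> int:
        return self.V_e.shape[1]

    # named sub-blocks of the cell basis
    @property
    def V_x_c(self) -> np.ndarray:
        return self.V_c[: 3 * self.N_c]

    @property
    def V_fce_c(self) -> np.ndarray:
        return self.V_c[3 * self.N_c : 6 * self.N_c]

    @property
    def V_ffa_c(self) -> np.ndarray:
        return self.V_c[6 * self.N_c :]

    @property
    def V_x_e(self) -> np.ndarray:
        return self.V_e[: 3 * self.N_e]

    @property
    def V_felas_e(self) -> np.ndarray:
        return self.V_e[3 * self.N_e :]

    def retained_variance(self) -> tuple[float, float]:
        tc = self.evals_c.sum()
        te = self.evals_e.sum()
        rc = self.evals_c[: self.m_c].sum() / tc if tc > 0 else 1.0
        re = self.evals_e[: self.m_e].sum() / te if te > 0 else 1.0
        return float(rc), float(re)

    def validate(self) -> None:
        for V in (self.V_c, self.V_e):
            g = V.T @ V
            if not np.allclose(g, np.eye(V.shape[1]), atol=1e-10):
                raise ValueError("basis columns are not orthonormal")


def build_basis(zeta_c: np.ndarray, zeta_e: np.ndarray, m_c: int, m_e: int,
                N_c: int, N_e: int) -> LatentBasis:
    """PCA bases from pooled augmented samples.

    ``zeta_c``: (n_samples, 9*Nc) pooled over cells, runs and frames;
    ``zeta_e``: (n_samples_e, 6*Ne) pooled over runs and frames.
    """
    zeta_c = zeta_c.reshape(-1, zeta_c.shape[-1])
    zeta_e = zeta_e.reshape(-1, zeta_e.shape[-1])
    mean_c = zeta_c.mean(axis=0)
    mean_e = zeta_e.mean(axis=0)

    def _eig(X, mean):
        n, d = X.shape
        Xc = X - mean
        if n < d:
            # thin-data regime: SVD of the centred data matrix, equivalent to
            # eigen-solving the smaller Gram matrix but numerically cleaner
            _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            full = np.zeros(d)
            full[: len(s)] = s**2 / n
            return Vt.T, full
        C = (Xc.T @ Xc) / n
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        return evecs[:, order], np.clip(evals[order], 0.0, None)

    Vc_full, ev_c = _eig(zeta_c, mean_c)
    Ve_full, ev_e = _eig(zeta_e, mean_e)
    for m, ev, tag in ((m_c, ev_c, "cell"), (m_e, ev_e, "ecm")):
        rank = int(np.sum(ev > ev.max() * 1e-15)) if ev.max() > 0 else 0
        if m > max(rank, 1):
            raise ValueError(f"m_{tag[0]} = {m} exceeds data rank {rank} for the {tag} covariance")

    def _sign_fix(V):
        idx = np.argmax(np.abs(V), axis=0)
        s = np.sign(V[idx, np.arange(V.shape[1])])
        s[s == 0] = 1.0
        return V * s

    def _orth(V):
        # Gram-trick columns with tiny eigenvalues can drift off orthonormal;
        # QR restores it without changing the retained span
        Q, R = np.linalg.qr(V)
        return Q * np.sign(np.diag(R))

    basis = LatentBasis(
        V_c=_sign_fix(_orth(Vc_full[:, :m_c])),
        V_e=_sign_fix(_orth(Ve_full[:, :m_e])),
        evals_c=ev_c, evals_e=ev_e, mean_c=mean_c, mean_e=mean_e, N_c=N_c, N_e=N_e,
    )
    basis.validate()
    return basis


def project(zeta: np.ndarray, V: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """z = V^T (zeta - mean); works on single vectors or leading batch axes."""
    zeta = np.asarray(zeta)
    if zeta.shape[-1] != V.shape[0]:
        raise ValueError("dimension mismatch between zeta and basis")
    return (zeta - mean) @ V


def reconstruct(z: np.ndarray, V: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """zeta_hat = V z + mean; the residual is orthogonal to the basis columns."""
    z = np.asarray(z)
    if z.shape[-1] != V.shape[1]:
        raise ValueError("dimension mismatch between z and basis")
    return z @ V.T + mean
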