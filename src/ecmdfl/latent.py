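"""Reduced-order latent dynamics: identification and superposition simulation.

After dual-faceted augmentation and PCA projection, each cell obeys

    dz_c/dt = A z_c + B u + C z_e

and the shared ECM obeys

    dz_e/dt = G z_e + sum_k [ D^k z_c^k + b^k ]

where A, B, C, G are identified by (ridge) least squares from single-cell
training runs, while the couplings D^k = V_x_e^T (1/D_e) P_map^k V_ffa_c
are assembled analytically from the known adhesion mapping matrices and
refreshed whenever bonds change.  ``b^k`` is the companion offset carrying
the centring mean of the adhesion-force block through the same mapping;
it is likewise known, not regressed.  Adding a cell therefore never
requires re-identification: only the D^k set and the sum change.

The API follows the model/results idiom: :class:`LatentDynamicsModel` is
built from training trajectories plus a basis, ``fit()`` returns a
:class:`LatentDynamicsResults` carrying the matrices, residual diagnostics
and a ``summary()``; reduced-order simulation hangs off the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .adhesion import build_mapping_matrix, update_adhesions
from .augmented import (
    LatentBasis,
    build_augmented_cell,
    build_augmented_ecm,
    project,
)
from .cells import lamellipodial_input, max_stiffness_direction, update_polarity
from .config import SimulationConfig
from .simulate import TrajectoryDataset, World, compute_forces

__all__ = ["assemble_Dk", "LatentDynamicsModel", "LatentDynamicsResults"]


def assemble_Dk(P_map: csr_matrix, basis: LatentBasis, D_e: float) -> np.ndarray:
    """Latent coupling D^k = V_x_e^T (1/D_e) P_map^k V_ffa_c, shape (m_e, m_c).

    Must be re-assembled whenever the bond set (hence P_map^k) changes; each
    added or removed bond is a rank-<=3 update.
    """
    if P_map.shape != (3 * basis.N_e, 3 * basis.N_c):
        raise ValueError("mapping matrix shape inconsistent with basis")
    return basis.V_x_e.T @ (P_map @ basis.V_ffa_c) / D_e


def _coupling_offset(P_map: csr_matrix, basis: LatentBasis, D_e: float) -> np.ndarray:
    """Known constant b^k = V_x_e^T (1/D_e) P_map^k mu_ffa (centring carry-over)."""
    mu_ffa = basis.mean_c[6 * basis.N_c :]
    return basis.V_x_e.T @ (P_map @ mu_ffa) / D_e


def _inject(Vxe_blocks: np.ndarray, ba: np.ndarray, f3: np.ndarray, D_e: float) -> np.ndarray:
    """-(1/D_e) * sum over bonds of V_x_e[j-block]^T f3[i]  (P blocks are -I)."""
    i, j = ba[:, 0], ba[:, 1]
    return -np.einsum("nkm,nk->m", Vxe_blocks[j], f3[i]) / D_e


def _coupling_term(bond_arrays, basis: LatentBasis, D_e: float, z_c_frame: np.ndarray) -> np.ndarray:
    """sum_k (D^k z_c^k + b^k) for one frame, computed matrix-free per bond."""
    out = np.zeros(basis.m_e)
    Vxe_blocks = basis.V_x_e.reshape(basis.N_e, 3, basis.m_e)
    mu_ffa = basis.mean_c[6 * basis.N_c :]
    for k, ba in enumerate(bond_arrays):
        if len(ba) == 0:
            continue
        f3 = (basis.V_ffa_c @ z_c_frame[k] + mu_ffa).reshape(-1, 3)  # reconstructed FA forces
        out += _inject(Vxe_blocks, ba, f3, D_e)
    return out


@dataclass
class LatentDynamicsResults:
    """Identified latent matrices with diagnostics; simulation entry point."""

    model: "LatentDynamicsModel"
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    a0: np.ndarray        # cell-equation intercept (carries the centring means)
    g0: np.ndarray        # ECM-equation intercept
    ridge: float
    resid_rms_cell: float
    resid_rms_ecm: float
    data_rms_cell: float
    data_rms_ecm: float

    @property
    def basis(self) -> LatentBasis:
        return self.model.basis

    def spectral_abscissa(self) -> tuple[float, float]:
        sa = float(np.max(np.linalg.eigvals(self.A).real))
        sg = float(np.max(np.linalg.eigvals(self.G).real))
        return sa, sg

    def summary(self) -> str:
        sa, sg = self.spectral_abscissa()
        rc, re = self.basis.retained_variance()
        lines = [
            "Latent cell-ECM dynamics (dual-faceted linearization + PCA reduction)",
            "=" * 70,
            f"latent dimensions        m_c = {self.basis.m_c}, m_e = {self.basis.m_e}"
            f"  (total {self.basis.m_c + self.basis.m_e})",
            f"retained variance        cell {rc:.6f}, ECM {re:.6f}",
            f"training samples         cell eq {self.model.n_samples_cell},"
            f" ECM eq {self.model.n_samples_ecm}",
            f"ridge parameter          {self.ridge:.3e}",
            f"residual RMS (cell eq)   {self.resid_rms_cell:.6e}"
            f"  (data RMS {self.data_rms_cell:.6e})",
            f"residual RMS (ECM eq)    {self.resid_rms_ecm:.6e}"
            f"  (data RMS {self.data_rms_ecm:.6e})",
            f"spectral abscissa        A: {sa:+.6f} 1/s, G: {sg:+.6f} 1/s",
            "=" * 70,
        ]
        if sa >= 0 or sg >= 0:
            lines.append("WARNING: identified dynamics not strictly dissipative "
                         "(non-negative spectral abscissa)")
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def simulate(
        self,
        world0: World,
        config: SimulationConfig,
        t_end: float | None = None,
        divergence_norm: float = 1e9,
    ) -> TrajectoryDataset:
        """Reduced-order superposition simulation from a full-order initial state.

        Each cell's latent state evolves under the shared identified
        matrices; cells couple only through the ECM latent state.  Per
        sampling step the membrane/ECM geometry is reconstructed from the
        latent states to (i) recompute lamellipodial inputs through the
        polarity loop, (ii) run the stochastic adhesion update and refresh
        the couplings.  Raises ``FloatingPointError`` when the latent norm
        exceeds ``divergence_norm`` (unstable identified model).
        """
        basis = self.basis
        h = config.sample_interval
        n_frames = int(round((t_end if t_end is not None else config.t_end) / h)) + 1
        rng = np.random.default_rng(config.seed)

        world = world0.copy()
        K = world.n_cells
        Nc = basis.N_c
        Ne = basis.N_e
        D_e = world.net.D_e

        forces = compute_forces(world)
        z_c = np.empty((K, basis.m_c))
        for k in range(K):
            zeta = np.concatenate([
                world.cell_coords[k].ravel(), forces["f_ce"][k].ravel(), forces["f_fa_c"][k].ravel(),
            ])
            z_c[k] = project(zeta, basis.V_c, basis.mean_c)
        zeta_e = np.concatenate([world.ecm_coords.ravel(), forces["f_elas_e"].ravel()])
        z_e = project(zeta_e, basis.V_e, basis.mean_e)

        times = np.empty(n_frames)
        cell_xs = np.empty((n_frames, K, Nc, 3))
        ecm_xs = np.empty((n_frames, Ne, 3))
        f_ce = np.empty((n_frames, K, Nc, 3))
        f_fa_c = np.empty((n_frames, K, Nc, 3))
        f_elas_e = np.empty((n_frames, Ne, 3))
        u_rec = np.empty((n_frames, K, Nc, 3))
        pol = np.empty((n_frames, K, 3))
        bonds: list = []
        bond_rest: list = []

        mu_c = basis.mean_c
        mu_e = basis.mean_e
        for f in range(n_frames):
            # reconstruct world geometry and force channels from latent states
            zeta_c_hat = z_c @ basis.V_c.T + mu_c          # (K, 9Nc)
            zeta_e_hat = z_e @ basis.V_e.T + mu_e          # (6Ne,)
            x_cells = zeta_c_hat[:, : 3 * Nc].reshape(K, Nc, 3)
            x_ecm = zeta_e_hat[: 3 * Ne].reshape(Ne, 3)
            # fixed boundary nodes stay put regardless of reconstruction noise
            fixed = world.net.boundary_fixed
            x_ecm[fixed] = world0.ecm_coords[fixed]

            times[f] = f * h
            cell_xs[f] = x_cells
            ecm_xs[f] = x_ecm
            f_ce[f] = zeta_c_hat[:, 3 * Nc : 6 * Nc].reshape(K, Nc, 3)
            f_fa_c[f] = zeta_c_hat[:, 6 * Nc :].reshape(K, Nc, 3)
            f_elas_e[f] = zeta_e_hat[3 * Ne :].reshape(Ne, 3)
            for k in range(K):
                pol[f, k] = world.polarities[k].d_pol
            bond_arrays = [world.adhesions.bond_array(k) for k in range(K)]
            bonds.append(bond_arrays)
            bond_rest.append([world.adhesions.bond_rest(k) for k in range(K)])

            # lamellipodial inputs from reconstructed geometry (polarity loop)
            us = np.empty((K, 3 * Nc))
            for k in range(K):
                us[k] = lamellipodial_input(world.cells[k], world.polarities[k], x_cells[k])
            u_rec[f] = us.reshape(K, Nc, 3)
            if f == n_frames - 1:
                break

            coup = _coupling_term(bond_arrays, basis, D_e, z_c)
            z_c = z_c + h * (z_c @ self.A.T + us @ self.B.T
                             + np.outer(np.ones(K), self.C @ z_e + self.a0))
            z_e = z_e + h * (self.G @ z_e + self.g0 + coup)
            if not np.all(np.isfinite(z_e)) or np.linalg.norm(z_e) > divergence_norm \
               or np.linalg.norm(z_c) > divergence_norm:
                raise FloatingPointError(f"latent state diverged at frame {f}")

            # kinetics on reconstructed geometry
            world.cell_coords = [x_cells[k].copy() for k in range(K)]
            world.ecm_coords = x_ecm.copy()
            world.adhesions = update_adhesions(
                world.adhesions, world.cell_coords, world.ecm_coords, rng,
                fixed_mask=world.net.boundary_fixed,
            )
            new_pol = []
            for k, p in enumerate(world.polarities):
                centroid = world.cell_coords[k].mean(axis=0)
                try:
                    dms = max_stiffness_direction(
                        world.net, world.ecm_coords, centroid, world.sensing_radius,
                        fallback=p.d_pol,
                    )
                except ValueError:
                    dms = p.d_pol
                new_pol.append(update_polarity(p, dms, h))
            world.polarities = new_pol

        return TrajectoryDataset(
            times=times, cell_xs=cell_xs, ecm_xs=ecm_xs, f_ce=f_ce, f_fa_c=f_fa_c,
            f_elas_e=f_elas_e, u=u_rec, bonds=bonds, bond_rest=bond_rest, polarity=pol,
            config=config, seed=config.seed,
        )


class LatentDynamicsModel:
    """Pooled latent-space regression dataset for the cell and ECM equations.

    Build with :meth:`from_trajectories` (projects training runs, estimates
    time derivatives by forward differences at the sampling interval, and
    subtracts the analytically known adhesion couplings from the ECM
    targets) or directly from latent arrays, e.g. for planted-system
    recovery studies.  ``fit`` performs the two independent least-squares
    problems.
    """

    def __init__(
        self,
        z_c: np.ndarray,        # (n, m_c) pooled cell latent samples
        u: np.ndarray,          # (n, 3*Nc) matching inputs
        z_e_cell: np.ndarray,   # (n, m_e) ECM latent seen by each cell sample
        dz_c: np.ndarray,       # (n, m_c) cell latent derivatives
        z_e: np.ndarray,        # (n_e, m_e) pooled ECM latent samples
        dz_e_resid: np.ndarray, # (n_e, m_e) dz_e minus known couplings
        basis: LatentBasis | None = None,
        dt: float = 1.0,
    ):
        self.z_c = np.asarray(z_c, dtype=float)
        self.u = np.asarray(u, dtype=float)
        self.z_e_cell = np.asarray(z_e_cell, dtype=float)
        self.dz_c = np.asarray(dz_c, dtype=float)
        self.z_e = np.asarray(z_e, dtype=float)
        self.dz_e_resid = np.asarray(dz_e_resid, dtype=float)
        self.basis = basis
        self.dt = dt
        n = len(self.z_c)
        if not (len(self.u) == len(self.z_e_cell) == len(self.dz_c) == n):
            raise ValueError("cell-equation arrays must share their first dimension")
        if len(self.z_e) != len(self.dz_e_resid):
            raise ValueError("ECM-equation arrays must share their first dimension")

    @property
    def n_samples_cell(self) -> int:
        return len(self.z_c)

    @property
    def n_samples_ecm(self) -> int:
        return len(self.z_e)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_trajectories(cls, trajs: list[TrajectoryDataset], basis: LatentBasis,
                          D_e: float | None = None) -> "LatentDynamicsModel":
        """Assemble the pooled training dataset from nonlinear training runs.

        Derivatives are forward differences of the latent samples at the
        sampling interval, making the identified model the exact one-step
        Euler map whenever the underlying dynamics are linear.  The last
        frame of each run carries no derivative and is dropped.
        """
        rows_zc, rows_u, rows_zec, rows_dzc = [], [], [], []
        rows_ze, rows_dze = [], []
        if D_e is None:
            D_e = trajs[0].config.params.D_e if trajs[0].config else 10.0
        for traj in trajs:
            h = float(traj.times[1] - traj.times[0])
            zc = project(build_augmented_cell(traj), basis.V_c, basis.mean_c)   # (F,K,m_c)
            ze = project(build_augmented_ecm(traj), basis.V_e, basis.mean_e)    # (F,m_e)
            F, K, _ = zc.shape
            dzc = (zc[1:] - zc[:-1]) / h
            dze = (ze[1:] - ze[:-1]) / h
            # subtract the exact FA injection: P_map^k applied to the recorded
            # membrane adhesion forces (known matrices x known data, no fit)
            coup = np.empty((F - 1, basis.m_e))
            Vxe_blocks = basis.V_x_e.reshape(basis.N_e, 3, basis.m_e)
            for t in range(F - 1):
                acc = np.zeros(basis.m_e)
                for k in range(K):
                    ba = traj.bonds[t][k]
                    if len(ba):
                        acc += _inject(Vxe_blocks, ba, traj.f_fa_c[t, k], D_e)
                coup[t] = acc
            for k in range(K):
                rows_zc.append(zc[:-1, k])
                rows_u.append(traj.u[:-1, k].reshape(F - 1, -1))
                rows_zec.append(ze[:-1])
                rows_dzc.append(dzc[:, k])
            rows_ze.append(ze[:-1])
            rows_dze.append(dze - coup)
        return cls(
            z_c=np.vstack(rows_zc), u=np.vstack(rows_u), z_e_cell=np.vstack(rows_zec),
            dz_c=np.vstack(rows_dzc), z_e=np.vstack(rows_ze), dz_e_resid=np.vstack(rows_dze),
            basis=basis, dt=float(trajs[0].times[1] - trajs[0].times[0]),
        )

    # ------------------------------------------------------------------ #
    @staticmethod
    def _ridge_solve(X: np.ndarray, Y: np.ndarray, ridge: float,
                     intercept: bool = False) -> np.ndarray:
        """Solve min ||X T - Y||^2 + lam ||T||^2 with trace-scaled lam.

        With ``intercept`` a trailing ones column is appended and left
        unpenalised; the returned matrix has p (+1) rows.
        """
        p = X.shape[1]
        if intercept:
            X = np.hstack([X, np.ones((len(X), 1))])
        q = X.shape[1]
        gram = X.T @ X
        if ridge == 0.0:
            rank = np.linalg.matrix_rank(gram)
            if rank < q:
                raise np.linalg.LinAlgError(
                    f"regressor rank {rank} < {q}; use a positive ridge parameter"
                )
            return np.linalg.solve(gram, X.T @ Y)
        lam = ridge * np.trace(gram) / max(p, 1)
        P = lam * np.eye(q)
        if intercept:
            P[-1, -1] = 0.0
        return np.linalg.solve(gram + P, X.T @ Y)

    def fit(self, ridge: float = 1e-8, resid_warn_ratio: float = 0.5,
            intercept: bool = True) -> LatentDynamicsResults:
        """Identify A, B, C (cell equation) and G (ECM equation).

        The two regressions are independent; couplings D^k are never
        regressed.  Because the latent states are centred, the true
        augmented dynamics are affine in z; with ``intercept`` (default)
        each regression carries an unpenalised constant column absorbing
        the centring means.  Warns when the lamellipodial input channel is
        unexcited (B indeterminate, driven to ~0 by the ridge) and when a
        residual RMS exceeds ``resid_warn_ratio`` times the target RMS.
        """
        m_c = self.z_c.shape[1]
        m_e = self.z_e.shape[1]
        nu = self.u.shape[1]

        if np.max(np.abs(self.u)) == 0.0:
            warnings.warn(
                "input channel u is identically zero in the training data; "
                "B is indeterminate and the ridge drives it toward zero",
                stacklevel=2,
            )
            if ridge == 0.0:
                ridge = 1e-12

        X1 = np.hstack([self.z_c, self.u, self.z_e_cell])
        T1 = self._ridge_solve(X1, self.dz_c, ridge, intercept=intercept)
        A = T1[:m_c].T
        B = T1[m_c : m_c + nu].T
        C = T1[m_c + nu : m_c + nu + m_e].T
        a0 = T1[-1].copy() if intercept else np.zeros(m_c)
        pred1 = X1 @ T1[: m_c + nu + m_e] + (a0 if intercept else 0.0)
        resid1 = self.dz_c - pred1

        T2 = self._ridge_solve(self.z_e, self.dz_e_resid, ridge, intercept=intercept)
        G = T2[:m_e].T
        g0 = T2[-1].copy() if intercept else np.zeros(m_e)
        resid2 = self.dz_e_resid - (self.z_e @ T2[:m_e] + (g0 if intercept else 0.0))

        def _rms(a):
            return float(np.sqrt(np.mean(a**2))) if a.size else 0.0

        res = LatentDynamicsResults(
            model=self, A=A, B=B, C=C, G=G, a0=a0, g0=g0, ridge=ridge,
            resid_rms_cell=_rms(resid1), resid_rms_ecm=_rms(resid2),
            data_rms_cell=_rms(self.dz_c), data_rms_ecm=_rms(self.dz_e_resid),
        )
        for tag, r, d in (("cell", res.resid_rms_cell, res.data_rms_cell),
                          ("ECM", res.resid_rms_ecm, res.data_rms_ecm)):
            if d > 0 and r / d > resid_warn_ratio:
                warnings.warn(f"{tag}-equation residual RMS is {r / d:.2f} of the target RMS",
                              stacklevel=2)
        sa, sg = res.spectral_abscissa()
        if sa >= 0 or sg >= 0:
            warnings.warn(
                f"identified dynamics not strictly dissipative (abscissa A {sa:+.3e}, G {sg:+.3e})",
                stacklevel=2,
            )
        return res
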