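"""Comparison models: global first-order Taylor and trajectory-piecewise-linear.

Both baselines replace the complete smooth vector field — membrane
cortical elasticity, ECM fiber elasticity and the adhesion springs at a
frozen bond topology — by algebraic linearizations, with the lamellipodial
input frozen at its reference value.  A global Taylor expansion therefore
yields a single linear time-invariant system; the TPWL baseline blends
many such local models selected along a training trajectory (regaining
some of the discrete adhesion/polarity adaptivity through the switching),
with normalised Gaussian kernel weights.  The reduced latent model, by
contrast, re-runs the adhesion and polarity loops online, which is exactly
the structural advantage the comparison is meant to expose.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix

from .adhesion import fa_forces
from .cells import cortical_elastic_forces, lamellipodial_input
from .config import SimulationConfig
from .network import ecm_elastic_forces
from .simulate import TrajectoryDataset, World, world_from_frame

__all__ = ["fd_jacobian", "TaylorModel", "TPWLModel"]


def fd_jacobian(fun, x0: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``fun`` at ``x0`` (flat in/out).

    Per-coordinate step ``rel_step * max(1, |x_i|)``.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    n = len(x0)
    f0 = np.asarray(fun(x0)).ravel()
    J = np.empty((len(f0), n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x0[i]))
        xp = x0.copy(); xp[i] += h
        xm = x0.copy(); xm[i] -= h
        J[:, i] = (np.asarray(fun(xp)).ravel() - np.asarray(fun(xm)).ravel()) / (2 * h)
    return J


class _FrozenField:
    """Smooth force field of a world with the bond topology held fixed.

    Maps the concatenated free coordinates [cells..., ecm] to nodal force
    sums divided by the damping constants, i.e. the velocity field of the
    overdamped dynamics (fixed boundary rows are zero).  The frozen
    lamellipodial input of the reference world is included as a constant.
    """

    def __init__(self, world: World):
        self.world = world
        self.K = world.n_cells
        self.Nc = world.cells[0].n_nodes if self.K else 0
        self.Ne = world.net.n_nodes
        self.free = ~world.net.boundary_fixed
        self.u_ref = [
            lamellipodial_input(world.cells[k], world.polarities[k], world.cell_coords[k])
            .reshape(-1, 3)
            for k in range(self.K)
        ]

    def pack(self, cell_coords, ecm_coords) -> np.ndarray:
        parts = [c.ravel() for c in cell_coords] + [ecm_coords.ravel()]
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray):
        cells = [
            x[3 * self.Nc * k : 3 * self.Nc * (k + 1)].reshape(-1, 3)
            for k in range(self.K)
        ]
        ecm = x[3 * self.Nc * self.K :].reshape(-1, 3)
        return cells, ecm

    def velocity(self, x: np.ndarray) -> np.ndarray:
        """Full velocity field (smooth part + frozen input) at packed state x."""
        cells, ecm = self.unpack(x)
        w = self.world
        out = []
        F_fa_c, F_fa_e = fa_forces(w.adhesions, cells, ecm)
        for k in range(self.K):
            F = cortical_elastic_forces(w.cells[k], cells[k]) + F_fa_c[k] + self.u_ref[k]
            out.append((F / w.cells[k].D_c).ravel())
        Fe = (ecm_elastic_forces(w.net, ecm) + F_fa_e) / w.net.D_e
        Fe[~self.free] = 0.0
        out.append(Fe.ravel())
        return np.concatenate(out)


def _linearize(field: _FrozenField, rel_step: float = 1e-6):
    """Affine model (x0, v0, J sparse) of the frozen velocity field."""
    x0 = field.pack(field.world.cell_coords, field.world.ecm_coords)
    v0 = field.velocity(x0)
    J = fd_jacobian(field.velocity, x0, rel_step)
    J[np.abs(J) < 1e-13] = 0.0
    return x0, v0, csr_matrix(J)


def _integrate_affine(world0: World, config: SimulationConfig, rhs,
                      n_frames: int) -> TrajectoryDataset:
    """Euler integration of ``rhs(x)`` with full-simulator recording layout.

    Force channels recorded are the frozen-topology nonlinear evaluations at
    the recorded states (so downstream metrics see physical forces); bonds
    and polarity stay at their reference values.
    """
    K = world0.n_cells
    Nc = world0.cells[0].n_nodes if K else 0
    Ne = world0.net.n_nodes
    field = _FrozenField(world0)
    x = field.pack(world0.cell_coords, world0.ecm_coords)
    h = config.sample_interval
    sub = config.record_every
    dt = config.dt

    times = np.empty(n_frames)
    cell_xs = np.empty((n_frames, K, Nc, 3))
    ecm_xs = np.empty((n_frames, Ne, 3))
    f_ce = np.empty((n_frames, K, Nc, 3))
    f_fa_c = np.empty((n_frames, K, Nc, 3))
    f_elas_e = np.empty((n_frames, Ne, 3))
    u_rec = np.empty((n_frames, K, Nc, 3))
    pol = np.empty((n_frames, K, 3))
    bonds = []
    bond_rest = []
    ref_bonds = [world0.adhesions.bond_array(k) for k in range(K)]
    ref_rest = [world0.adhesions.bond_rest(k) for k in range(K)]

    for f in range(n_frames):
        cells, ecm = field.unpack(x)
        times[f] = f * h
        ecm_xs[f] = ecm
        f_elas_e[f] = ecm_elastic_forces(world0.net, ecm)
        F_fa_list, _ = fa_forces(world0.adhesions, cells, ecm)
        for k in range(K):
            cell_xs[f, k] = cells[k]
            f_ce[f, k] = cortical_elastic_forces(world0.cells[k], cells[k])
            f_fa_c[f, k] = F_fa_list[k]
            u_rec[f, k] = field.u_ref[k]
            pol[f, k] = world0.polarities[k].d_pol
        bonds.append(ref_bonds)
        bond_rest.append(ref_rest)
        if f == n_frames - 1:
            break
        for _ in range(sub):
            x = x + dt * rhs(x)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite baseline state at frame {f}")

    return TrajectoryDataset(
        times=times, cell_xs=cell_xs, ecm_xs=ecm_xs, f_ce=f_ce, f_fa_c=f_fa_c,
        f_elas_e=f_elas_e, u=u_rec, bonds=bonds, bond_rest=bond_rest, polarity=pol,
        config=config, seed=config.seed,
    )


class TaylorModel:
    """Global first-order Taylor linearization about the initial configuration.

    v(x) ~= v(x0) + J (x - x0) for the complete smooth vector field with
    the reference bond topology and lamellipodial input held fixed: a
    single LTI model.  At t = 0 its forces equal the nonlinear ones
    exactly.
    """

    def __init__(self, world0: World, rel_step: float = 1e-6):
        self.world0 = world0.copy()
        self.field = _FrozenField(self.world0)
        self.x0, self.v0, self.J = _linearize(self.field, rel_step)

    def velocity(self, x: np.ndarray) -> np.ndarray:
        return self.v0 + self.J @ (x - self.x0)

    def simulate(self, config: SimulationConfig, t_end: float | None = None) -> TrajectoryDataset:
        n_frames = int(round((t_end if t_end is not None else config.t_end)
                             / config.sample_interval)) + 1
        return _integrate_affine(self.world0, config, self.velocity, n_frames)


class TPWLModel:
    """Trajectory-piecewise-linear approximation of the nonlinear system.

    Linearization points are selected greedily along a training trajectory
    (a new point each time the state advances one arc-length increment,
    sized to yield about ``kappa`` points).  Each point carries its own
    frozen bond topology and input from that frame.  The simulated vector
    field is the normalised-Gaussian-kernel-weighted combination of the
    local affine models; with kappa = 1 it reduces to the Taylor baseline
    about that single point.
    """

    def __init__(self, world0: World, traj: TrajectoryDataset, kappa: int = 100,
                 bandwidth: float | None = None, rel_step: float = 1e-6):
        if kappa < 1:
            raise ValueError("kappa must be >= 1")
        self.world0 = world0.copy()
        F = traj.n_frames
        states = np.hstack([traj.cell_xs.reshape(F, -1), traj.ecm_xs.reshape(F, -1)])
        self.point_indices = self._greedy_indices(states, kappa)

        self._points = []
        for fi in self.point_indices:
            w = world_from_frame(world0, traj, fi)
            field = _FrozenField(w)
            self._points.append(_linearize(field, rel_step))
        self._pts = np.array([p[0] for p in self._points])
        if bandwidth is None:
            if len(self._pts) > 1:
                d = np.linalg.norm(np.diff(self._pts, axis=0), axis=1)
                bandwidth = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
            else:
                bandwidth = 1.0
        self.bandwidth = bandwidth

    @staticmethod
    def _greedy_indices(states: np.ndarray, kappa: int) -> np.ndarray:
        if kappa >= len(states):
            return np.arange(len(states))
        seg = np.linalg.norm(np.diff(states, axis=0), axis=1)
        total = seg.sum()
        if total == 0:
            return np.array([0])
        thresh = total / kappa
        idx = [0]
        acc = 0.0
        for i, d in enumerate(seg):
            acc += d
            if acc >= thresh and len(idx) < kappa:
                idx.append(i + 1)
                acc = 0.0
        return np.array(sorted(set(idx)))

    def weights(self, x: np.ndarray) -> np.ndarray:
        d2 = np.sum((self._pts - x) ** 2, axis=1)
        w = np.exp(-0.5 * (d2 - d2.min()) / self.bandwidth**2)
        return w / w.sum()

    def velocity(self, x: np.ndarray) -> np.ndarray:
        w = self.weights(x)
        out = np.zeros_like(x)
        for wi, (x0, v0, J) in zip(w, self._points):
            if wi < 1e-12:
                continue
            out += wi * (v0 + J @ (x - x0))
        return out

    def simulate(self, config: SimulationConfig, t_end: float | None = None) -> TrajectoryDataset:
        n_frames = int(round((t_end if t_end is not None else config.t_end)
                             / config.sample_interval)) + 1
        return _integrate_affine(self.world0, config, self.velocity, n_frames)
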