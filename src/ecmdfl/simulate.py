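"""Coupled overdamped dynamics of cells and the ECM fiber network.

Every node obeys force balance between elastic / adhesion / active forces
and viscous damping, giving first-order (inertia-free) dynamics
``dx/dt = (sum of forces) / D`` integrated with explicit Euler.  Adhesion
kinetics and polarity rotation advance at the recording cadence, which is
the model's kinetic time step (integrator substeps are purely numerical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adhesion import AdhesionState, fa_forces, update_adhesions
from .cells import (
    CellMesh,
    PolarityState,
    cortical_elastic_energy,
    cortical_elastic_forces,
    lamellipodial_input,
    max_stiffness_direction,
    update_polarity,
)
from .config import SimulationConfig
from .network import ECMNetwork, ecm_elastic_energy, ecm_elastic_forces

__all__ = ["World", "TrajectoryDataset", "compute_forces", "step", "simulate", "total_energy", "world_from_frame"]


@dataclass
class World:
    """Mutable state of one multi-cell / ECM system."""

    net: ECMNetwork
    cells: list            # list[CellMesh]
    adhesions: AdhesionState
    polarities: list       # list[PolarityState]
    cell_coords: list      # list[(Nc,3)]
    ecm_coords: np.ndarray # (Ne,3)
    sensing_radius: float = 15.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "World":
        return World(
            net=self.net,
            cells=self.cells,
            adhesions=self.adhesions.copy(),
            polarities=list(self.polarities),
            cell_coords=[c.copy() for c in self.cell_coords],
            ecm_coords=self.ecm_coords.copy(),
            sensing_radius=self.sensing_radius,
        )


@dataclass
class TrajectoryDataset:
    """Recorded frames of a simulation run.

    The stored force channels are exactly the ones the integrator used at
    each recorded state, which is what the augmented-state pipeline
    consumes.  ``bonds[f][k]`` is the (n, 3) array of (i, j, n_int) bonds of
    cell k at frame f.
    """

    times: np.ndarray       # (F,)
    cell_xs: np.ndarray     # (F, K, Nc, 3)
    ecm_xs: np.ndarray      # (F, Ne, 3)
    f_ce: np.ndarray        # (F, K, Nc, 3)
    f_fa_c: np.ndarray      # (F, K, Nc, 3)
    f_elas_e: np.ndarray    # (F, Ne, 3)
    u: np.ndarray           # (F, K, Nc, 3)
    bonds: list             # [frame][cell] -> (n,3) int array (i, j, n_int)
    bond_rest: list         # [frame][cell] -> (n,) float rest lengths
    polarity: np.ndarray    # (F, K, 3)
    config: SimulationConfig | None = None
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_cells(self) -> int:
        return self.cell_xs.shape[1]

    def check_aligned(self, other: "TrajectoryDataset") -> None:
        if self.cell_xs.shape != other.cell_xs.shape or self.ecm_xs.shape != other.ecm_xs.shape:
            raise ValueError("trajectory shapes differ")
        if not np.allclose(self.times, other.times):
            raise ValueError("trajectory timestamps differ")


def compute_forces(world: World) -> dict:
    """All force channels at the current world state."""
    F_ce = [cortical_elastic_forces(c, x) for c, x in zip(world.cells, world.cell_coords)]
    F_fa_c, F_fa_e = fa_forces(world.adhesions, world.cell_coords, world.ecm_coords)
    F_elas = ecm_elastic_forces(world.net, world.ecm_coords)
    u = [
        lamellipodial_input(c, p, x).reshape(-1, 3)
        for c, p, x in zip(world.cells, world.polarities, world.cell_coords)
    ]
    return {"f_ce": F_ce, "f_fa_c": F_fa_c, "f_fa_e": F_fa_e, "f_elas_e": F_elas, "u": u}


def _advance_positions(world: World, forces: dict, dt: float) -> None:
    for k, cell in enumerate(world.cells):
        tot = forces["f_ce"][k] + forces["f_fa_c"][k] + forces["u"][k]
        world.cell_coords[k] = world.cell_coords[k] + dt * tot / cell.D_c
    free = ~world.net.boundary_fixed
    ecm_tot = forces["f_elas_e"] + forces["f_fa_e"]
    world.ecm_coords = world.ecm_coords.copy()
    world.ecm_coords[free] += dt * ecm_tot[free] / world.net.D_e


def update_decisions(world: World, dt_kinetic: float, rng: np.random.Generator) -> None:
    """Adhesion attach/detach sweep followed by the polarity rotation step."""
    world.adhesions = update_adhesions(
        world.adhesions, world.cell_coords, world.ecm_coords, rng,
        fixed_mask=world.net.boundary_fixed,
    )
    new_pol = []
    for k, p in enumerate(world.polarities):
        centroid = world.cell_coords[k].mean(axis=0)
        try:
            dms = max_stiffness_direction(
                world.net, world.ecm_coords, centroid, world.sensing_radius, fallback=p.d_pol
            )
        except ValueError:
            dms = p.d_pol
        new_pol.append(update_polarity(p, dms, dt_kinetic))
    world.polarities = new_pol


def step(world: World, dt: float, rng: np.random.Generator | None = None,
         kinetics: bool = True) -> dict:
    """One explicit-Euler step; returns the forces used.

    Fixed-boundary ECM nodes never move.  Raises on a non-finite state
    (signals that ``dt`` exceeds the stability bound).
    """
    forces = compute_forces(world)
    _advance_positions(world, forces, dt)
    if not np.all(np.isfinite(world.ecm_coords)):
        raise FloatingPointError("non-finite ECM state: dt too large or unstable parameters")
    for x in world.cell_coords:
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite cell state: dt too large or unstable parameters")
    if kinetics:
        if rng is None:
            rng = np.random.default_rng(0)
        update_decisions(world, dt, rng)
    return forces


def total_energy(world: World) -> float:
    """Potential energy bookkeeping: fiber + membrane + adhesion springs."""
    e = ecm_elastic_energy(world.net, world.ecm_coords)
    for c, x in zip(world.cells, world.cell_coords):
        e += cortical_elastic_energy(c, x)
    st = world.adhesions
    for k, x in enumerate(world.cell_coords):
        ba = st.bond_array(k)
        if len(ba):
            d = world.ecm_coords[ba[:, 1]] - x[ba[:, 0]]
            stretch = np.maximum(np.linalg.norm(d, axis=1) - st.bond_rest(k), 0.0)
            e += 0.5 * st.k_fa * np.sum(ba[:, 2] * stretch**2)
    return float(e)


def simulate(world: World, config: SimulationConfig, progress: bool = False) -> TrajectoryDataset:
    """Integrate the nonlinear system and record every ``record_every`` substeps.

    Deterministic for a fixed ``config.seed``.  Adhesion/polarity kinetics
    advance once per recorded sample using the sampling interval as the
    kinetic time step.
    """
    rng = np.random.default_rng(config.seed)
    world = world.copy()
    K = world.n_cells
    Nc = world.cells[0].n_nodes if K else 0
    Ne = world.net.n_nodes
    n_steps = config.n_steps
    rec = config.record_every
    n_frames = n_steps // rec + 1

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

    frame = 0
    for s in range(n_steps + 1):
        forces = compute_forces(world)
        if s % rec == 0:
            times[frame] = s * config.dt
            ecm_xs[frame] = world.ecm_coords
            f_elas_e[frame] = forces["f_elas_e"]
            for k in range(K):
                cell_xs[frame, k] = world.cell_coords[k]
                f_ce[frame, k] = forces["f_ce"][k]
                f_fa_c[frame, k] = forces["f_fa_c"][k]
                u_rec[frame, k] = forces["u"][k]
                pol[frame, k] = world.polarities[k].d_pol
            bonds.append([world.adhesions.bond_array(k) for k in range(K)])
            bond_rest.append([world.adhesions.bond_rest(k) for k in range(K)])
            frame += 1
        if s == n_steps:
            break
        _advance_positions(world, forces, config.dt)
        if not np.all(np.isfinite(world.ecm_coords)):
            raise FloatingPointError(f"non-finite state at step {s}: dt too large")
        if (s + 1) % rec == 0:
            update_decisions(world, config.sample_interval, rng)
        if progress and s % max(1, n_steps // 10) == 0:
            print(f"  step {s}/{n_steps} (t = {s * config.dt:.0f} s)", flush=True)

    return TrajectoryDataset(
        times=times, cell_xs=cell_xs, ecm_xs=ecm_xs, f_ce=f_ce, f_fa_c=f_fa_c,
        f_elas_e=f_elas_e, u=u_rec, bonds=bonds, bond_rest=bond_rest, polarity=pol,
        config=config, seed=config.seed,
    )


def world_from_frame(template: World, traj: TrajectoryDataset, frame: int) -> World:
    """Rebuild a :class:`World` from a recorded frame (coords, bonds, polarity).

    The template supplies the static structures (network, meshes, adhesion
    parameters, sensing radius).
    """
    from dataclasses import replace as _replace

    w = template.copy()
    w.cell_coords = [traj.cell_xs[frame, k].copy() for k in range(traj.n_cells)]
    w.ecm_coords = traj.ecm_xs[frame].copy()
    bonds = {}
    for k in range(traj.n_cells):
        ba = traj.bonds[frame][k]
        L0 = traj.bond_rest[frame][k] if traj.bond_rest else np.zeros(len(ba))
        bonds[k] = {int(i): (int(j), int(n), float(l))
                    for (i, j, n), l in zip(ba, L0)}
    w.adhesions = AdhesionState(
        bonds=bonds, k_fa=template.adhesions.k_fa, n_int=template.adhesions.n_int,
        d_bind=template.adhesions.d_bind, d_break=template.adhesions.d_break,
        p_on=template.adhesions.p_on,
    )
    w.polarities = [
        _replace(template.polarities[k], d_pol=traj.polarity[frame, k] /
                 np.linalg.norm(traj.polarity[frame, k]))
        for k in range(traj.n_cells)
    ]
    return w
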