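"""Quantitative comparison of trajectories: RMSE, compaction, forces, edges.

Slice membership for the compaction profile is material: nodes are
assigned to axial slices by their initial coordinates, so normalized slice
volumes V(t)/V(0) remain well defined under large deformation.  Slice
volumes are 3-D convex hulls of the member nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .simulate import TrajectoryDataset

__all__ = [
    "trajectory_rmse",
    "CompactionProfile",
    "compaction_profile",
    "gel_volume",
    "intercell_elastic_force",
    "max_edge_displacement",
]


def trajectory_rmse(traj_a: TrajectoryDataset, traj_b: TrajectoryDataset,
                    entity: str = "all") -> float:
    """Root mean square node-position difference pooled over nodes and frames (um).

    ``entity`` selects ``"cells"``, ``"ecm"`` or ``"all"``; trajectories
    must share timestamps and node correspondence.
    """
    traj_a.check_aligned(traj_b)
    sq = []
    if entity in ("cells", "all"):
        d = traj_a.cell_xs - traj_b.cell_xs
        sq.append(np.sum(d * d, axis=-1).ravel())
    if entity in ("ecm", "all"):
        d = traj_a.ecm_xs - traj_b.ecm_xs
        sq.append(np.sum(d * d, axis=-1).ravel())
    if not sq:
        raise ValueError("entity must be 'cells', 'ecm' or 'all'")
    return float(np.sqrt(np.mean(np.concatenate(sq))))


@dataclass
class CompactionProfile:
    """Per-slice normalized volumes over time."""

    edges: np.ndarray       # (n_slices + 1,) axial slice boundaries, um
    times: np.ndarray       # (T,)
    volumes: np.ndarray     # (T, n_slices) raw hull volumes, um^3
    normalized: np.ndarray  # (T, n_slices) V(t)/V(0)

    @property
    def n_slices(self) -> int:
        return len(self.edges) - 1

    def slice_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        centers = self.slice_centers()
        for ti, t in enumerate(self.times):
            for si in range(self.n_slices):
                rows.append((t, si, centers[si], self.volumes[ti, si], self.normalized[ti, si]))
        return pd.DataFrame(rows, columns=["time", "slice", "z_center", "volume", "normalized"])


def compaction_profile(traj: TrajectoryDataset, slice_thickness: float = 10.0,
                       axis: int = 2, frames: np.ndarray | None = None) -> CompactionProfile:
    """Axial compaction profile from convex-hull volumes of material slices.

    The domain is cut into slices of ``slice_thickness`` along ``axis``;
    each ECM node belongs to the slice containing its initial axial
    coordinate.  Raises if a slice holds fewer than 4 non-coplanar nodes.
    """
    x0 = traj.ecm_xs[0]
    zmin, zmax = x0[:, axis].min(), x0[:, axis].max()
    n_slices = max(1, int(np.ceil((zmax - zmin) / slice_thickness - 1e-9)))
    edges = zmin + slice_thickness * np.arange(n_slices + 1)
    member = np.clip(((x0[:, axis] - zmin) / slice_thickness).astype(int), 0, n_slices - 1)

    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames)
    vols = np.empty((len(frames), n_slices))
    for ti, f in enumerate(frames):
        pts = traj.ecm_xs[f]
        for si in range(n_slices):
            p = pts[member == si]
            if len(p) < 4:
                raise ValueError(f"slice {si} has fewer than 4 nodes")
            try:
                vols[ti, si] = ConvexHull(p).volume
            except Exception as exc:  # qhull degenerate input
                raise ValueError(f"slice {si} nodes are degenerate (coplanar?)") from exc
    v0 = vols[0]
    if np.any(v0 <= 0):
        raise ValueError("zero initial slice volume")
    return CompactionProfile(
        edges=edges, times=traj.times[frames], volumes=vols, normalized=vols / v0,
    )


def intercell_elastic_force(traj: TrajectoryDataset, region: tuple[float, float],
                            axis: int = 2) -> np.ndarray:
    """Mean ECM elastic-force magnitude over nodes initially in ``region`` (nN).

    ``region`` is an axial interval (lo, hi); membership is by initial
    (material) coordinates.  Returns one value per frame.
    """
    lo, hi = region
    x0 = traj.ecm_xs[0]
    mask = (x0[:, axis] >= lo) & (x0[:, axis] <= hi)
    if not np.any(mask):
        raise ValueError("no ECM node in the requested region")
    mags = np.linalg.norm(traj.f_elas_e[:, mask, :], axis=-1)
    return mags.mean(axis=1)


def max_edge_displacement(traj: TrajectoryDataset, edge_nodes: np.ndarray) -> np.ndarray:
    """Max displacement from the initial position over ``edge_nodes``, per frame (um)."""
    edge_nodes = np.asarray(edge_nodes)
    if edge_nodes.size == 0:
        raise ValueError("edge node set is empty")
    d = traj.ecm_xs[:, edge_nodes, :] - traj.ecm_xs[0, edge_nodes, :]
    return np.linalg.norm(d, axis=-1).max(axis=1)


def gel_volume(traj: TrajectoryDataset, frames: np.ndarray | None = None) -> np.ndarray:
    """Total gel volume per frame: convex hull of all ECM nodes (um^3).

    A robust global compaction measure; unlike the per-slice material
    profile it cannot double-count overlapping deformed slices.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    return np.array([ConvexHull(traj.ecm_xs[f]).volume for f in np.asarray(frames)])
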