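"""Cell membrane meshes, cortical mechanics, polarity dynamics and lamellipodia.

Each cell is a closed triangulated membrane (icosphere).  Passive membrane
mechanics combine edge springs (in-plane elasticity) with an isotropic
cortical tension that contracts the membrane toward smaller surface area.
The active machinery is a polarity unit vector relaxing toward the local
maximum-stiffness direction of the ECM, and lamellipodial forces applied to
membrane nodes inside the leading-edge cone around the polarity axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .network import ECMNetwork, segment_tensions

__all__ = [
    "CellMesh",
    "PolarityState",
    "make_cell_mesh",
    "cortical_elastic_energy",
    "cortical_elastic_forces",
    "update_polarity",
    "lamellipodial_input",
    "max_stiffness_direction",
]

_DEGENERATE_AREA = 1e-10


@dataclass
class CellMesh:
    """Closed triangulated membrane mesh of one cell.

    ``nodes`` is the rest geometry; during simulation current coordinates
    live in the :class:`~ecmdfl.simulate.World`.
    """

    nodes: np.ndarray             # (Nc, 3) rest coordinates, um
    triangles: np.ndarray         # (T, 3) int
    edges: np.ndarray             # (E, 2) int, unique undirected
    rest_edge_lengths: np.ndarray # (E,) um
    rest_area: float              # um^2
    k_edge: float = 1.0
    gamma: float = 0.2            # cortical tension, nN/um^2
    D_c: float = 10.0
    cell_id: int = 0
    radius: float = 6.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        v = self.n_nodes
        e = len(self.edges)
        f = len(self.triangles)
        if v - e + f != 2:
            raise ValueError("membrane mesh is not a closed 2-manifold (Euler characteristic != 2)")
        if np.any(self.rest_edge_lengths <= 0):
            raise ValueError("non-positive rest edge length")


@dataclass(frozen=True)
class PolarityState:
    """Cell polarity: leading-edge direction and lamellipodial parameters."""

    d_pol: np.ndarray            # unit 3-vector
    kappa: float = 0.002         # 1/s
    alpha_L: float = np.pi / 3   # rad
    f_L: float = 1.0             # nN

    def __post_init__(self):
        d = np.asarray(self.d_pol, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("polarity vector must be unit norm")
        if not (0 < self.alpha_L < np.pi):
            raise ValueError("alpha_L must lie in (0, pi)")
        object.__setattr__(self, "d_pol", d)


def make_cell_mesh(
    center,
    radius: float = 6.0,
    subdivisions: int = 1,
    *,
    k_edge: float = 1.0,
    gamma: float = 0.2,
    D_c: float = 10.0,
    cell_id: int = 0,
) -> CellMesh:
    """Icosphere membrane mesh centred at ``center`` (subdivision 1 -> 42 nodes)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    nodes = np.asarray(m.vertices, dtype=float) + np.asarray(center, dtype=float)
    tris = np.asarray(m.faces, dtype=np.int64)
    edges = np.unique(np.sort(m.edges_unique, axis=1), axis=0).astype(np.int64)
    rest = np.linalg.norm(nodes[edges[:, 1]] - nodes[edges[:, 0]], axis=1)
    cell = CellMesh(
        nodes=nodes, triangles=tris, edges=edges, rest_edge_lengths=rest,
        rest_area=float(m.area), k_edge=k_edge, gamma=gamma, D_c=D_c,
        cell_id=cell_id, radius=radius,
    )
    cell.validate()
    return cell


def _check_cell_coords(cell: CellMesh, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (cell.n_nodes, 3):
        raise ValueError(f"coords must have shape {(cell.n_nodes, 3)}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords


def _triangle_normals(cell: CellMesh, coords: np.ndarray):
    a, b, c = (coords[cell.triangles[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    nrm = np.linalg.norm(n, axis=1)
    if np.any(nrm < _DEGENERATE_AREA):
        raise ValueError("degenerate (zero-area) membrane triangle")
    return a, b, c, n, nrm


def cortical_elastic_energy(cell: CellMesh, coords: np.ndarray) -> float:
    """Edge-spring energy + gamma * total membrane area (nN*um)."""
    coords = _check_cell_coords(cell, coords)
    d = coords[cell.edges[:, 1]] - coords[cell.edges[:, 0]]
    L = np.linalg.norm(d, axis=1)
    e = 0.5 * cell.k_edge * np.sum((L - cell.rest_edge_lengths) ** 2)
    _, _, _, _, nrm = _triangle_normals(cell, coords)
    e += cell.gamma * 0.5 * np.sum(nrm)
    return float(e)


def cortical_elastic_forces(cell: CellMesh, coords: np.ndarray) -> np.ndarray:
    """Cortical tension + membrane elastic nodal forces, shape (Nc, 3), nN.

    Negative gradient of :func:`cortical_elastic_energy`; the vector sum over
    the closed mesh is zero (internal forces only).
    """
    coords = _check_cell_coords(cell, coords)
    F = np.zeros_like(coords)

    # edge springs
    ed = cell.edges
    d = coords[ed[:, 1]] - coords[ed[:, 0]]
    L = np.linalg.norm(d, axis=1)
    if np.any(L < 1e-8):
        raise ValueError("collapsed membrane edge")
    f = (cell.k_edge * (L - cell.rest_edge_lengths) / L)[:, None] * d
    np.add.at(F, ed[:, 0], f)
    np.add.at(F, ed[:, 1], -f)

    # cortical tension: F = -gamma * grad(total area)
    a, b, c, n, nrm = _triangle_normals(cell, coords)
    nh = n / nrm[:, None]
    ga = 0.5 * np.cross(nh, c - b)
    gb = 0.5 * np.cross(nh, a - c)
    gc = 0.5 * np.cross(nh, b - a)
    np.add.at(F, cell.triangles[:, 0], -cell.gamma * ga)
    np.add.at(F, cell.triangles[:, 1], -cell.gamma * gb)
    np.add.at(F, cell.triangles[:, 2], -cell.gamma * gc)
    return F


def update_polarity(p: PolarityState, d_max_stiff: np.ndarray, dt: float) -> PolarityState:
    """One explicit-Euler step of the polarity rotation, then renormalise.

    The polarity relaxes toward the maximum-stiffness direction via
    d(d_pol)/dt = kappa * d_pol x (d_ms x d_pol); the right-hand side is
    orthogonal to d_pol, so the norm is preserved to first order and a
    renormalisation removes the residual drift.  Aligned and anti-parallel
    configurations are fixed points (the latter unstable).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = p.d_pol
    dms = np.asarray(d_max_stiff, dtype=float)
    rhs = p.kappa * np.cross(d, np.cross(dms, d))
    new = d + dt * rhs
    new /= np.linalg.norm(new)
    return replace(p, d_pol=new)


def lamellipodial_input(cell: CellMesh, p: PolarityState, coords: np.ndarray | None = None) -> np.ndarray:
    """Lamellipodial force input u for one cell, flat shape (3*Nc,), nN.

    Nodes whose centroid-to-node direction lies within the leading-edge cone
    (angle <= alpha_L from the polarity axis) receive an outward force of
    magnitude f_L along that direction; all other entries are exactly zero.
    """
    if coords is None:
        coords = cell.nodes
    coords = _check_cell_coords(cell, coords)
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    nrm = np.linalg.norm(rel, axis=1)
    nrm = np.where(nrm < 1e-12, 1.0, nrm)
    dirs = rel / nrm[:, None]
    cosang = dirs @ p.d_pol
    mask = cosang >= np.cos(p.alpha_L)
    u = np.zeros_like(coords)
    u[mask] = p.f_L * dirs[mask]
    return u.ravel()


def max_stiffness_direction(
    net: ECMNetwork,
    ecm_coords: np.ndarray,
    cell_centroid,
    sensing_radius: float,
    fallback: np.ndarray | None = None,
) -> np.ndarray:
    """Principal direction of the local fiber-tension tensor near the cell.

    Builds M = sum_s |T_s| u_s u_s^T over springs whose midpoint lies within
    ``sensing_radius`` of ``cell_centroid`` and returns its leading unit
    eigenvector.  The sign is chosen toward the tension-weighted centroid of
    the contributing springs (the higher-tension half-space); ties fall back
    to making the first non-zero component positive.  If every local spring
    is slack the ``fallback`` direction (current polarity) is returned.
    """
    centroid = np.asarray(cell_centroid, dtype=float)
    sp, T, u, mid = segment_tensions(net, ecm_coords)
    near = np.linalg.norm(mid - centroid, axis=1) <= sensing_radius
    if not np.any(near):
        raise ValueError("no ECM segment within sensing radius")
    w = np.abs(T[near])
    if np.all(w < 1e-12):
        if fallback is not None:
            return np.asarray(fallback, dtype=float)
        raise ValueError("all local segments slack and no fallback polarity given")
    uu = u[near]
    M = (uu * w[:, None]).T @ uu
    evals, evecs = np.linalg.eigh(M)
    v = evecs[:, -1]
    # orient toward the tension-weighted mass of contributing springs
    bias = (w[:, None] * (mid[near] - centroid)).sum(axis=0)
    s = float(v @ bias)
    if abs(s) > 1e-12:
        v = v * np.sign(s)
    else:
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if len(nz) and v[nz[0]] < 0:
            v = -v
    return v / np.linalg.norm(v)
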