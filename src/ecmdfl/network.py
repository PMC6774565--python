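"""Procedural 3-D ECM fiber networks and their elastic/damping mechanics.

The extracellular matrix is discretised as straight fibers subdivided into
linear spring segments, with harmonic-cosine angular springs at interior
fiber nodes and additional crosslink springs joining nearby nodes of
distinct fibers.  The generated geometry is the stress-free reference
state: rest lengths equal generated lengths and rest angles are straight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "Cylinder",
    "Box",
    "ECMNetwork",
    "generate_network",
    "ecm_elastic_energy",
    "ecm_elastic_forces",
    "segment_tensions",
]

_COLLAPSE_TOL = 1e-8


@dataclass(frozen=True)
class Cylinder:
    """Cylindrical domain of given ``radius`` and ``length``, axis along z.

    Spans z in [0, length], centred on the z-axis.  The two flat end planes
    are the fixed (constrained) boundaries; the curved surface is free.
    """

    radius: float
    length: float
    axis: int = 2  # z

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.length

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        return (r2 <= self.radius**2) & (pts[:, 2] >= 0.0) & (pts[:, 2] <= self.length)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # uniform in the cylinder via sqrt-radius trick
        r = self.radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        z = rng.uniform(0, self.length, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th), z])

    def boundary_mask(self, pts: np.ndarray, tol: float) -> np.ndarray:
        return (pts[:, 2] <= tol) | (pts[:, 2] >= self.length - tol)

    @property
    def extent(self) -> float:
        return max(2 * self.radius, self.length)

    def to_dict(self) -> dict:
        return {"kind": "cylinder", "radius": self.radius, "length": self.length}


@dataclass(frozen=True)
class Box:
    """Axis-aligned box [0,lx]x[0,ly]x[0,lz]; the z=0 face is fixed (plated gel)."""

    lx: float
    ly: float
    lz: float

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo = pts >= 0.0
        hi = pts <= np.array([self.lx, self.ly, self.lz])
        return lo.all(axis=1) & hi.all(axis=1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(size=(n, 3)) * np.array([self.lx, self.ly, self.lz])

    def boundary_mask(self, pts: np.ndarray, tol: float) -> np.ndarray:
        return pts[:, 2] <= tol

    @property
    def extent(self) -> float:
        return max(self.lx, self.ly, self.lz)

    def to_dict(self) -> dict:
        return {"kind": "box", "lx": self.lx, "ly": self.ly, "lz": self.lz}


def domain_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "cylinder":
        return Cylinder(radius=d["radius"], length=d["length"])
    if kind == "box":
        return Box(lx=d["lx"], ly=d["ly"], lz=d["lz"])
    raise ValueError(f"unknown domain kind: {kind!r}")


@dataclass
class ECMNetwork:
    """Discrete fiber-network model of the ECM.

    ``segments`` are consecutive-node springs along fibers; ``crosslinks``
    are springs joining nodes of distinct fibers.  Both carry rest lengths
    from the generated (stress-free) geometry.  ``bend_triples`` are
    (i, j, k) triples of consecutive nodes on one fiber carrying an angular
    spring that penalises deviation from the straight rest shape.
    """

    nodes: np.ndarray            # (N, 3) um
    segments: np.ndarray         # (S, 2) int
    seg_rest: np.ndarray         # (S,) um
    bend_triples: np.ndarray     # (B, 3) int
    crosslinks: np.ndarray       # (C, 2) int
    cross_rest: np.ndarray       # (C,) um
    boundary_fixed: np.ndarray   # (N,) bool
    fiber_id: np.ndarray         # (N,) int
    k_axial: float = 2.0
    k_bend: float = 0.1
    k_cross: float = 2.0
    D_e: float = 10.0
    domain: object = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def all_springs(self) -> np.ndarray:
        """Segments and crosslinks concatenated, (S+C, 2)."""
        if len(self.crosslinks):
            return np.vstack([self.segments, self.crosslinks])
        return self.segments.copy()

    @property
    def all_rest(self) -> np.ndarray:
        return np.concatenate([self.seg_rest, self.cross_rest])

    @property
    def all_k(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(self.segments), self.k_axial), np.full(len(self.crosslinks), self.k_cross)]
        )

    def validate(self) -> None:
        n = self.n_nodes
        sp = self.all_springs
        if len(sp) and (sp.min() < 0 or sp.max() >= n):
            raise ValueError("spring index out of range")
        if len(sp) and np.any(sp[:, 0] == sp[:, 1]):
            raise ValueError("degenerate spring with identical endpoints")
        if np.any(self.all_rest <= 0):
            raise ValueError("non-positive rest length")


def _spring_adjacency(n: int, springs: np.ndarray) -> coo_matrix:
    if len(springs) == 0:
        return coo_matrix((n, n))
    data = np.ones(len(springs))
    return coo_matrix((data, (springs[:, 0], springs[:, 1])), shape=(n, n))


def _generate_once(
    domain, n_fibers: int, segments_per_fiber: int, crosslink_radius: float,
    rng: np.random.Generator, boundary_tol: float, min_fiber_length: float,
):
    nodes = []
    segments = []
    triples = []
    fiber_id = []
    for f in range(n_fibers):
        # straight chord between two interior points; convex domains keep it inside
        for _ in range(200):
            p0 = domain.sample(rng, 1)[0]
            p1 = domain.sample(rng, 1)[0]
            if np.linalg.norm(p1 - p0) >= min_fiber_length:
                break
        else:
            raise RuntimeError("could not place fiber endpoints")
        base = len(nodes)
        ts = np.linspace(0.0, 1.0, segments_per_fiber + 1)
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        nodes.extend(pts)
        fiber_id.extend([f] * len(pts))
        for s in range(segments_per_fiber):
            segments.append((base + s, base + s + 1))
        for s in range(1, segments_per_fiber):
            triples.append((base + s - 1, base + s, base + s + 1))
    nodes = np.asarray(nodes, dtype=float)
    segments = np.asarray(segments, dtype=np.int64)
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    fiber_id = np.asarray(fiber_id, dtype=np.int64)

    # crosslinks: node pairs from distinct fibers within the crosslink radius
    crosslinks = []
    if crosslink_radius > 0 and len(nodes):
        tree = cKDTree(nodes)
        pairs = tree.query_pairs(r=crosslink_radius, output_type="ndarray")
        if len(pairs):
            diff_fiber = fiber_id[pairs[:, 0]] != fiber_id[pairs[:, 1]]
            dists = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
            keep = diff_fiber & (dists > 10 * _COLLAPSE_TOL)
            crosslinks = pairs[keep]
    crosslinks = np.asarray(crosslinks, dtype=np.int64).reshape(-1, 2)

    seg_rest = np.linalg.norm(nodes[segments[:, 1]] - nodes[segments[:, 0]], axis=1)
    cross_rest = (
        np.linalg.norm(nodes[crosslinks[:, 1]] - nodes[crosslinks[:, 0]], axis=1)
        if len(crosslinks)
        else np.zeros(0)
    )
    boundary = domain.boundary_mask(nodes, boundary_tol)
    return nodes, segments, seg_rest, triples, crosslinks, cross_rest, boundary, fiber_id


def generate_network(
    domain,
    n_fibers: int,
    segments_per_fiber: int,
    crosslink_radius: float,
    seed: int,
    *,
    k_axial: float = 2.0,
    k_bend: float = 0.1,
    k_cross: float = 2.0,
    D_e: float = 10.0,
    boundary_tol: float = 5.0,
    min_fiber_length: float | None = None,
    max_retries: int = 20,
) -> ECMNetwork:
    """Generate a connected, stress-free fiber network inside ``domain``.

    Fibers are straight chords between two uniformly sampled interior
    points, subdivided into ``segments_per_fiber`` equal segments.  Nodes of
    different fibers closer than ``crosslink_radius`` are joined by
    crosslink springs.  Deterministic for a fixed ``seed``.  Raises
    ``RuntimeError`` if no connected graph is obtained within
    ``max_retries`` regenerations (fiber density too low).
    """
    if domain.volume <= 0:
        raise ValueError("domain volume must be positive")
    if n_fibers < 1 or segments_per_fiber < 1:
        raise ValueError("counts must be >= 1")
    if min_fiber_length is None:
        min_fiber_length = 0.3 * domain.extent

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 100_003 * attempt)
        nodes, segments, seg_rest, triples, crosslinks, cross_rest, boundary, fiber_id = _generate_once(
            domain, n_fibers, segments_per_fiber, crosslink_radius, rng, boundary_tol, min_fiber_length
        )
        springs = np.vstack([segments, crosslinks]) if len(crosslinks) else segments
        n_comp, _ = connected_components(_spring_adjacency(len(nodes), springs), directed=False)
        if n_comp == 1 or n_fibers == 1:
            net = ECMNetwork(
                nodes=nodes, segments=segments, seg_rest=seg_rest, bend_triples=triples,
                crosslinks=crosslinks, cross_rest=cross_rest, boundary_fixed=boundary,
                fiber_id=fiber_id, k_axial=k_axial, k_bend=k_bend, k_cross=k_cross,
                D_e=D_e, domain=domain,
            )
            net.validate()
            return net
    raise RuntimeError(
        f"network disconnected after {max_retries} attempts; increase fiber count or crosslink radius"
    )


def _check_coords(net: ECMNetwork, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (net.n_nodes, 3):
        raise ValueError(f"coords must have shape {(net.n_nodes, 3)}, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords


def _stretch_terms(net: ECMNetwork, coords: np.ndarray):
    sp = net.all_springs
    d = coords[sp[:, 1]] - coords[sp[:, 0]]
    L = np.linalg.norm(d, axis=1)
    if np.any(L < _COLLAPSE_TOL):
        raise ValueError("collapsed spring segment (length below tolerance)")
    return sp, d, L, net.all_rest, net.all_k


def ecm_elastic_energy(net: ECMNetwork, coords: np.ndarray) -> float:
    """Total stretch + bending energy (nN*um)."""
    coords = _check_coords(net, coords)
    sp, d, L, L0, k = _stretch_terms(net, coords)
    e = 0.5 * np.sum(k * (L - L0) ** 2)
    if len(net.bend_triples):
        i, j, kk = net.bend_triples.T
        b1 = coords[j] - coords[i]
        b2 = coords[kk] - coords[j]
        c = np.sum(b1 * b2, axis=1) / (np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1))
        e += net.k_bend * np.sum(1.0 - c)
    return float(e)


def ecm_elastic_forces(net: ECMNetwork, coords: np.ndarray) -> np.ndarray:
    """Elastic nodal forces F = -grad E (stretch + bending), shape (N, 3), nN.

    Zero at the rest configuration; equal and opposite per spring, so the
    total over an isolated network vanishes.
    """
    coords = _check_coords(net, coords)
    F = np.zeros_like(coords)
    sp, d, L, L0, k = _stretch_terms(net, coords)
    # spring stretched (L > L0): pulls endpoints together
    fmag = (k * (L - L0) / L)[:, None] * d  # force on node sp[:,0] (toward sp[:,1])
    np.add.at(F, sp[:, 0], fmag)
    np.add.at(F, sp[:, 1], -fmag)

    if len(net.bend_triples):
        i, j, kk = net.bend_triples.T
        b1 = coords[j] - coords[i]
        b2 = coords[kk] - coords[j]
        L1 = np.linalg.norm(b1, axis=1)
        L2 = np.linalg.norm(b2, axis=1)
        if np.any(L1 < _COLLAPSE_TOL) or np.any(L2 < _COLLAPSE_TOL):
            raise ValueError("collapsed fiber segment in bending triple")
        inv12 = 1.0 / (L1 * L2)
        c = np.sum(b1 * b2, axis=1) * inv12
        # E = k_b (1 - c); F = k_b * grad c
        dc_db1 = b2 * inv12[:, None] - (c / L1**2)[:, None] * b1
        dc_db2 = b1 * inv12[:, None] - (c / L2**2)[:, None] * b2
        np.add.at(F, i, -net.k_bend * dc_db1)
        np.add.at(F, j, net.k_bend * (dc_db1 - dc_db2))
        np.add.at(F, kk, net.k_bend * dc_db2)
    return F


def segment_tensions(net: ECMNetwork, coords: np.ndarray):
    """Axial tension T = k (L - L0) and unit direction for every spring.

    Returns (springs (M,2), tensions (M,), unit_dirs (M,3), midpoints (M,3)).
    Positive tension = taut (stretched) spring.
    """
    coords = _check_coords(net, coords)
    sp, d, L, L0, k = _stretch_terms(net, coords)
    T = k * (L - L0)
    u = d / L[:, None]
    mid = 0.5 * (coords[sp[:, 0]] + coords[sp[:, 1]])
    return sp, T, u, mid
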