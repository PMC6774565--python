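"""Focal-adhesion bonds between cell membrane nodes and ECM nodes.

Each bond is a linear spring per bound integrin between one membrane node
and one ECM node, transmitting equal-and-opposite forces (the global sum of
all focal-adhesion forces is exactly zero).  Attachment is stochastic
within a binding range; detachment is deterministic beyond a rupture
distance.  The bond topology is also expressible as a sparse mapping
matrix of {0, -1} entries routing each cell's membrane forces to its ECM
partner nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import cKDTree

__all__ = ["AdhesionState", "fa_forces", "build_mapping_matrix", "update_adhesions"]


@dataclass
class AdhesionState:
    """Bond sets per cell plus the force-law and kinetics parameters.

    ``bonds[k]`` maps cell-node index ``i`` -> (ecm-node index ``j``,
    integrin count, rest length).  An ECM node is bound to at most one
    cell.  Each bond is a tension-only spring whose rest length is the
    separation at formation, so the transmitted force is exactly zero at
    attachment and builds smoothly with subsequent relative motion (a
    deterministic stand-in for gradual integrin-recruitment kinetics).
    With rest length 0 the law reduces to k_fa * n_int * (x_e - x_c).
    """

    bonds: dict                  # {k: {i: (j, n_bound, rest_length)}}
    k_fa: float = 0.5            # nN/um per integrin
    n_int: int = 10              # integrins per mature adhesion
    d_bind: float = 4.0          # um
    d_break: float = 10.0        # um
    p_on: float = 0.5

    def __post_init__(self):
        if not (self.d_break > self.d_bind > 0):
            raise ValueError("require d_break > d_bind > 0")
        self._check_exclusive()

    def _check_exclusive(self):
        seen = {}
        for k, cb in self.bonds.items():
            for i, bond in cb.items():
                j, n = bond[0], bond[1]
                if n < 1:
                    raise ValueError("integrin count must be >= 1")
                if j in seen and seen[j] != k:
                    raise ValueError(f"ECM node {j} bound by cells {seen[j]} and {k}")
                seen[j] = k

    @staticmethod
    def _norm_bond(bond) -> tuple:
        """Accept (j, n) or (j, n, L0); missing rest length means 0."""
        if len(bond) == 2:
            return bond[0], bond[1], 0.0
        return bond[0], bond[1], bond[2]

    def bonded_ecm_nodes(self) -> set:
        return {bond[0] for cb in self.bonds.values() for bond in cb.values()}

    def bond_array(self, k: int) -> np.ndarray:
        """Bond topology of cell k as an (n, 3) int array of (i, j, n_int)."""
        cb = self.bonds.get(k, {})
        if not cb:
            return np.zeros((0, 3), dtype=np.int64)
        return np.array([(i, bond[0], bond[1]) for i, bond in sorted(cb.items())],
                        dtype=np.int64)

    def bond_rest(self, k: int) -> np.ndarray:
        """Rest lengths aligned with :meth:`bond_array` rows."""
        cb = self.bonds.get(k, {})
        return np.array([self._norm_bond(cb[i])[2] for i in sorted(cb)], dtype=float)

    def copy(self) -> "AdhesionState":
        return AdhesionState(
            bonds={k: dict(cb) for k, cb in self.bonds.items()},
            k_fa=self.k_fa, n_int=self.n_int,
            d_bind=self.d_bind, d_break=self.d_break, p_on=self.p_on,
        )


def fa_forces(state: AdhesionState, cell_coords: list[np.ndarray], ecm_coords: np.ndarray):
    """Paired focal-adhesion forces.

    Returns ``(F_fa_cells, F_fa_ecm)`` where ``F_fa_cells[k]`` has shape
    (Nc, 3) and ``F_fa_ecm`` shape (Ne, 3).  Per bond the cell node feels
    the tension-only spring force k_fa * n_int * max(|d| - L0, 0) * d_hat
    with d = x_j^e - x_i^c, and the ECM node its negation, so the global
    sum cancels to machine precision.  With L0 = 0 this is exactly
    k_fa * n_int * (x_j^e - x_i^c).
    """
    F_ecm = np.zeros_like(ecm_coords)
    F_cells = []
    for k, coords in enumerate(cell_coords):
        Fc = np.zeros_like(coords)
        ba = state.bond_array(k)
        if len(ba):
            i, j, n = ba[:, 0], ba[:, 1], ba[:, 2]
            if i.max() >= len(coords) or j.max() >= len(ecm_coords):
                raise IndexError("bond references node out of range")
            L0 = state.bond_rest(k)
            d = ecm_coords[j] - coords[i]
            dist = np.linalg.norm(d, axis=1)
            safe = np.where(dist < 1e-12, 1.0, dist)
            stretch = np.maximum(dist - L0, 0.0)
            f = (state.k_fa * n * stretch / safe)[:, None] * d
            np.add.at(Fc, i, f)
            np.add.at(F_ecm, j, -f)
        F_cells.append(Fc)
    return F_cells, F_ecm


def build_mapping_matrix(state: AdhesionState, k: int, N_e: int, N_c: int) -> csr_matrix:
    """Sparse mapping matrix (3*N_e x 3*N_c) for cell ``k``.

    For every bond (i, j) the 3x3 block at block-row j, block-column i is
    minus the identity; all other entries are zero.  Applying it to the
    cell's membrane adhesion forces yields the forces delivered to the ECM
    nodes by that cell.
    """
    state._check_exclusive()
    ba = state.bond_array(k)
    if len(ba) == 0:
        return csr_matrix((3 * N_e, 3 * N_c))
    i, j = ba[:, 0], ba[:, 1]
    rows = (3 * j[:, None] + np.arange(3)[None, :]).ravel()
    cols = (3 * i[:, None] + np.arange(3)[None, :]).ravel()
    data = -np.ones(len(rows))
    return coo_matrix((data, (rows, cols)), shape=(3 * N_e, 3 * N_c)).tocsr()


def update_adhesions(
    state: AdhesionState,
    cell_coords: list[np.ndarray],
    ecm_coords: np.ndarray,
    rng: np.random.Generator,
    fixed_mask: np.ndarray | None = None,
) -> AdhesionState:
    """One attachment/detachment sweep; returns a new state.

    Bonds stretched beyond ``d_break`` detach.  Then each unbound membrane
    node attaches with probability ``p_on`` to its nearest free ECM node
    within ``d_bind``; the new bond's rest length is the current
    separation, so it forms unloaded (fixed-boundary ECM nodes and nodes
    already bound to any cell are excluded).  Iteration order is fixed, so
    the bond history is deterministic for a seeded generator.
    """
    new = state.copy()

    # detachment
    for k, coords in enumerate(cell_coords):
        cb = new.bonds.get(k, {})
        for i in sorted(list(cb)):
            j = cb[i][0]
            if np.linalg.norm(ecm_coords[j] - coords[i]) > state.d_break:
                del cb[i]

    taken = new.bonded_ecm_nodes()
    tree = cKDTree(ecm_coords)
    for k, coords in enumerate(cell_coords):
        cb = new.bonds.setdefault(k, {})
        free_nodes = [i for i in range(len(coords)) if i not in cb]
        if not free_nodes:
            continue
        cand = tree.query_ball_point(coords[free_nodes], r=state.d_bind)
        for idx, i in enumerate(free_nodes):
            options = [
                j for j in cand[idx]
                if j not in taken and (fixed_mask is None or not fixed_mask[j])
            ]
            if not options:
                continue
            if rng.uniform() >= state.p_on:
                continue
            d = np.linalg.norm(ecm_coords[options] - coords[i], axis=1)
            jbest = int(np.argmin(d))
            j = options[jbest]
            cb[i] = (j, state.n_int, float(d[jbest]))
            taken.add(j)
    return new
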