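"""Seeded fixture generator for the standard study scenarios.

Every scenario is generated procedurally at a reduced "desk" mesh scale
(about 290 ECM nodes, 42 membrane nodes per cell) so that the whole
pipeline — nonlinear ground truth, training, reduction, superposition —
runs on a laptop.  Scenarios:

``toy_spring``        scalar hard-spring system for the worked example.
``tiny_cylinder``     one cell centred in the 40 x 100 um cylinder.
``two_cell_cylinder`` two cells on the cylinder axis, default 30 um apart.
``plated_box``        250 x 100 x 50 um gel slab, 5-cell cluster near the
                      left edge plus one isolated cell near the right edge.
"""

from __future__ import annotations

import numpy as np

from .cells import CellMesh, PolarityState, make_cell_mesh
from .adhesion import AdhesionState
from .config import SimulationConfig
from .network import Box, Cylinder, generate_network
from .params import PhysicalParams
from .simulate import World
from .toy import ToySpringSystem

__all__ = ["make_fixture", "build_world", "FIXTURES"]

FIXTURES = ("toy_spring", "tiny_cylinder", "two_cell_cylinder", "plated_box")


def build_world(config: SimulationConfig) -> World:
    """Construct the initial world (network, cells, empty adhesions) from a config."""
    from .network import domain_from_dict

    p = config.params
    domain = domain_from_dict(config.domain)
    net_seed = config.network_seed if config.network_seed is not None else config.seed
    net = generate_network(
        domain, config.n_fibers, config.segments_per_fiber, config.crosslink_radius,
        seed=net_seed, k_axial=p.k_axial, k_bend=p.k_bend, k_cross=p.k_cross, D_e=p.D_e,
    )
    rng = np.random.default_rng(config.seed + 1)
    cells, polarities, coords = [], [], []
    for k, spec in enumerate(config.cells):
        cell = make_cell_mesh(
            spec["center"], radius=spec["radius"], k_edge=p.k_edge, gamma=p.gamma,
            D_c=p.D_c, cell_id=k,
        )
        cells.append(cell)
        coords.append(cell.nodes.copy())
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        polarities.append(PolarityState(d_pol=d, kappa=p.kappa, alpha_L=p.alpha_L, f_L=p.f_L))
    adhesions = AdhesionState(
        bonds={k: {} for k in range(len(cells))},
        k_fa=p.k_fa, n_int=p.n_int, d_bind=p.d_bind, d_break=p.d_break, p_on=p.p_on,
    )
    return World(
        net=net, cells=cells, adhesions=adhesions, polarities=polarities,
        cell_coords=coords, ecm_coords=net.nodes.copy(), sensing_radius=p.sensing_radius,
    )


def _cylinder_config(seed: int, centers: list, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed,
        domain={"kind": "cylinder", "radius": 20.0, "length": 100.0},
        n_fibers=48,
        segments_per_fiber=5,
        crosslink_radius=6.0,
        cells=[{"center": list(c), "radius": 6.0} for c in centers],
    )
    base.update(overrides)
    return SimulationConfig(**base)


def make_fixture(name: str, seed: int = 0, spacing: float = 30.0, **overrides):
    """Build a named scenario; returns (world, config) or the toy system.

    Deterministic for fixed seed.  ``spacing`` applies to
    ``two_cell_cylinder`` (centre-to-centre distance along the axis).
    """
    if name == "toy_spring":
        return ToySpringSystem(a=1.0, b=1.0, D=1.0), {"x0": 0.1, "t_end": 1.0, "n_samples": 101}

    if name == "tiny_cylinder":
        cfg = _cylinder_config(seed, [(0.0, 0.0, 50.0)], **overrides)
    elif name == "two_cell_cylinder":
        half = spacing / 2.0
        cfg = _cylinder_config(
            seed, [(0.0, 0.0, 50.0 - half), (0.0, 0.0, 50.0 + half)], **overrides
        )
    elif name == "plated_box":
        # 5-cell cluster near the left edge (quincunx in the mid-height plane)
        cluster = [
            (25.0, 50.0, 25.0),
            (40.0, 35.0, 25.0),
            (40.0, 65.0, 25.0),
            (55.0, 50.0, 25.0),
            (25.0, 20.0, 25.0),
        ]
        isolated = [(225.0, 50.0, 25.0)]
        base = dict(
            seed=seed,
            domain={"kind": "box", "lx": 250.0, "ly": 100.0, "lz": 50.0},
            n_fibers=90,
            segments_per_fiber=5,
            crosslink_radius=7.0,
            cells=[{"center": list(c), "radius": 6.0} for c in cluster + isolated],
        )
        base.update(overrides)
        cfg = SimulationConfig(**base)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")

    return build_world(cfg), cfg
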