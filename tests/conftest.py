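"""Shared fixtures: small geometries, a linear world, and cached study runs."""

import numpy as np
import pytest
import trimesh

from ecmdfl.adhesion import AdhesionState
from ecmdfl.cells import CellMesh, PolarityState, make_cell_mesh
from ecmdfl.config import SimulationConfig
from ecmdfl.network import Cylinder, ECMNetwork, generate_network
from ecmdfl.simulate import World


@pytest.fixture(scope="session")
def small_net():
    """Connected desk-scale cylinder network (~290 nodes)."""
    return generate_network(Cylinder(20.0, 100.0), 48, 5, 6.0, seed=0)


@pytest.fixture(scope="session")
def cell():
    return make_cell_mesh((0.0, 0.0, 50.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def build_linear_world(seed=3, Ne=20, n_fixed=4, k_net=0.5, k_edge=0.3, k_fa=0.2):
    """Fully linear test system: zero-rest-length springs everywhere.

    Hookean springs with zero rest length give forces linear in the
    coordinates, cortical tension is off, and the preset bonds have zero
    rest length, so the complete vector field is linear.  Adhesion
    kinetics are disabled (p_on = 0, unreachable d_break).
    """
    r = np.random.default_rng(seed)
    nodes = r.uniform(0, 20, size=(Ne, 3))
    segs = np.array(
        [(i, j) for i in range(Ne) for j in range(i + 1, Ne)
         if np.linalg.norm(nodes[i] - nodes[j]) < 9.0]
    )
    net = ECMNetwork(
        nodes=nodes, segments=segs, seg_rest=np.zeros(len(segs)),
        bend_triples=np.zeros((0, 3), int), crosslinks=np.zeros((0, 2), int),
        cross_rest=np.zeros(0), boundary_fixed=np.arange(Ne) < n_fixed,
        fiber_id=np.zeros(Ne, int), k_axial=k_net, k_bend=0.0, k_cross=k_net, D_e=10.0,
    )
    ico = trimesh.creation.icosphere(subdivisions=0, radius=3.0)
    cnodes = np.asarray(ico.vertices) + np.array([10.0, 10.0, 10.0])
    edges = np.unique(np.sort(ico.edges_unique, axis=1), axis=0)
    cell = CellMesh(
        nodes=cnodes, triangles=np.asarray(ico.faces), edges=edges,
        rest_edge_lengths=np.zeros(len(edges)), rest_area=0.0,
        k_edge=k_edge, gamma=0.0, D_c=10.0,
    )
    adh = AdhesionState(
        bonds={0: {0: (4, 2, 0.0), 3: (7, 1, 0.0), 5: (11, 3, 0.0)}},
        k_fa=k_fa, n_int=2, d_bind=4.0, d_break=1e9, p_on=0.0,
    )
    pol = [PolarityState(d_pol=np.array([1.0, 0.0, 0.0]), kappa=0.0, f_L=0.0)]
    world = World(
        net=net, cells=[cell], adhesions=adh, polarities=pol,
        cell_coords=[cnodes.copy()], ecm_coords=nodes.copy(), sensing_radius=50.0,
    )
    cfg = SimulationConfig(
        dt=0.25, t_end=40.0, record_every=1, seed=0,
        cells=[{"center": [10.0, 10.0, 10.0], "radius": 3.0}],
    )
    return world, cfg


@pytest.fixture(scope="session")
def linear_world():
    return build_linear_world()
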