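"""Artifact plumbing: HDF5 containers, VTK legacy output, CSV tables, manifests."""

from __future__ import annotations

import hashlib
import json
import time

import h5py
import numpy as np
import pandas as pd

from .augmented import LatentBasis
from .config import SimulationConfig
from .simulate import TrajectoryDataset

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_basis",
    "load_basis",
    "save_model",
    "load_model",
    "write_vtk_polydata",
    "bonds_to_frame",
    "write_manifest",
]


def save_trajectory(traj: TrajectoryDataset, path) -> None:
    """One HDF5 container per run: /times, /cells, /ecm, /bonds, /config."""
    with h5py.File(path, "w") as f:
        f["times"] = traj.times
        f["cells/x"] = traj.cell_xs
        f["cells/f_ce"] = traj.f_ce
        f["cells/f_fa"] = traj.f_fa_c
        f["cells/u"] = traj.u
        f["cells/polarity"] = traj.polarity
        f["ecm/x"] = traj.ecm_xs
        f["ecm/f_elas"] = traj.f_elas_e
        g = f.create_group("bonds")
        for fi, frame in enumerate(traj.bonds):
            for k, ba in enumerate(frame):
                g[f"f{fi}/c{k}"] = ba
                if traj.bond_rest:
                    g[f"f{fi}/r{k}"] = traj.bond_rest[fi][k]
        if traj.config is not None:
            f.attrs["config"] = json.dumps(traj.config.to_dict())
        if traj.seed is not None:
            f.attrs["seed"] = traj.seed


def load_trajectory(path) -> TrajectoryDataset:
    with h5py.File(path, "r") as f:
        n_frames, K = f["cells/x"].shape[:2]
        bonds = [
            [f[f"bonds/f{fi}/c{k}"][()].astype(np.int64).reshape(-1, 3) for k in range(K)]
            for fi in range(n_frames)
        ]
        bond_rest = [
            [f[f"bonds/f{fi}/r{k}"][()].astype(float).reshape(-1)
             if f"bonds/f{fi}/r{k}" in f else np.zeros(len(bonds[fi][k]))
             for k in range(K)]
            for fi in range(n_frames)
        ]
        cfg = None
        if "config" in f.attrs:
            cfg = SimulationConfig.from_dict(json.loads(f.attrs["config"]))
        return TrajectoryDataset(
            times=f["times"][()],
            cell_xs=f["cells/x"][()],
            ecm_xs=f["ecm/x"][()],
            f_ce=f["cells/f_ce"][()],
            f_fa_c=f["cells/f_fa"][()],
            f_elas_e=f["ecm/f_elas"][()],
            u=f["cells/u"][()],
            bonds=bonds,
            bond_rest=bond_rest,
            polarity=f["cells/polarity"][()],
            config=cfg,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_basis(basis: LatentBasis, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("basis")
        g["Vc"] = basis.V_c
        g["Ve"] = basis.V_e
        g["eigvals_c"] = basis.evals_c
        g["eigvals_e"] = basis.evals_e
        g["mean_c"] = basis.mean_c
        g["mean_e"] = basis.mean_e
        g.attrs["N_c"] = basis.N_c
        g.attrs["N_e"] = basis.N_e


def load_basis(path) -> LatentBasis:
    with h5py.File(path, "r") as f:
        g = f["basis"]
        return LatentBasis(
            V_c=g["Vc"][()], V_e=g["Ve"][()],
            evals_c=g["eigvals_c"][()], evals_e=g["eigvals_e"][()],
            mean_c=g["mean_c"][()], mean_e=g["mean_e"][()],
            N_c=int(g.attrs["N_c"]), N_e=int(g.attrs["N_e"]),
        )


def save_model(results, path) -> None:
    """Store identified matrices together with their basis."""
    save_basis(results.basis, path)
    with h5py.File(path, "a") as f:
        g = f.create_group("model")
        g["A"] = results.A
        g["B"] = results.B
        g["C"] = results.C
        g["G"] = results.G
        g["a0"] = results.a0
        g["g0"] = results.g0
        g.attrs["ridge"] = results.ridge
        g.attrs["resid_rms_cell"] = results.resid_rms_cell
        g.attrs["resid_rms_ecm"] = results.resid_rms_ecm
        g.attrs["data_rms_cell"] = results.data_rms_cell
        g.attrs["data_rms_ecm"] = results.data_rms_ecm


def load_model(path):
    from .latent import LatentDynamicsModel, LatentDynamicsResults

    basis = load_basis(path)
    with h5py.File(path, "r") as f:
        g = f["model"]
        shell = LatentDynamicsModel(
            z_c=np.zeros((0, g["A"].shape[0])), u=np.zeros((0, g["B"].shape[1])),
            z_e_cell=np.zeros((0, g["G"].shape[0])), dz_c=np.zeros((0, g["A"].shape[0])),
            z_e=np.zeros((0, g["G"].shape[0])), dz_e_resid=np.zeros((0, g["G"].shape[0])),
            basis=basis,
        )
        return LatentDynamicsResults(
            model=shell, A=g["A"][()], B=g["B"][()], C=g["C"][()], G=g["G"][()],
            a0=g["a0"][()], g0=g["g0"][()],
            ridge=float(g.attrs["ridge"]),
            resid_rms_cell=float(g.attrs["resid_rms_cell"]),
            resid_rms_ecm=float(g.attrs["resid_rms_ecm"]),
            data_rms_cell=float(g.attrs["data_rms_cell"]),
            data_rms_ecm=float(g.attrs["data_rms_ecm"]),
        )


def write_vtk_polydata(path, points: np.ndarray, lines: np.ndarray | None = None,
                       polygons: np.ndarray | None = None) -> None:
    """Minimal legacy ASCII VTK polydata writer (points + lines or triangles)."""
    points = np.asarray(points, dtype=float)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\necmdfl geometry\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(points)} float\n")
        for p in points:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        if lines is not None and len(lines):
            lines = np.asarray(lines, dtype=int)
            f.write(f"LINES {len(lines)} {3 * len(lines)}\n")
            for a, b in lines:
                f.write(f"2 {a} {b}\n")
        if polygons is not None and len(polygons):
            polygons = np.asarray(polygons, dtype=int)
            f.write(f"POLYGONS {len(polygons)} {4 * len(polygons)}\n")
            for a, b, c in polygons:
                f.write(f"3 {a} {b} {c}\n")


def bonds_to_frame(traj: TrajectoryDataset) -> pd.DataFrame:
    """Long-format bond table (t, cell, cell_node, ecm_node, n_int)."""
    rows = []
    for fi, frame in enumerate(traj.bonds):
        t = traj.times[fi]
        for k, ba in enumerate(frame):
            for i, j, n in ba:
                rows.append((t, k, int(i), int(j), int(n)))
    return pd.DataFrame(rows, columns=["time", "cell", "cell_node", "ecm_node", "n_int"])


def write_manifest(path, config: SimulationConfig, stages: dict) -> dict:
    """Run manifest: config hash, seed, package version, stage artifact paths."""
    from . import __version__

    cfg = config.to_dict()
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "config_hash": digest,
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {k: str(v) for k, v in stages.items()},
    }
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
        f.write("\n")
    return manifest
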