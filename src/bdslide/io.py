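"""File formats: native system/trajectory containers and XYZ/PDB export.

The native system file is JSON (floats serialised via ``repr`` round-trip,
hence bit-exact); trajectories use HDF5 with provenance attributes (seed,
config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .engine import Protocol, Trajectory
from .model import SystemSpec, Topology


def _arr(a):
    return np.asarray(a).tolist()


def save_system(system: SystemSpec, path) -> None:
    t = system.topology
    doc = {
        "format": "bdslide-system",
        "version": __version__,
        "names": list(system.names),
        "positions": _arr(system.positions),
        "sigma": _arr(system.sigma),
        "stokes": _arr(system.stokes),
        "charge": _arr(system.charge),
        "molecule": _arr(system.molecule),
        "residue": _arr(system.residue),
        "topology": {
            "bonds": _arr(t.bonds), "bond_k": _arr(t.bond_k),
            "bond_r0": _arr(t.bond_r0),
            "angles": _arr(t.angles), "angle_k": _arr(t.angle_k),
            "angle_t0": _arr(t.angle_t0),
            "torsions": _arr(t.torsions), "torsion_k": _arr(t.torsion_k),
            "torsion_p0": _arr(t.torsion_p0),
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_system(path) -> SystemSpec:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "bdslide-system":
        raise ValueError(f"{path}: not a bdslide system file")
    td = doc["topology"]
    topo = Topology(
        np.array(td["bonds"], np.int64).reshape(-1, 2),
        np.array(td["bond_k"]), np.array(td["bond_r0"]),
        np.array(td["angles"], np.int64).reshape(-1, 3),
        np.array(td["angle_k"]), np.array(td["angle_t0"]),
        np.array(td["torsions"], np.int64).reshape(-1, 4),
        np.array(td["torsion_k"]), np.array(td["torsion_p0"]))
    return SystemSpec(np.array(doc["positions"]), np.array(doc["sigma"]),
                      np.array(doc["stokes"]), np.array(doc["charge"]),
                      np.array(doc["molecule"], np.int64),
                      np.array(doc["residue"], np.int64),
                      list(doc["names"]), topo)


def provenance_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def save_trajectory(traj: Trajectory, path) -> None:
    import h5py
    with h5py.File(path, "w") as h:
        h.create_dataset("times_ns", data=traj.times_ns)
        h.create_dataset("frames", data=traj.frames)
        if traj.energies is not None:
            h.create_dataset("energies", data=traj.energies)
        h.attrs["version"] = __version__
        prov = dict(traj.provenance)
        if traj.protocol is not None:
            prov["protocol"] = {k: v for k, v in traj.protocol.__dict__.items()}
        h.attrs["provenance"] = json.dumps(prov, default=str)
        h.attrs["config_hash"] = provenance_hash(prov)


def load_trajectory(path) -> Trajectory:
    import h5py
    with h5py.File(path, "r") as h:
        prov = json.loads(h.attrs["provenance"])
        proto = None
        if "protocol" in prov:
            proto = Protocol(**prov.pop("protocol"))
        return Trajectory(h["times_ns"][...], h["frames"][...],
                          h["energies"][...] if "energies" in h else None,
                          proto, prov)


def export_xyz(traj: Trajectory, names, path) -> None:
    """Multi-frame XYZ with the bead-type name in the element column."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    n = traj.frames.shape[1]
    with open(path, "w") as fh:
        for t, frame in zip(traj.times_ns, traj.frames):
            fh.write(f"{n}\nt = {t:.6f} ns\n")
            for nm, (x, y, z) in zip(names, frame):
                fh.write(f"{nm:<4s} {x:12.5f} {y:12.5f} {z:12.5f}\n")


def export_pdb(traj: Trajectory, system: SystemSpec, path) -> None:
    """Multi-model PDB (one bead per atom record) with bond CONECTs."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    n = system.n_beads
    atoms = struc.AtomArrayStack(traj.n_frames, n)
    atoms.coord = traj.frames.astype(np.float32)
    atoms.chain_id = np.where(np.array(system.molecule) == 0, "A", "B")
    atoms.res_id = np.asarray(system.residue) + 1
    atoms.res_name = np.array([nm[:3] for nm in system.names])
    atoms.atom_name = np.array(system.names)
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.full(n, True)
    bonds = system.topology.bonds
    if len(bonds):
        bl = struc.BondList(n, np.column_stack(
            [bonds, np.full(len(bonds), struc.BondType.SINGLE)]))
        atoms.bonds = bl
    f = pdb.PDBFile()
    pdb.set_structure(f, atoms)
    f.write(str(path))
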