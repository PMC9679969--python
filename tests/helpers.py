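"""Shared builders for hand-crafted structural fixtures."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from ligmodes.structio import AtomRecord, Structure


def mini_structure(atoms, id: str = "mini") -> Structure:
    """Build a Structure from tuples
    (name, element, resname, resseq, chain, (x, y, z)[, hetero])."""
    records = []
    for i, spec in enumerate(atoms):
        name, element, resname, resseq, chain, xyz = spec[:6]
        hetero = spec[6] if len(spec) > 6 else False
        records.append(
            AtomRecord(
                serial=i + 1, name=name, element=element, resname=resname,
                resseq=resseq, chain_id=chain, coords=np.asarray(xyz, dtype=float),
                is_hetero=hetero,
            )
        )
    return Structure.from_atoms(records, id=id)


def hexagon_coords(center, normal, radius: float = 1.39) -> np.ndarray:
    """Six vertices of a regular hexagon in the plane perpendicular to
    ``normal`` through ``center``."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = np.deg2rad(np.arange(0, 360, 60))
    return np.asarray(center) + radius * (
        np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
    )


def benzene_atoms(center, normal, resname="BNZ", resseq=1, chain="L", hetero=True):
    """Atom tuples of an idealized benzene (1.39 Å sides)."""
    return [
        (f"C{i+1}", "C", resname, resseq, chain, tuple(p), hetero)
        for i, p in enumerate(hexagon_coords(center, normal))
    ]


def phe_ring_atoms(center, normal, resseq=10, chain="A"):
    """A PHE aromatic ring with template atom names on ideal hexagon sites."""
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    return [
        (name, "C", "PHE", resseq, chain, tuple(p))
        for name, p in zip(names, hexagon_coords(center, normal))
    ]


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation and translation."""
    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return rot, t


def apply_rigid(coords: np.ndarray, rot: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ rot.T + t
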