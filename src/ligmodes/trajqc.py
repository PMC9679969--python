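"""Trajectory admission filters.

Before fingerprint statistics are pooled, each production run must pass two
criteria: the ligand stays bound to the protein in every frame, and a
partially bound ligand never collapses into self-stacked (hairpin)
conformations, which would contaminate the binding-mode statistics with
intramolecular aromatic contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .fingerprints import InteractionCriteria, InteractionDetector, _rings_stack, ring_geometry
from .structio import Structure, Trajectory

__all__ = [
    "QCReport",
    "min_protein_ligand_distance",
    "filter_bound",
    "detect_self_stacking",
    "qc_trajectory",
]


@dataclass
class QCReport:
    """Per-trajectory admission diagnostics."""

    trajectory_id: str
    min_distance_per_frame: np.ndarray
    bound_all_frames: bool
    self_stacking_frames: list[int] = field(default_factory=list)

    @property
    def admitted(self) -> bool:
        return self.bound_all_frames and not self.self_stacking_frames


def _heavy_indices(topology: Structure, ligand_resnames: frozenset[str]) -> tuple[np.ndarray, np.ndarray]:
    heavy = topology.element != "H"
    lig = np.isin(topology.resname, list(ligand_resnames)) & heavy
    prot = ~np.isin(topology.resname, list(ligand_resnames)) & heavy & ~topology.is_hetero
    if not lig.any():
        raise ValueError(f"no ligand atoms with resnames {sorted(ligand_resnames)}")
    return np.flatnonzero(prot), np.flatnonzero(lig)


def min_protein_ligand_distance(
    frame: np.ndarray, topology: Structure, ligand_resnames: Iterable[str]
) -> float:
    """Minimum heavy-atom distance between protein and ligand in one frame."""
    ligand_resnames = frozenset(r.upper() for r in ligand_resnames)
    prot, lig = _heavy_indices(topology, ligand_resnames)
    return float(cdist(frame[prot], frame[lig]).min())


def filter_bound(
    traj: Trajectory,
    ligand_resnames: Iterable[str],
    contact_d: float = 4.5,
) -> QCReport:
    """Bound-throughout criterion: the ligand's minimum heavy-atom distance
    to the protein must be <= ``contact_d`` in every frame."""
    ligand_resnames = frozenset(r.upper() for r in ligand_resnames)
    prot, lig = _heavy_indices(traj.topology, ligand_resnames)
    mins = np.array(
        [cdist(traj.coords[f][prot], traj.coords[f][lig]).min() for f in range(traj.frame_count)]
    )
    return QCReport(
        trajectory_id=traj.id,
        min_distance_per_frame=mins,
        bound_all_frames=bool(np.all(mins <= contact_d)),
    )


def detect_self_stacking(
    traj: Trajectory,
    ligand_resnames: Iterable[str],
    criteria: InteractionCriteria | None = None,
    partial_threshold: int = 3,
    contact_d: float = 4.5,
) -> list[int]:
    """Frames where a partially bound ligand self-stacks.

    A frame is flagged when fewer than ``partial_threshold`` protein
    residues are in heavy-atom contact (<= ``contact_d``) with the ligand
    AND two non-adjacent ligand repeat-unit rings satisfy the π-stacking
    criterion with each other.
    """
    criteria = criteria or InteractionCriteria()
    ligand_resnames = frozenset(r.upper() for r in ligand_resnames)
    detector = InteractionDetector(traj.topology, ligand_resnames, criteria)
    rings = detector.ligand_rings
    if len(rings) < 2:
        raise ValueError(f"ligand has {len(rings)} perceived rings; need >= 2")
    top = traj.topology
    heavy = top.element != "H"
    lig_mask = np.isin(top.resname, list(ligand_resnames)) & heavy
    prot_mask = ~lig_mask & heavy & ~top.is_hetero
    prot_idx = np.flatnonzero(prot_mask)
    lig_idx = np.flatnonzero(lig_mask)
    residues = [(str(top.chain_id[i]), int(top.resseq[i])) for i in prot_idx]

    flagged: list[int] = []
    for f in range(traj.frame_count):
        coords = traj.coords[f]
        d = cdist(coords[prot_idx], coords[lig_idx])
        in_contact = {residues[k] for k in np.flatnonzero((d <= contact_d).any(axis=1))}
        if len(in_contact) >= partial_threshold:
            continue
        geometries = [ring_geometry(coords, r.atom_indices) for r in rings]
        for a in range(len(rings)):
            stacked = False
            for b in range(a + 1, len(rings)):
                if abs(rings[a].owner - rings[b].owner) < 2:
                    continue  # adjacent repeat units cannot stack without bond strain
                ca, na, _ = geometries[a]
                cb, nb, _ = geometries[b]
                if _rings_stack(ca, na, cb, nb, criteria):
                    flagged.append(f)
                    stacked = True
                    break
            if stacked:
                break
    return flagged


def qc_trajectory(
    traj: Trajectory,
    ligand_resnames: Iterable[str],
    contact_d: float = 4.5,
    criteria: InteractionCriteria | None = None,
    partial_threshold: int = 3,
) -> QCReport:
    """Full admission check: bound throughout and no partially-bound
    self-stacking frames."""
    report = filter_bound(traj, ligand_resnames, contact_d)
    report.self_stacking_frames = detect_self_stacking(
        traj, ligand_resnames, criteria, partial_threshold, contact_d
    )
    return report
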