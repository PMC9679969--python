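"""Geometric protein-ligand interaction fingerprints.

Each trajectory frame is reduced to a boolean vector over
``(chain, residue, interaction type)`` descriptors with the five types

* ``hydrophobic`` — protein C/S heavy atom near a ligand carbon,
* ``pi_stacking`` — aromatic ring pair, face-to-face or edge-to-face,
* ``hbond_protein_donor`` / ``hbond_protein_acceptor`` — heavy-atom
  donor-acceptor contacts, the role taken by the protein side,
* ``oh_pi`` — a Ser/Thr/Tyr hydroxyl oxygen over a ligand ring face.

All criteria are geometric, defined on heavy atoms (hydrogens are accepted
but not required) and fully configurable through
:class:`InteractionCriteria`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import cdist

from .structio import STANDARD_AMINO_ACIDS, Structure, Trajectory

__all__ = [
    "InteractionCriteria",
    "RingSystem",
    "Fingerprint",
    "INTERACTION_TYPES",
    "perceive_rings",
    "ring_geometry",
    "detect_hydrophobic",
    "detect_pi_stacking",
    "detect_hbond",
    "detect_oh_pi",
    "fingerprint_trajectory",
    "InteractionDetector",
]

logger = logging.getLogger(__name__)

INTERACTION_TYPES = (
    "hydrophobic",
    "pi_stacking",
    "hbond_protein_donor",
    "hbond_protein_acceptor",
    "oh_pi",
)

# single-bond covalent radii, Å
_COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "H": 0.31}
_BOND_SLACK = 0.4

# residue-template ring atoms for the four aromatic amino acids
_PROTEIN_RING_TEMPLATES: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}

_PROTEIN_DONORS: dict[str, tuple[str, ...]] = {
    "*backbone": ("N",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}
_PROTEIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*backbone": ("O", "OXT"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}
_HYDROXYL_ATOMS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for all detectors (distances Å, angles degrees).

    Defaults follow widely used interaction-fingerprinting conventions:
    4.5 Å hydrophobic carbon contact; π-stacking face-to-face at <= 5.5 Å
    centroid distance and <= 35° interplanar angle or edge-to-face at
    <= 6.5 Å and >= 50°; 3.5 Å heavy-atom hydrogen bond; OH-π at <= 4.5 Å
    hydroxyl-O-to-centroid with <= 40° off the ring axis.
    """

    hydrophobic_d: float = 4.5
    pi_centroid_d_parallel: float = 5.5
    pi_angle_parallel: float = 35.0
    pi_centroid_d_tshaped: float = 6.5
    pi_angle_tshaped_min: float = 50.0
    hbond_da_d: float = 3.5
    ohpi_d: float = 4.5
    ohpi_axis_angle: float = 40.0
    # optional tightening when explicit hydrogens are present
    hbond_angle_filter: bool = False
    hbond_dha_min_angle: float = 130.0

    def __post_init__(self) -> None:
        for name in (
            "hydrophobic_d", "pi_centroid_d_parallel", "pi_centroid_d_tshaped",
            "hbond_da_d", "ohpi_d",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pi_angle_parallel", "pi_angle_tshaped_min", "ohpi_axis_angle"):
            if not 0 < getattr(self, name) <= 90:
                raise ValueError(f"{name} must lie in (0, 90] degrees")

    def scaled(self, **kwargs) -> "InteractionCriteria":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RingSystem:
    """An aromatic ring: member atom indices plus best-fit plane geometry.

    ``owner`` is ``(chain, resseq)`` for protein rings or the ligand
    repeat-unit index (int) for ligand rings.  ``centroid``/``normal``
    describe the topology frame; per-frame geometry is recomputed with
    :func:`ring_geometry`.
    """

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray
    owner: tuple[str, int] | int


def ring_geometry(coords: np.ndarray, atom_indices: Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, unit best-fit-plane normal and max planar deviation (Å)."""
    pts = np.asarray(coords, dtype=float)[list(atom_indices)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    deviation = float(np.max(np.abs(centered @ normal)))
    return centroid, normal, deviation


def _infer_bonds(coords: np.ndarray, elements: np.ndarray) -> nx.Graph:
    """Distance-based covalent bond perception (covalent radii + 0.4 Å slack)."""
    n = len(elements)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    radii = np.array([_COVALENT_RADII.get(e, 0.77) for e in elements])
    d = cdist(coords, coords)
    limit = radii[:, None] + radii[None, :] + _BOND_SLACK
    ii, jj = np.nonzero((d <= limit) & (d > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(int(i), int(j))
    return g


def perceive_rings(
    structure: Structure,
    ligand_resnames: Iterable[str],
    max_planar_deviation: float = 0.3,
) -> list[RingSystem]:
    """Aromatic ring systems of protein (template-based, PHE/TYR/TRP/HIS)
    and ligand (6-membered all-carbon cycles from distance-inferred bonds,
    accepted when the best-fit plane deviation is <= ``max_planar_deviation``).

    Ligand rings get integer repeat-unit owners in atom-index order, so
    consecutive owners correspond to adjacent repeat units for a linear
    polymer-like ligand.
    """
    rings: list[RingSystem] = []
    ligand_resnames = frozenset(r.upper() for r in ligand_resnames)

    # protein rings from residue templates
    prot = np.isin(structure.resname, list(_PROTEIN_RING_TEMPLATES))
    for chain, resseq in sorted(
        {(str(structure.chain_id[i]), int(structure.resseq[i])) for i in np.flatnonzero(prot)}
    ):
        res_mask = (structure.chain_id == chain) & (structure.resseq == resseq)
        resname = str(structure.resname[np.flatnonzero(res_mask)[0]])
        name_to_idx = {str(structure.name[i]): int(i) for i in np.flatnonzero(res_mask)}
        for template in _PROTEIN_RING_TEMPLATES[resname]:
            try:
                idx = tuple(name_to_idx[a] for a in template)
            except KeyError:
                logger.warning("skipping %s %s %d: missing ring atoms", resname, chain, resseq)
                continue
            centroid, normal, _ = ring_geometry(structure.coords, idx)
            rings.append(RingSystem(idx, centroid, normal, owner=(chain, resseq)))

    # ligand rings by cycle perception
    lig_idx = np.flatnonzero(np.isin(structure.resname, list(ligand_resnames)))
    if len(lig_idx) > 0:
        g = _infer_bonds(structure.coords[lig_idx], structure.element[lig_idx])
        found: list[tuple[int, ...]] = []
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) != 6:
                continue
            global_idx = tuple(sorted(int(lig_idx[i]) for i in cycle))
            if any(structure.element[i] != "C" for i in global_idx):
                continue
            centroid, normal, dev = ring_geometry(structure.coords, global_idx)
            if dev > max_planar_deviation:
                continue
            found.append(global_idx)
        for unit, global_idx in enumerate(sorted(found, key=min)):
            centroid, normal, _ = ring_geometry(structure.coords, global_idx)
            rings.append(RingSystem(global_idx, centroid, normal, owner=unit))
    return rings


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes, folded to [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def _axis_angle(vec: np.ndarray, normal: np.ndarray) -> float:
    """Angle between a vector and the (sign-folded) ring axis, degrees."""
    norm = np.linalg.norm(vec)
    if norm == 0:
        return 0.0
    c = abs(float(np.dot(vec / norm, normal)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


class InteractionDetector:
    """Precomputed atom bookkeeping for fast per-frame detection.

    Built once from a topology; every ``*_frame`` method takes an (n, 3)
    coordinate array for one frame and returns the detected descriptors.
    """

    def __init__(
        self,
        topology: Structure,
        ligand_resnames: Iterable[str],
        criteria: InteractionCriteria | None = None,
    ):
        self.topology = topology
        self.criteria = criteria or InteractionCriteria()
        self.ligand_resnames = frozenset(r.upper() for r in ligand_resnames)
        lig_mask = np.isin(topology.resname, list(self.ligand_resnames))
        if not lig_mask.any():
            raise ValueError(
                f"ligand resnames {sorted(self.ligand_resnames)} not present in topology"
            )
        self.ligand_idx = np.flatnonzero(lig_mask)
        prot_mask = np.isin(topology.resname, list(STANDARD_AMINO_ACIDS)) & ~lig_mask
        self.protein_idx = np.flatnonzero(prot_mask)
        heavy = topology.element != "H"

        def _residue_of(i: int) -> tuple[str, int]:
            return (str(topology.chain_id[i]), int(topology.resseq[i]))

        self._residue_of = _residue_of
        # hydrophobic partners
        self.prot_c = np.flatnonzero(prot_mask & np.isin(topology.element, ["C", "S"]))
        self.lig_c = np.flatnonzero(lig_mask & (topology.element == "C"))
        # hydrogen-bond partners
        donors, acceptors = [], []
        for i in np.flatnonzero(prot_mask & heavy & np.isin(topology.element, ["N", "O"])):
            resname, atname = str(topology.resname[i]), str(topology.name[i])
            if atname in _PROTEIN_DONORS["*backbone"] and resname != "PRO":
                donors.append(i)
            elif atname in _PROTEIN_DONORS.get(resname, ()):
                donors.append(i)
            if atname in _PROTEIN_ACCEPTORS["*backbone"] or atname in _PROTEIN_ACCEPTORS.get(resname, ()):
                acceptors.append(i)
        self.prot_donors = np.array(donors, dtype=int)
        self.prot_acceptors = np.array(acceptors, dtype=int)
        self.hydroxyl_o = np.array(
            [
                i
                for i in np.flatnonzero(prot_mask)
                if (str(topology.resname[i]), str(topology.name[i])) in _HYDROXYL_ATOMS
            ],
            dtype=int,
        )
        self._classify_ligand_oxygens()
        rings = perceive_rings(topology, self.ligand_resnames)
        self.protein_rings = [r for r in rings if isinstance(r.owner, tuple)]
        self.ligand_rings = [r for r in rings if isinstance(r.owner, int)]
        self.hydrogens = np.flatnonzero(topology.element == "H")

    def _classify_ligand_oxygens(self) -> None:
        """Split ligand oxygens into acceptors and (hydroxyl) donors via the
        inferred bond graph; ester oxygens are acceptors only."""
        top = self.topology
        lig = self.ligand_idx
        g = _infer_bonds(top.coords[lig], top.element[lig])
        acceptors, donors = [], []
        local_elem = top.element[lig]
        for local, global_i in enumerate(lig):
            if local_elem[local] != "O":
                continue
            neighbors = list(g.neighbors(local))
            degree = len(neighbors)
            if degree >= 2:
                acceptors.append(global_i)  # bridging ester O
                continue
            carbon_has_other_o = any(
                local_elem[nn] == "O" and nn != local
                for n in neighbors
                for nn in g.neighbors(n)
            )
            acceptors.append(global_i)
            if not carbon_has_other_o:
                donors.append(global_i)  # hydroxyl-like terminal O
        self.lig_o_acceptors = np.array(acceptors, dtype=int)
        self.lig_o_donors = np.array(donors, dtype=int)

    # ---- per-frame detectors -------------------------------------------

    def hydrophobic_frame(self, coords: np.ndarray) -> set[tuple[str, int]]:
        if len(self.prot_c) == 0 or len(self.lig_c) == 0:
            return set()
        d = cdist(coords[self.prot_c], coords[self.lig_c])
        hits = np.flatnonzero((d <= self.criteria.hydrophobic_d).any(axis=1))
        return {self._residue_of(int(self.prot_c[i])) for i in hits}

    def pi_stacking_frame(self, coords: np.ndarray) -> set[tuple[tuple[str, int], int]]:
        out: set[tuple[tuple[str, int], int]] = set()
        for pring in self.protein_rings:
            pc, pn, _ = ring_geometry(coords, pring.atom_indices)
            for lring in self.ligand_rings:
                lc, ln, _ = ring_geometry(coords, lring.atom_indices)
                if _rings_stack(pc, pn, lc, ln, self.criteria):
                    out.add((pring.owner, lring.owner))
        return out

    def _hbond_pairs(
        self, coords: np.ndarray, prot_idx: np.ndarray, lig_idx: np.ndarray
    ) -> list[tuple[int, int]]:
        if len(prot_idx) == 0 or len(lig_idx) == 0:
            return []
        d = cdist(coords[prot_idx], coords[lig_idx])
        ii, jj = np.nonzero(d <= self.criteria.hbond_da_d)
        return [(int(prot_idx[i]), int(lig_idx[j])) for i, j in zip(ii, jj)]

    def _dha_ok(self, coords: np.ndarray, donor: int, acceptor: int) -> bool:
        """Optional D-H...A angle filter; permissive when no H is attached."""
        if not self.criteria.hbond_angle_filter or len(self.hydrogens) == 0:
            return True
        dh = np.linalg.norm(coords[self.hydrogens] - coords[donor], axis=1)
        attached = self.hydrogens[dh <= 1.2]
        if len(attached) == 0:
            return True
        for h in attached:
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= self.criteria.hbond_dha_min_angle:
                return True
        return False

    def hbond_frame(self, coords: np.ndarray) -> set[tuple[tuple[str, int], str]]:
        out: set[tuple[tuple[str, int], str]] = set()
        for p, l in self._hbond_pairs(coords, self.prot_donors, self.lig_o_acceptors):
            if self._dha_ok(coords, p, l):
                out.add((self._residue_of(p), "donor"))
        for p, l in self._hbond_pairs(coords, self.prot_acceptors, self.lig_o_donors):
            if self._dha_ok(coords, l, p):
                out.add((self._residue_of(p), "acceptor"))
        return out

    def oh_pi_frame(self, coords: np.ndarray) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        if len(self.hydroxyl_o) == 0:
            return out
        for lring in self.ligand_rings:
            lc, ln, _ = ring_geometry(coords, lring.atom_indices)
            vecs = coords[self.hydroxyl_o] - lc
            dists = np.linalg.norm(vecs, axis=1)
            for k in np.flatnonzero(dists <= self.criteria.ohpi_d):
                if _axis_angle(vecs[k], ln) <= self.criteria.ohpi_axis_angle:
                    out.add(self._residue_of(int(self.hydroxyl_o[k])))
        return out

    def descriptors_frame(self, coords: np.ndarray) -> set[tuple[str, int, str]]:
        """All (chain, resseq, type) descriptors present in one frame."""
        out: set[tuple[str, int, str]] = set()
        for chain, resseq in self.hydrophobic_frame(coords):
            out.add((chain, resseq, "hydrophobic"))
        for (chain, resseq), _ring in self.pi_stacking_frame(coords):
            out.add((chain, resseq, "pi_stacking"))
        for (chain, resseq), role in self.hbond_frame(coords):
            out.add((chain, resseq, f"hbond_protein_{role}"))
        for chain, resseq in self.oh_pi_frame(coords):
            out.add((chain, resseq, "oh_pi"))
        return out


def _rings_stack(
    c1: np.ndarray, n1: np.ndarray, c2: np.ndarray, n2: np.ndarray,
    criteria: InteractionCriteria,
) -> bool:
    d = float(np.linalg.norm(c1 - c2))
    angle = _interplanar_angle(n1, n2)
    face_to_face = d <= criteria.pi_centroid_d_parallel and angle <= criteria.pi_angle_parallel
    edge_to_face = d <= criteria.pi_centroid_d_tshaped and angle >= criteria.pi_angle_tshaped_min
    return face_to_face or edge_to_face


# ---- one-shot functional API (thin wrappers over InteractionDetector) ----

def detect_hydrophobic(
    frame: np.ndarray,
    topology: Structure,
    ligand_resnames: Iterable[str],
    criteria: InteractionCriteria | None = None,
) -> set[tuple[str, int]]:
    """Protein residues with a C/S heavy atom within ``hydrophobic_d`` of
    any ligand carbon in the given frame."""
    return InteractionDetector(topology, ligand_resnames, criteria).hydrophobic_frame(frame)


def detect_pi_stacking(
    frame: np.ndarray,
    rings_protein: Sequence[RingSystem],
    rings_ligand: Sequence[RingSystem],
    criteria: InteractionCriteria | None = None,
) -> set[tuple[tuple[str, int], int]]:
    """(protein residue, ligand ring) pairs stacking face-to-face or
    edge-to-face in the given frame."""
    criteria = criteria or InteractionCriteria()
    out: set[tuple[tuple[str, int], int]] = set()
    for pring in rings_protein:
        pc, pn, _ = ring_geometry(frame, pring.atom_indices)
        for lring in rings_ligand:
            lc, ln, _ = ring_geometry(frame, lring.atom_indices)
            if _rings_stack(pc, pn, lc, ln, criteria):
                out.add((pring.owner, lring.owner))
    return out


def detect_hbond(
    frame: np.ndarray,
    topology: Structure,
    ligand_resnames: Iterable[str],
    criteria: InteractionCriteria | None = None,
) -> set[tuple[tuple[str, int], str]]:
    """Heavy-atom hydrogen bonds as (protein residue, role) records; role is
    the protein side's role (donor or acceptor)."""
    return InteractionDetector(topology, ligand_resnames, criteria).hbond_frame(frame)


def detect_oh_pi(
    frame: np.ndarray,
    topology: Structure,
    ligand_resnames: Iterable[str],
    criteria: InteractionCriteria | None = None,
) -> set[tuple[str, int]]:
    """Protein residues whose Ser/Thr/Tyr hydroxyl O sits over a ligand ring
    face (OH-π geometry: <= ``ohpi_d`` from the centroid, <= ``ohpi_axis_angle``
    off the ring normal)."""
    return InteractionDetector(topology, ligand_resnames, criteria).oh_pi_frame(frame)


@dataclass
class Fingerprint:
    """Boolean frames × descriptors matrix with (chain, resseq, type) labels."""

    matrix: np.ndarray
    labels: list[tuple[str, int, str]]
    frame_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count does not match matrix columns")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate descriptor labels")
        if not self.frame_ids:
            self.frame_ids = list(range(self.matrix.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.matrix.shape[1]

    def with_labels(self, labels: Sequence[tuple[str, int, str]]) -> "Fingerprint":
        """Reindex onto a (super)set of labels, filling absent columns with 0."""
        col = {lab: i for i, lab in enumerate(self.labels)}
        out = np.zeros((self.n_frames, len(labels)), dtype=bool)
        for j, lab in enumerate(labels):
            if lab in col:
                out[:, j] = self.matrix[:, col[lab]]
        return Fingerprint(out, list(labels), list(self.frame_ids))

    @staticmethod
    def concat(parts: Sequence["Fingerprint"]) -> "Fingerprint":
        """Row-wise concatenation on the sorted union of descriptor sets."""
        union = sorted({lab for p in parts for lab in p.labels})
        mats = [p.with_labels(union).matrix for p in parts]
        ids: list[int] = []
        for p in parts:
            ids.extend(p.frame_ids)
        return Fingerprint(np.vstack(mats), union, ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}:{r}:{t}" for c, r, t in self.labels]
        return pd.DataFrame(self.matrix.astype(int), columns=cols, index=self.frame_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="frame")

    @staticmethod
    def from_csv(path) -> "Fingerprint":
        df = pd.read_csv(path, index_col="frame")
        labels = []
        for col in df.columns:
            chain, resseq, typ = col.split(":")
            labels.append((chain, int(resseq), typ))
        return Fingerprint(df.to_numpy(dtype=bool), labels, list(df.index))


def fingerprint_trajectory(
    traj: Trajectory,
    ligand_resnames: Iterable[str],
    criteria: InteractionCriteria | None = None,
) -> Fingerprint:
    """Compute the interaction fingerprint of every frame.

    A (chain, resseq, type) column exists iff that descriptor is detected in
    at least one frame; columns are sorted by (chain, resseq, type).
    """
    detector = InteractionDetector(traj.topology, ligand_resnames, criteria)
    per_frame: list[set[tuple[str, int, str]]] = [
        detector.descriptors_frame(traj.coords[f]) for f in range(traj.frame_count)
    ]
    labels = sorted({d for frame in per_frame for d in frame})
    col = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((traj.frame_count, len(labels)), dtype=bool)
    for f, descriptors in enumerate(per_frame):
        for d in descriptors:
            matrix[f, col[d]] = True
    return Fingerprint(matrix, labels)
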