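"""Crystal-structure characterization.

Detectors for the structural features that characterize a halophilic
PET-hydrolase crystal: disulfide bridges, the Ser-His-Asp catalytic triad
of the alpha/beta-hydrolase fold, coordination shells of monovalent ions
(Na+/Cl-), and least-squares superposition RMSD between protein chains.

All detectors operate on heavy atoms and author residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structio import (
    ION_RESNAMES,
    STANDARD_AMINO_ACIDS,
    WATER_RESNAMES,
    Structure,
)

__all__ = [
    "DisulfideBond",
    "CatalyticTriad",
    "IonSite",
    "SuperpositionResult",
    "detect_disulfides",
    "detect_catalytic_triad",
    "ion_coordination",
    "superpose",
    "pairwise_chain_rmsd",
    "structure_report",
]


@dataclass(frozen=True)
class DisulfideBond:
    """An S-S bridge between two cysteines (typical bond length ~2.05 Å)."""

    chain_id_a: str
    chain_id_b: str
    resseq_a: int
    resseq_b: int
    ss_distance: float

    @property
    def intra_chain(self) -> bool:
        return self.chain_id_a == self.chain_id_b


@dataclass(frozen=True)
class CatalyticTriad:
    """Ser-His-Asp triple with its two hydrogen-bond distances."""

    chain_id: str
    ser_resseq: int
    his_resseq: int
    asp_resseq: int
    d_ser_his: float  # Ser Ogamma - His Nepsilon2, Å
    d_his_asp: float  # His Ndelta1 - nearest Asp carboxylate O, Å


@dataclass(frozen=True)
class IonSite:
    """Coordination shell of a monatomic ion."""

    ion_element: str
    ion_serial: int
    coordinating_atoms: tuple[tuple[str, int, str, float], ...]
    water_count: int

    @property
    def coordination_number(self) -> int:
        return len(self.coordinating_atoms) + self.water_count


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform minimizing RMSD between paired coordinate sets."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    atom_count: int


def detect_disulfides(structure: Structure, cutoff: float = 2.3) -> list[DisulfideBond]:
    """Find all CYS SG-SG pairs within ``cutoff`` Å (intra- or inter-chain).

    Each pair is reported once, sorted by (resseq_a, resseq_b) with
    ``resseq_a < resseq_b`` (chain order breaks residue-number ties).
    """
    mask = (structure.resname == "CYS") & (structure.name == "SG")
    idx = np.flatnonzero(mask)
    bonds: list[DisulfideBond] = []
    for i, j in combinations(idx, 2):
        d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        if d > cutoff:
            continue
        a = (str(structure.chain_id[i]), int(structure.resseq[i]))
        b = (str(structure.chain_id[j]), int(structure.resseq[j]))
        if (a[1], a[0]) > (b[1], b[0]):
            a, b = b, a
        bonds.append(
            DisulfideBond(
                chain_id_a=a[0], chain_id_b=b[0],
                resseq_a=a[1], resseq_b=b[1], ss_distance=d,
            )
        )
    bonds.sort(key=lambda x: (x.resseq_a, x.resseq_b, x.chain_id_a, x.chain_id_b))
    return bonds


def detect_catalytic_triad(
    structure: Structure, chain: str, d_max: float = 3.5
) -> CatalyticTriad | None:
    """Find the Ser-His-Asp triad of a chain.

    A triple qualifies when Ser Ogamma-His Nepsilon2 <= ``d_max`` and His
    Ndelta1-nearest Asp carboxylate O <= ``d_max`` (hydrogen-bond distance).
    Among qualifying triples the one minimizing the distance sum is
    returned; ``None`` means no triad was found (not an error).
    """
    if chain not in structure.chains:
        raise ValueError(f"chain {chain!r} not present (chains: {structure.chains})")
    in_chain = structure.chain_id == chain

    def _atoms(resname: str, atom_names: tuple[str, ...]) -> list[tuple[int, np.ndarray]]:
        m = in_chain & (structure.resname == resname) & np.isin(structure.name, list(atom_names))
        return [(int(structure.resseq[i]), structure.coords[i]) for i in np.flatnonzero(m)]

    sers = _atoms("SER", ("OG",))
    his_ne2 = {r: c for r, c in _atoms("HIS", ("NE2",))}
    his_nd1 = {r: c for r, c in _atoms("HIS", ("ND1",))}
    asp_o: dict[int, list[np.ndarray]] = {}
    for r, c in _atoms("ASP", ("OD1", "OD2")):
        asp_o.setdefault(r, []).append(c)

    best: CatalyticTriad | None = None
    for ser_res, og in sers:
        for his_res in set(his_ne2) & set(his_nd1):
            d1 = float(np.linalg.norm(og - his_ne2[his_res]))
            if d1 > d_max:
                continue
            for asp_res, oxygens in asp_o.items():
                d2 = min(float(np.linalg.norm(his_nd1[his_res] - o)) for o in oxygens)
                if d2 > d_max:
                    continue
                cand = CatalyticTriad(chain, ser_res, his_res, asp_res, d1, d2)
                if best is None or cand.d_ser_his + cand.d_his_asp < best.d_ser_his + best.d_his_asp:
                    best = cand
    return best


def ion_coordination(structure: Structure, ion_serial: int, cutoff: float = 3.0) -> IonSite:
    """Coordination shell of the ion with the given serial number.

    Protein/ligand heavy atoms within ``cutoff`` are listed with distances;
    water oxygens are counted.  Other ions and hydrogens are excluded.
    """
    where = np.flatnonzero(structure.serial == ion_serial)
    if len(where) != 1:
        raise ValueError(f"serial {ion_serial} matches {len(where)} atoms, expected 1")
    i = int(where[0])
    if not structure.is_hetero[i] or structure.resname[i] not in ION_RESNAMES:
        raise ValueError(
            f"serial {ion_serial} ({structure.resname[i]} {structure.name[i]}) is not a monatomic ion"
        )
    d = np.linalg.norm(structure.coords - structure.coords[i], axis=1)
    near = (d <= cutoff) & (np.arange(len(structure)) != i) & (structure.element != "H")
    coordinating: list[tuple[str, int, str, float]] = []
    water_count = 0
    for j in np.flatnonzero(near):
        if structure.resname[j] in WATER_RESNAMES:
            if structure.element[j] == "O":
                water_count += 1
        elif structure.resname[j] in ION_RESNAMES and structure.is_hetero[j]:
            continue
        else:
            coordinating.append(
                (str(structure.chain_id[j]), int(structure.resseq[j]), str(structure.name[j]), float(d[j]))
            )
    coordinating.sort(key=lambda t: t[3])
    return IonSite(
        ion_element=str(structure.element[i]),
        ion_serial=ion_serial,
        coordinating_atoms=tuple(coordinating),
        water_count=water_count,
    )


def superpose(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of paired coordinate sets.

    Returns the proper rotation (det +1) and translation mapping ``mobile``
    onto ``fixed`` and the RMSD of the transformed mobile set.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError(f"paired (n, 3) coordinate sets required, got {fixed.shape} vs {mobile.shape}")
    n = fixed.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atom pairs, got {n}")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - cf, mobile - cm)
    rmsd = float(rssd / np.sqrt(n))
    rotation = rot.as_matrix()
    translation = cf - rotation @ cm
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd, atom_count=n)


def _chain_atom_table(structure: Structure, chain: str) -> dict[tuple[int, str], np.ndarray]:
    mask = (
        (structure.chain_id == chain)
        & np.isin(structure.resname, list(STANDARD_AMINO_ACIDS))
        & (structure.element != "H")
    )
    table: dict[tuple[int, str], np.ndarray] = {}
    for i in np.flatnonzero(mask):
        key = (int(structure.resseq[i]), str(structure.name[i]))
        table.setdefault(key, structure.coords[i])
    return table


def pairwise_chain_rmsd(structure: Structure, chains: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """All-against-all superposition RMSD between protein chains.

    For each chain pair, atoms are matched by (resseq, atom name) on the
    intersection of the two chains (heavy protein atoms after altloc
    resolution) and superposed.  Returns (chain ids, symmetric Å matrix).
    """
    if chains is None:
        chains = [
            c for c in structure.chains
            if np.any((structure.chain_id == c) & np.isin(structure.resname, list(STANDARD_AMINO_ACIDS)))
        ]
    if len(chains) < 2:
        raise ValueError(f"need at least 2 protein chains, got {chains}")
    tables = {c: _chain_atom_table(structure, c) for c in chains}
    n = len(chains)
    matrix = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        shared = sorted(set(tables[chains[a]]) & set(tables[chains[b]]))
        if len(shared) < 3:
            raise ValueError(
                f"chains {chains[a]} and {chains[b]} share only {len(shared)} atoms"
            )
        xa = np.array([tables[chains[a]][k] for k in shared])
        xb = np.array([tables[chains[b]][k] for k in shared])
        matrix[a, b] = matrix[b, a] = superpose(xa, xb).rmsd
    return chains, matrix


def structure_report(
    structure: Structure,
    triad_chain: str | None = None,
    disulfide_cutoff: float = 2.3,
    ion_cutoff: float = 3.0,
) -> dict:
    """Full characterization as a JSON-serializable dict: protein chains,
    disulfides, catalytic triad(s), ion coordination shells and the
    pairwise chain-RMSD matrix (when >= 2 protein chains are present)."""
    protein_chains = [
        c for c in structure.chains
        if np.any((structure.chain_id == c) & np.isin(structure.resname, list(STANDARD_AMINO_ACIDS)))
    ]
    report: dict = {"id": structure.id, "protein_chains": protein_chains}
    report["disulfides"] = [
        {
            "chain_a": b.chain_id_a, "chain_b": b.chain_id_b,
            "resseq_a": b.resseq_a, "resseq_b": b.resseq_b,
            "ss_distance": round(b.ss_distance, 3),
        }
        for b in detect_disulfides(structure, cutoff=disulfide_cutoff)
    ]
    triad_chains = [triad_chain] if triad_chain else protein_chains
    report["catalytic_triads"] = {}
    for c in triad_chains:
        t = detect_catalytic_triad(structure, c)
        report["catalytic_triads"][c] = (
            None if t is None else {
                "ser": t.ser_resseq, "his": t.his_resseq, "asp": t.asp_resseq,
                "d_ser_his": round(t.d_ser_his, 3), "d_his_asp": round(t.d_his_asp, 3),
            }
        )
    ion_mask = np.isin(structure.resname, list(ION_RESNAMES)) & structure.is_hetero
    report["ion_sites"] = []
    for i in np.flatnonzero(ion_mask):
        site = ion_coordination(structure, int(structure.serial[i]), cutoff=ion_cutoff)
        report["ion_sites"].append(
            {
                "element": site.ion_element,
                "serial": site.ion_serial,
                "coordinating_atoms": [
                    {"chain": c, "resseq": r, "name": nm, "distance": round(d, 3)}
                    for c, r, nm, d in site.coordinating_atoms
                ],
                "water_count": site.water_count,
                "coordination_number": site.coordination_number,
            }
        )
    if len(protein_chains) >= 2:
        ids, matrix = pairwise_chain_rmsd(structure, protein_chains)
        report["chain_rmsd"] = {"chains": ids, "matrix": [[round(float(v), 3) for v in row] for row in matrix]}
    return report
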