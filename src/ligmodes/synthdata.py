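"""Seeded generators for every fixture the pipeline needs.

Two families of synthetic objects:

* toy *structures* with planted features — disulfide cysteine pairs at the
  ideal 2.05 Å S-S distance, a Ser-His-Asp triad in hydrogen-bond geometry,
  and octahedrally coordinated sodium sites — on a poly-alanine helix
  scaffold;
* toy *complexes* — a pocket of pseudo-residues facing a rigid,
  methyl-ester-capped 4-repeat-unit aromatic ligand (mimicking a PET
  tetramer), with frames sampled from K planted rigid poses under a Markov
  dwell process, Gaussian positional jitter, and per-residue Bernoulli
  contact realization.  The generative mode labels are returned as ground
  truth, so binding-mode recovery and contact-frequency statistics can be
  validated without running molecular dynamics.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, Structure, Trajectory

__all__ = [
    "SyntheticComplexSpec",
    "build_pet_tetramer",
    "make_toy_structure",
    "make_synthetic_trajectory",
    "make_qc_ensemble",
    "make_self_stacking_trajectory",
    "make_synthetic_asymmetric_unit",
]

LIGAND_RESNAME = "PTE"

_HEX_ANGLES = np.deg2rad(np.arange(0, 360, 60))


# ---------------------------------------------------------------------------
# ligand


def build_pet_tetramer(
    resname: str = LIGAND_RESNAME, chain_id: str = "L", resseq: int = 1
) -> Structure:
    """A rigid PET-tetramer analogue: four planar all-carbon hexagons
    (1.39 Å sides, normals along y) joined by carboxyl-ester/glycol linkers
    along x, with methyl-ester end caps (neutral continuation of a longer
    chain).  Heavy atoms only; bond distances respect covalent radii so
    distance-based bond perception recovers exactly four 6-rings.
    """
    atoms: list[tuple[str, str, float, float, float]] = []
    n_c = n_o = 0

    def add(element: str, x: float, y: float, z: float) -> None:
        nonlocal n_c, n_o
        if element == "C":
            n_c += 1
            name = f"C{n_c}"
        else:
            n_o += 1
            name = f"O{n_o}"
        atoms.append((name, element, x, y, z))

    def add_ring(xc: float) -> None:
        for a in _HEX_ANGLES:
            add("C", xc + 1.39 * np.cos(a), 0.0, 1.39 * np.sin(a))

    def add_carboxyl(x7: float) -> None:
        add("C", x7, 0.0, 0.0)       # carboxyl carbon
        add("O", x7, 1.23, 0.0)      # keto oxygen, out of the backbone line

    ring_pitch = 12.80
    centers = [i * ring_pitch for i in range(4)]
    # left methyl-ester cap: CH3-O-C(=O)- attached to ring 1
    add("C", centers[0] - 5.63, 0.0, 0.0)
    add("O", centers[0] - 4.20, 0.0, 0.0)
    add_carboxyl(centers[0] - 2.86)
    for i, xc in enumerate(centers):
        add_ring(xc)
        if i < 3:
            # -C(=O)-O-CH2-CH2-O-C(=O)- glycol linker to the next ring
            add_carboxyl(xc + 2.86)
            add("O", xc + 4.20, 0.0, 0.0)
            add("C", xc + 5.63, 0.0, 0.0)
            add("C", xc + 7.17, 0.0, 0.0)
            add("O", xc + 8.60, 0.0, 0.0)
            add_carboxyl(xc + 9.94)
    # right cap
    add_carboxyl(centers[3] + 2.86)
    add("O", centers[3] + 4.20, 0.0, 0.0)
    add("C", centers[3] + 5.63, 0.0, 0.0)

    records = [
        AtomRecord(
            serial=i + 1, name=name, element=element, resname=resname,
            resseq=resseq, chain_id=chain_id,
            coords=np.array([x, y, z]), is_hetero=True,
        )
        for i, (name, element, x, y, z) in enumerate(atoms)
    ]
    return Structure.from_atoms(records, id="pet-tetramer")


# ---------------------------------------------------------------------------
# toy structures with planted features


_HIS_RING = ("CG", "ND1", "CD2", "CE1", "NE2")


def _helix_backbone(n_residues: int, chain_id: str, resname: str = "ALA") -> list[AtomRecord]:
    """Poly-alanine-like scaffold on an ideal helix (author numbering 1..n)."""
    records: list[AtomRecord] = []
    radius, twist, rise = 10.0, np.deg2rad(40.0), 1.5
    serial = 1
    for i in range(n_residues):
        a = i * twist
        ca = np.array([radius * np.cos(a), radius * np.sin(a), rise * i])
        outward = np.array([np.cos(a), np.sin(a), 0.0])
        offsets = {
            "N": ca - np.array([1.0, 0.0, 0.8]),
            "CA": ca,
            "C": ca + np.array([1.0, 0.0, 0.8]),
            "O": ca + np.array([1.2, 0.4, 1.6]),
            "CB": ca + 1.5 * outward,
        }
        for name, pos in offsets.items():
            records.append(
                AtomRecord(
                    serial=serial, name=name, element=name[0], resname=resname,
                    resseq=i + 1, chain_id=chain_id, coords=pos,
                )
            )
            serial += 1
    return records


def _rebuild_serials(records: list[AtomRecord]) -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=i + 1, name=r.name, element=r.element, resname=r.resname,
            resseq=r.resseq, chain_id=r.chain_id, coords=r.coords,
            occupancy=r.occupancy, altloc=r.altloc, is_hetero=r.is_hetero,
        )
        for i, r in enumerate(records)
    ]


def make_toy_structure(
    n_residues: int = 60,
    with_disulfides: Sequence[tuple[int, int]] = (),
    with_triad: bool | tuple[int, int, int] = False,
    with_ion_sites: Sequence[int | tuple[Sequence[int], int]] = (),
    chain_id: str = "A",
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> Structure:
    """Poly-alanine helix with planted structural features.

    ``with_disulfides`` — residue pairs converted to CYS whose SG atoms sit
    2.05 Å apart.  ``with_triad`` — True plants Ser/His/Asp at residues
    (n//4, n//2, 3n//4) with Ser Og-His Ne2 = 3.0 Å and His Nd1-Asp Od1 =
    2.8 Å; a 3-tuple picks the residue numbers (Ser, His, Asp).
    ``with_ion_sites`` — one Na+ per entry; an int ``c`` gives ``c`` water
    oxygens at 2.4 Å in octahedral directions, a tuple
    ``(carbonyl_resseqs, n_waters)`` repositions those residues' backbone O
    onto the first octahedral positions and fills with waters.
    Gaussian noise (``noise_sigma`` Å) perturbs non-feature scaffold atoms.
    """
    rng = np.random.default_rng(seed)
    records = _helix_backbone(n_residues, chain_id)
    feature_serials: set[int] = set()
    by_key = {(r.resseq, r.name): i for i, r in enumerate(records)}

    def _retype(resseq: int, resname: str) -> None:
        if not 1 <= resseq <= n_residues:
            raise ValueError(f"residue {resseq} outside scaffold range 1..{n_residues}")
        for i, r in enumerate(records):
            if r.resseq == resseq and r.chain_id == chain_id and r.resname != "HOH":
                records[i] = AtomRecord(
                    serial=r.serial, name=r.name, element=r.element, resname=resname,
                    resseq=r.resseq, chain_id=r.chain_id, coords=r.coords,
                )

    used: set[int] = set()
    for a, b in with_disulfides:
        if a in used or b in used or a == b:
            raise ValueError(f"disulfide residues overlap a previous placement: ({a}, {b})")
        used.update((a, b))
        _retype(a, "CYS")
        _retype(b, "CYS")
        mid = 0.5 * (records[by_key[(a, "CA")]].coords + records[by_key[(b, "CA")]].coords)
        anchor = mid + np.array([0.0, 0.0, 0.5])
        for resseq, offset in ((a, np.zeros(3)), (b, np.array([2.05, 0.0, 0.0]))):
            records.append(
                AtomRecord(
                    serial=0, name="SG", element="S", resname="CYS",
                    resseq=resseq, chain_id=chain_id, coords=anchor + offset,
                )
            )

    if with_triad:
        if with_triad is True:
            ser, his, asp = n_residues // 4, n_residues // 2, 3 * n_residues // 4
        else:
            ser, his, asp = with_triad
        if used & {ser, his, asp}:
            raise ValueError("triad residues overlap a previous placement")
        used.update((ser, his, asp))
        _retype(ser, "SER")
        _retype(his, "HIS")
        _retype(asp, "ASP")
        center = np.array([25.0, 25.0, 0.6 * n_residues])
        og = center.copy()
        # imidazole pentagon in the xy-plane with NE2 facing the serine
        ring_center = og + np.array([3.0 + 1.14, 0.0, 0.0])
        pent = {}
        for name, ang in zip(("NE2", "CE1", "ND1", "CD2", "CG"), np.deg2rad([180, 108, 36, -108, -36])):
            pent[name] = ring_center + 1.14 * np.array([np.cos(ang), np.sin(ang), 0.0])
        od1 = pent["ND1"] + 2.8 * np.array([np.cos(np.deg2rad(36)), np.sin(np.deg2rad(36)), 0.0])
        od2 = od1 + np.array([0.0, 0.0, 2.2])
        planted = [("SER", ser, "OG", "O", og)]
        planted += [("HIS", his, nm, nm[0], pos) for nm, pos in pent.items()]
        planted += [("ASP", asp, "OD1", "O", od1), ("ASP", asp, "OD2", "O", od2)]
        for resname, resseq, name, element, pos in planted:
            records.append(
                AtomRecord(
                    serial=0, name=name, element=element, resname=resname,
                    resseq=resseq, chain_id=chain_id, coords=pos,
                )
            )

    octahedral = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    water_resseq = 900
    for k, site in enumerate(with_ion_sites):
        if isinstance(site, int):
            carbonyl_resseqs: list[int] = []
            n_waters = site
        else:
            carbonyl_resseqs = list(site[0])
            n_waters = int(site[1])
        if len(carbonyl_resseqs) + n_waters > 6:
            raise ValueError("octahedral site takes at most 6 ligands")
        # clear of the helix (radius ~11.5 around the z-axis); coordinating
        # carbonyl oxygens are repositioned onto the octahedral vertices
        na_pos = np.array([-30.0, -30.0, 12.0 * (k + 1)])
        positions = na_pos + 2.4 * octahedral
        slot = 0
        for resseq in carbonyl_resseqs:
            i = by_key[(resseq, "O")]
            r = records[i]
            records[i] = AtomRecord(
                serial=r.serial, name=r.name, element=r.element, resname=r.resname,
                resseq=r.resseq, chain_id=r.chain_id, coords=positions[slot],
            )
            slot += 1
        records.append(
            AtomRecord(
                serial=0, name="NA", element="Na", resname="NA", resseq=800 + k,
                chain_id=chain_id, coords=na_pos, is_hetero=True,
            )
        )
        for _ in range(n_waters):
            records.append(
                AtomRecord(
                    serial=0, name="O", element="O", resname="HOH", resseq=water_resseq,
                    chain_id=chain_id, coords=positions[slot], is_hetero=True,
                )
            )
            water_resseq += 1
            slot += 1

    structure = Structure.from_atoms(_rebuild_serials(records), id="toy-structure")
    if noise_sigma > 0:
        plain = (
            (structure.resname == "ALA")
            & ~structure.is_hetero
        )
        structure.coords[plain] += rng.normal(0.0, noise_sigma, size=(int(plain.sum()), 3))
    return structure


# ---------------------------------------------------------------------------
# synthetic complexes with planted binding modes


@dataclass
class SyntheticComplexSpec:
    """Generative conditions of a synthetic protein-ligand trajectory.

    ``contact_sets`` lists, per planted mode, the pocket residues that can
    touch the ligand in that mode (pairwise disjoint windows of 8 residues
    by default, so between-mode fingerprints are disjoint and the planted
    truth is unambiguous).  ``contact_prob`` is the per-frame Bernoulli
    probability that a contact-set residue's side chain actually reaches the
    ligand — 0.95 models 5% fingerprint flip noise.  ``dwell`` is the mean
    number of consecutive frames spent in one mode (Markov chain, uniform
    switch target).  ``jitter_sigma`` is rigid-body Gaussian positional
    noise on the ligand, in Å.
    """

    n_modes: int = 2
    frames: int = 500
    dwell: float = 20.0
    jitter_sigma: float = 0.25
    contact_sets: list[list[int]] | None = None
    contact_prob: float | Sequence[float] = 0.95
    seed: int = 0
    n_pocket_residues: int | None = None
    ohpi_probe: tuple[float, float] | None = None  # (mean distance Å, sigma Å)

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.contact_sets is None:
            # 8 residues per mode: a realistic pocket engages ~8-10 residues
            self.contact_sets = [
                list(range(8 * m + 1, 8 * m + 9)) for m in range(self.n_modes)
            ]
        if len(self.contact_sets) != self.n_modes:
            raise ValueError("need one contact set per mode")
        if self.n_pocket_residues is None:
            self.n_pocket_residues = max(max(max(s) for s in self.contact_sets), 8)
        for s in self.contact_sets:
            if min(s) < 1 or max(s) > self.n_pocket_residues:
                raise ValueError("contact set outside the pocket residue range")
        for row in self.contact_probabilities():
            if np.any(row <= 0) or np.any(row > 1):
                raise ValueError("contact_prob must lie in (0, 1]")

    def contact_probabilities(self) -> list[np.ndarray]:
        """Per-mode, per-residue Bernoulli probabilities."""
        if np.isscalar(self.contact_prob):
            return [
                np.full(len(s), float(self.contact_prob)) for s in self.contact_sets
            ]
        p = [float(v) for v in self.contact_prob]
        return [
            np.array([p[i % len(p)] for i in range(len(s))]) for s in self.contact_sets
        ]


def _pocket_topology(spec: SyntheticComplexSpec) -> tuple[Structure, dict]:
    """Pocket pseudo-residues on a line at y=8 facing the ligand at y=0."""
    records: list[AtomRecord] = []
    meta: dict = {}
    for i in range(spec.n_pocket_residues):
        x = -4.0 + 4.0 * i
        ca = np.array([x, 8.0, 0.0])
        for name, off in (
            ("N", np.array([-1.0, 0.8, 0.0])),
            ("CA", np.zeros(3)),
            ("C", np.array([1.0, 0.8, 0.0])),
            ("O", np.array([1.2, 1.8, 0.0])),
            ("CB", np.array([0.0, -1.0, 0.0])),
        ):
            records.append(
                AtomRecord(
                    serial=0, name=name, element=name[0], resname="ALA",
                    resseq=i + 1, chain_id="A", coords=ca + off,
                )
            )
    probe_resseq = None
    if spec.ohpi_probe is not None:
        probe_resseq = spec.n_pocket_residues + 1
        base = np.array([25.6, 14.0, 0.0])
        for name, off in (
            ("N", np.array([-1.0, 0.8, 0.0])),
            ("CA", np.zeros(3)),
            ("C", np.array([1.0, 0.8, 0.0])),
            ("O", np.array([1.2, 1.8, 0.0])),
            ("CB", np.array([0.0, -1.0, 0.0])),
            ("OG", np.array([0.0, -2.4, 0.0])),
        ):
            records.append(
                AtomRecord(
                    serial=0, name=name, element=name[0], resname="SER",
                    resseq=probe_resseq, chain_id="A", coords=base + off,
                )
            )
    ligand = build_pet_tetramer()
    records.extend(
        AtomRecord(
            serial=0, name=a.name, element=a.element, resname=a.resname,
            resseq=a.resseq, chain_id=a.chain_id, coords=a.coords, is_hetero=True,
        )
        for a in ligand
    )
    topo = Structure.from_atoms(_rebuild_serials(records), id="synthetic-complex")
    n_prot = len(records) - len(ligand)
    meta["ligand_slice"] = slice(n_prot, len(records))
    meta["probe_resseq"] = probe_resseq
    meta["cb_index"] = {
        int(topo.resseq[i]): int(i)
        for i in np.flatnonzero((topo.name == "CB") & (topo.resname == "ALA"))
    }
    meta["ca_x"] = {
        int(topo.resseq[i]): float(topo.coords[i, 0])
        for i in np.flatnonzero((topo.name == "CA") & ~topo.is_hetero)
    }
    if probe_resseq is not None:
        meta["og_index"] = int(
            np.flatnonzero((topo.name == "OG") & (topo.resseq == probe_resseq))[0]
        )
    lig_c = np.flatnonzero(
        (topo.element == "C") & (topo.resname == LIGAND_RESNAME)
    )
    meta["ligand_carbons"] = lig_c
    # ring-2 member indices (global), for the OH-pi probe
    ring2_x = 12.8
    lig_idx = np.arange(meta["ligand_slice"].start, meta["ligand_slice"].stop)
    ring_members = [
        int(i) for i in lig_idx
        if topo.element[i] == "C"
        and abs(np.linalg.norm(topo.coords[i] - [ring2_x, 0, 0]) - 1.39) < 1e-6
    ]
    meta["ring2_indices"] = tuple(ring_members)
    return topo, meta


def _mode_sequence(rng: np.random.Generator, n_modes: int, frames: int, dwell: float) -> np.ndarray:
    labels = np.empty(frames, dtype=int)
    state = int(rng.integers(n_modes))
    p_stay = 0.0 if dwell <= 1 else 1.0 - 1.0 / dwell
    for f in range(frames):
        labels[f] = state
        if n_modes > 1 and rng.random() >= p_stay:
            others = [m for m in range(n_modes) if m != state]
            state = others[int(rng.integers(len(others)))]
    return labels


def make_synthetic_trajectory(
    spec: SyntheticComplexSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Generate a trajectory with planted binding modes; returns
    ``(trajectory, per-frame ground-truth mode labels)``.

    Pose *m* centres the rigid ligand under its contact window; in every
    frame each contact-set residue of the active mode reaches the ligand
    (side-chain carbon at 3.8 Å below the nearest ligand carbon) with its
    Bernoulli probability, and retracts to 7 Å otherwise.  With the default
    disjoint contact sets the between-mode fingerprint Tanimoto is ~0.
    """
    rng = np.random.default_rng(spec.seed)
    topo, meta = _pocket_topology(spec)
    lig = meta["ligand_slice"]
    lig_coords0 = topo.coords[lig].copy()
    lig_center = lig_coords0.mean(axis=0)
    shifts = []
    for s in spec.contact_sets:
        window_x = np.mean([meta["ca_x"][r] for r in s])
        shifts.append(np.array([window_x - lig_center[0], 0.0, 0.0]))
    probs = spec.contact_probabilities()

    labels = _mode_sequence(rng, spec.n_modes, spec.frames, spec.dwell)
    coords = np.tile(topo.coords[None, :, :], (spec.frames, 1, 1))
    lig_carbons_local = meta["ligand_carbons"] - lig.start
    for f in range(spec.frames):
        m = int(labels[f])
        t_jit = rng.normal(0.0, spec.jitter_sigma, size=3)
        rot = Rotation.from_rotvec(rng.normal(0.0, 0.01, size=3))
        posed = rot.apply(lig_coords0 - lig_center) + lig_center + shifts[m] + t_jit
        coords[f, lig] = posed
        lig_c = posed[lig_carbons_local]
        for r, p in zip(spec.contact_sets[m], probs[m]):
            cb = meta["cb_index"][r]
            if rng.random() < p:
                ca_x = meta["ca_x"][r]
                nearest = lig_c[np.argmin(np.abs(lig_c[:, 0] - ca_x))]
                coords[f, cb] = nearest + np.array([0.0, 3.8, 0.0])
            # else: CB stays at its retracted topology position (y=7)
        if meta["probe_resseq"] is not None:
            mean_d, sigma_d = spec.ohpi_probe
            from .fingerprints import ring_geometry  # local import avoids a cycle

            centroid, normal, _ = ring_geometry(coords[f], meta["ring2_indices"])
            if normal[1] < 0:
                normal = -normal
            d = rng.normal(mean_d, sigma_d)
            coords[f, meta["og_index"]] = centroid + d * normal
    traj = Trajectory(topology=topo, coords=coords, id=f"synthetic-seed{spec.seed}")
    return traj, labels


def make_qc_ensemble(
    n_runs: int = 20,
    n_bound: int = 8,
    frames: int = 100,
    seed: int = 0,
    unbind_displacement: float = 25.0,
) -> tuple[list[Trajectory], list[bool]]:
    """An ensemble of short runs of which exactly ``n_bound`` stay bound
    throughout; the rest unbind (ligand displaced ``unbind_displacement`` Å
    away from the pocket) at a random frame.  Returns the runs and the
    planted admitted-truth flags, in a seeded random order."""
    rng = np.random.default_rng(seed)
    runs: list[Trajectory] = []
    truth: list[bool] = []
    order = rng.permutation(n_runs)
    bound_flags = np.zeros(n_runs, dtype=bool)
    bound_flags[order[:n_bound]] = True
    for k in range(n_runs):
        spec = SyntheticComplexSpec(
            n_modes=1, frames=frames, seed=int(rng.integers(2**31 - 1))
        )
        traj, _ = make_synthetic_trajectory(spec)
        if not bound_flags[k]:
            lig = np.isin(traj.topology.resname, [LIGAND_RESNAME])
            escape_frame = int(rng.integers(frames // 4, frames))
            traj.coords[escape_frame:, lig] += np.array([0.0, -unbind_displacement, 0.0])
        traj.id = f"run{k:02d}"
        runs.append(traj)
        truth.append(bool(bound_flags[k]))
    return runs, truth


def make_self_stacking_trajectory(
    n_contact_residues: int = 1, seed: int = 0
) -> Trajectory:
    """A single-frame hairpin conformation: ligand repeat units 3-4 folded
    back so ring 3 lies parallel 3.8 Å above ring 1, while exactly
    ``n_contact_residues`` pocket residues touch the ligand."""
    spec = SyntheticComplexSpec(
        n_modes=1,
        frames=1,
        jitter_sigma=0.0,
        contact_prob=1.0,
        seed=seed,
        contact_sets=[list(range(1, max(n_contact_residues, 1) + 1))],
    )
    traj, _ = make_synthetic_trajectory(spec)
    topo = traj.topology
    coords = traj.coords[0].copy()
    lig_idx = np.flatnonzero(topo.resname == LIGAND_RESNAME)
    base = build_pet_tetramer()
    pose_shift = coords[lig_idx[0]] - base.coords[0]
    # fold everything beyond the midpoint of linker 2-3 back over ring 1
    fold_mask = base.coords[:, 0] >= 19.2
    ring3_center_local = np.array([25.6, 0.0, 0.0])
    rot = Rotation.from_euler("z", 180, degrees=True)
    folded = base.coords.copy()
    folded[fold_mask] = (
        rot.apply(base.coords[fold_mask] - ring3_center_local)
        + np.array([0.0, 3.8, 0.0])  # ring 3 lands over ring 1
    )
    coords[lig_idx] = folded + pose_shift
    # re-anchor the contact side chains onto the folded ligand
    cb_all = np.flatnonzero((topo.name == "CB") & (topo.resname == "ALA"))
    coords[cb_all] = topo.coords[cb_all]
    lig_c = coords[lig_idx][base.element == "C"]
    for resseq in range(1, n_contact_residues + 1):
        cb = int(cb_all[resseq - 1])
        nearest = lig_c[np.argmin(np.linalg.norm(lig_c - topo.coords[cb], axis=1))]
        coords[cb] = nearest + np.array([0.0, 3.8, 0.0])
    return Trajectory(topology=topo, coords=coords[None, :, :], id="hairpin")


# ---------------------------------------------------------------------------
# synthetic crystal stand-in


def make_synthetic_asymmetric_unit(seed: int = 0, n_residues: int = 300) -> Structure:
    """SYNTHETIC stand-in for a halophilic PET-hydrolase crystal asymmetric
    unit: three copies of a poly-alanine chain with planted disulfides at
    residue pairs (27,30), (206,243), (277,294), a Ser163/His241/Asp209
    triad, and two octahedral Na+ sites (carbonyl O of residues 61/63/65 and
    282/284/287, three waters each).  The chains differ by rigid motions
    plus per-atom Gaussian noise calibrated so pairwise all-atom RMSD lands
    near 0.65 Å.  This object is generated, not experimental data.
    """
    rng = np.random.default_rng(seed)
    base = make_toy_structure(
        n_residues=n_residues,
        with_disulfides=[(27, 30), (206, 243), (277, 294)],
        with_triad=(163, 241, 209),
        with_ion_sites=[([61, 63, 65], 3), ([282, 284, 287], 3)],
        chain_id="A",
        seed=seed,
        noise_sigma=0.0,
    )
    sigma = 0.65 / np.sqrt(6.0)
    transforms = {
        "A": (Rotation.identity(), np.zeros(3)),
        "B": (Rotation.from_euler("z", 97, degrees=True), np.array([70.0, 0.0, 0.0])),
        "C": (Rotation.from_euler("x", -145, degrees=True), np.array([0.0, 70.0, -20.0])),
    }
    # feature atoms stay exact so planted geometries survive the noise
    feature = (
        (base.name == "SG")
        | np.isin(base.resname, ["SER", "HIS", "ASP", "HOH", "NA"])
        | np.isin(base.resseq, [61, 63, 65, 282, 284, 287]) & (base.name == "O")
    )
    records: list[AtomRecord] = []
    for chain, (rot, shift) in transforms.items():
        noise = rng.normal(0.0, sigma, size=base.coords.shape)
        noise[feature] = 0.0
        moved = rot.apply(base.coords + noise) + shift
        for i in range(len(base)):
            a = base.atom(i)
            records.append(
                AtomRecord(
                    serial=0, name=a.name, element=a.element, resname=a.resname,
                    resseq=a.resseq, chain_id=chain, coords=moved[i],
                    is_hetero=a.is_hetero,
                )
            )
    out = Structure.from_atoms(_rebuild_serials(records), id="synthetic-asymmetric-unit")
    return out
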