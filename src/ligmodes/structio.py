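"""Structure and trajectory I/O plus atom selection.

This module is the data backbone of the package: a light, array-backed
:class:`Structure` (one model of a PDB file), a :class:`Trajectory`
(constant topology + a stack of coordinate frames, in Å) and a small
selection mini-language (``protein``, ``ligand``, ``chain A``,
``resid 10-20`` ... combinable with ``and``/``or``/``not``).

PDB parsing and writing are delegated to :mod:`biotite`; multi-model PDB
files are the canonical trajectory fixture format.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
    "STANDARD_AMINO_ACIDS",
    "WATER_RESNAMES",
    "ION_RESNAMES",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_RESNAMES = frozenset({"HOH", "WAT"})
# Monatomic ions commonly modelled in crystal structures; PET6 binds Na+/Cl-.
ION_RESNAMES = frozenset(
    "NA CL K MG CA ZN MN FE CU NI CD CO BR CS LI SR RB IOD".split()
)

_TWO_LETTER_ELEMENTS = frozenset(
    "NA CL MG CA ZN MN FE CU NI CD CO BR CS LI SR RB SE".split()
)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised for malformed or unknown selection expressions."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of a structure (author numbering, coordinates in Å)."""

    serial: int
    name: str
    element: str
    resname: str
    resseq: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False


@dataclass
class Structure:
    """One structural model as parallel per-atom arrays.

    All coordinates are in Å.  ``resseq`` is the author residue number,
    matching residue labels like Ser163 used throughout the field.
    """

    id: str = ""
    serial: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    name: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U6"))
    element: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U2"))
    resname: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U5"))
    resseq: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    chain_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U4"))
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=float))
    occupancy: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    altloc: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))
    is_hetero: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __len__(self) -> int:
        return len(self.serial)

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self.atom(i)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            resname=str(self.resname[i]),
            resseq=int(self.resseq[i]),
            chain_id=str(self.chain_id[i]),
            coords=self.coords[i].copy(),
            occupancy=float(self.occupancy[i]),
            altloc=str(self.altloc[i]),
            is_hetero=bool(self.is_hetero[i]),
        )

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            id=self.id,
            serial=self.serial[idx].copy(),
            name=self.name[idx].copy(),
            element=self.element[idx].copy(),
            resname=self.resname[idx].copy(),
            resseq=self.resseq[idx].copy(),
            chain_id=self.chain_id[idx].copy(),
            coords=self.coords[idx].copy(),
            occupancy=self.occupancy[idx].copy(),
            altloc=self.altloc[idx].copy(),
            is_hetero=self.is_hetero[idx].copy(),
        )

    def select(self, expression: str, ligand_resnames: Iterable[str] = ()) -> np.ndarray:
        """Evaluate a selection expression; returns sorted atom indices."""
        return select_atoms(self, expression, ligand_resnames)

    @staticmethod
    def from_atoms(atoms: Sequence[AtomRecord], id: str = "") -> "Structure":
        n = len(atoms)
        s = Structure(
            id=id,
            serial=np.array([a.serial for a in atoms], dtype=int),
            name=np.array([a.name for a in atoms], dtype="U6"),
            element=np.array([a.element for a in atoms], dtype="U2"),
            resname=np.array([a.resname for a in atoms], dtype="U5"),
            resseq=np.array([a.resseq for a in atoms], dtype=int),
            chain_id=np.array([a.chain_id for a in atoms], dtype="U4"),
            coords=np.array([a.coords for a in atoms], dtype=float).reshape(n, 3),
            occupancy=np.array([a.occupancy for a in atoms], dtype=float),
            altloc=np.array([a.altloc for a in atoms], dtype="U1"),
            is_hetero=np.array([a.is_hetero for a in atoms], dtype=bool),
        )
        return s


@dataclass
class Trajectory:
    """Constant-topology frame stack; ``coords`` has shape (frames, atoms, 3) in Å."""

    topology: Structure
    coords: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def frame_structure(self, i: int) -> Structure:
        s = self.topology.subset(np.arange(len(self.topology)))
        s.coords = self.coords[i].copy()
        return s


def _infer_element(atom_name: str, resname: str, is_hetero: bool) -> str:
    """Infer the element symbol from the PDB atom-name columns."""
    name = atom_name.strip()
    if not name:
        return ""
    stripped = re.sub(r"[0-9']", "", name)
    if is_hetero and stripped.upper() in _TWO_LETTER_ELEMENTS and resname.strip().upper() in ION_RESNAMES:
        return stripped.upper().capitalize()
    if not stripped:
        # names like "1HB" reduce to H after digit stripping handled above;
        # an all-digit name carries no element information
        return ""
    first = stripped[0].upper()
    if first == "H" or name[0].isdigit():
        return "H"
    return first


def _structure_from_atom_array(array: bst.AtomArray, label: str) -> Structure:
    n = array.array_length()
    occupancy = (
        np.asarray(array.occupancy, dtype=float)
        if "occupancy" in array.get_annotation_categories()
        else np.ones(n)
    )
    serial = (
        np.asarray(array.atom_id, dtype=int)
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    altloc = (
        np.asarray(array.altloc_id, dtype="U1")
        if "altloc_id" in array.get_annotation_categories()
        else np.full(n, "", dtype="U1")
    )
    altloc = np.where(np.isin(altloc, [".", " ", "?"]), "", altloc)
    element = np.asarray(array.element, dtype="U2")
    resname = np.asarray(array.res_name, dtype="U5")
    name = np.asarray(array.atom_name, dtype="U6")
    hetero = np.asarray(array.hetero, dtype=bool)
    for i in range(n):
        if not element[i].strip():
            element[i] = _infer_element(str(name[i]), str(resname[i]), bool(hetero[i]))
    s = Structure(
        id=label,
        serial=serial,
        name=name,
        element=element,
        resname=resname,
        resseq=np.asarray(array.res_id, dtype=int),
        chain_id=np.asarray(array.chain_id, dtype="U4"),
        coords=np.asarray(array.coord, dtype=float).copy(),
        occupancy=occupancy,
        altloc=altloc,
        is_hetero=hetero,
    )
    if not np.all(np.isfinite(s.coords)):
        raise PDBParseError(f"{label}: non-finite coordinates in file")
    return s


def _find_bad_coordinate_line(text: str) -> int | None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    return lineno
    return None


def _load_pdb_file(path: str | Path) -> tuple[bpdb.PDBFile, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise PDBParseError(f"{path}: no ATOM/HETATM records (empty or non-PDB file)")
    bad = _find_bad_coordinate_line(text)
    if bad is not None:
        raise PDBParseError(f"{path}: malformed coordinate field on line {bad}")
    return bpdb.PDBFile.read(io.StringIO(text)), text


_ALTLOC_POLICIES = {"highest_occupancy": "occupancy", "first": "first"}


def read_structure(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Read model 1 of a PDB file.

    Waters and ions are retained (``is_hetero`` set); alternate locations
    are resolved per ``altloc_policy`` (``highest_occupancy`` — ties broken
    by altloc letter order, the file convention — or ``first``).
    """
    if altloc_policy not in _ALTLOC_POLICIES:
        raise ValueError(
            f"unknown altloc policy {altloc_policy!r}; choose from {sorted(_ALTLOC_POLICIES)}"
        )
    pdb_file, _ = _load_pdb_file(path)
    array = pdb_file.get_structure(
        model=1,
        altloc=_ALTLOC_POLICIES[altloc_policy],
        extra_fields=["occupancy", "atom_id"],
    )
    return _structure_from_atom_array(array, label=Path(path).stem)


def read_trajectory(path: str | Path, topology: Structure | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    The topology is taken from the first model unless supplied.  Models with
    an atom count different from model 1 raise an error naming the model.
    """
    pdb_file, _ = _load_pdb_file(path)
    n_models = pdb_file.get_model_count()
    first = pdb_file.get_structure(model=1, altloc="first", extra_fields=["occupancy", "atom_id"])
    n_atoms = first.array_length()
    frames = np.empty((n_models, n_atoms, 3), dtype=float)
    frames[0] = np.asarray(first.coord, dtype=float)
    for m in range(2, n_models + 1):
        arr = pdb_file.get_structure(model=m, altloc="first")
        if arr.array_length() != n_atoms:
            raise PDBParseError(
                f"{path}: model {m} has {arr.array_length()} atoms, "
                f"expected {n_atoms} (model 1)"
            )
        frames[m - 1] = np.asarray(arr.coord, dtype=float)
    top = topology if topology is not None else _structure_from_atom_array(first, Path(path).stem)
    if len(top) != n_atoms:
        raise ValueError(
            f"supplied topology has {len(top)} atoms but file frames have {n_atoms}"
        )
    return Trajectory(topology=top, coords=frames, id=Path(path).stem)


def _to_atom_array(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    array = bst.AtomArray(n)
    array.coord = np.asarray(structure.coords, dtype=np.float32)
    array.chain_id = structure.chain_id.astype("U4")
    array.res_id = structure.resseq.astype(int)
    array.res_name = structure.resname.astype("U5")
    array.atom_name = structure.name.astype("U6")
    array.element = structure.element.astype("U2")
    array.hetero = structure.is_hetero.astype(bool)
    array.set_annotation("occupancy", structure.occupancy.astype(float))
    array.set_annotation("atom_id", structure.serial.astype(int))
    array.set_annotation("b_factor", np.zeros(n))
    return array


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    template = _to_atom_array(traj.topology)
    stack = bst.stack([template] * traj.frame_count)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# --------------------------------------------------------------------------
# Selection mini-language
#
# expr      := term ("or" term)*
# term      := factor ("and" factor)*
# factor    := "not" factor | "(" expr ")" | primitive
# primitive := protein | water | ion | ligand
#            | chain <id> | resid <a>[-<b>] | resname <n> | name <n>

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _SelParser:
    def __init__(self, structure: Structure, expression: str, ligand_resnames: frozenset[str]):
        self.s = structure
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.ligand_resnames = ligand_resnames

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expr!r}")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._expr()
        if self._peek() is not None:
            tok, at = self._peek()
            raise SelectionError(f"unexpected token {tok!r} at position {at}")
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while (tok := self._peek()) is not None and tok[0].lower() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while (tok := self._peek()) is not None and tok[0].lower() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, at = self._next()
        word = tok.lower()
        if word == "not":
            return ~self._factor()
        if tok == "(":
            mask = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                raise SelectionError(f"unbalanced parenthesis opened at position {at}")
            self._next()
            return mask
        return self._primitive(word, at)

    def _value(self, keyword: str) -> str:
        tok = self._peek()
        if tok is None or tok[0] in {"(", ")"} or tok[0].lower() in {"and", "or", "not"}:
            raise SelectionError(f"keyword {keyword!r} requires a value")
        return self._next()[0]

    def _primitive(self, word: str, at: int) -> np.ndarray:
        s = self.s
        if word == "protein":
            return np.isin(s.resname, list(STANDARD_AMINO_ACIDS))
        if word == "water":
            return np.isin(s.resname, list(WATER_RESNAMES))
        if word == "ion":
            return np.isin(s.resname, list(ION_RESNAMES)) & s.is_hetero
        if word == "ligand":
            if not self.ligand_resnames:
                return np.zeros(len(s), dtype=bool)
            return np.isin(s.resname, list(self.ligand_resnames))
        if word == "chain":
            return s.chain_id == self._value("chain")
        if word == "resname":
            return s.resname == self._value("resname").upper()
        if word == "name":
            return s.name == self._value("name").upper()
        if word == "resid":
            value = self._value("resid")
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value)
            if m is None:
                raise SelectionError(f"bad resid range {value!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            return (s.resseq >= lo) & (s.resseq <= hi)
        raise SelectionError(f"unknown selection keyword {word!r} at position {at}")


def select_atoms(
    structure: Structure,
    expression: str,
    ligand_resnames: Iterable[str] = (),
) -> np.ndarray:
    """Evaluate the selection mini-language; returns a sorted, duplicate-free
    array of atom indices (possibly empty — an empty result is not an error)."""
    parser = _SelParser(structure, expression, frozenset(r.upper() for r in ligand_resnames))
    mask = parser.parse()
    return np.flatnonzero(mask)
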