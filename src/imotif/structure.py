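"""Structure data model and PDB I/O.

A lightweight atom/residue/structure/ensemble hierarchy tailored to
protonation-state-aware electrostatics: every atom carries a partial charge,
every cytosine a ``protonated`` flag (N3-protonated C+ vs neutral C).
PDB text parsing/writing is delegated to biotite behind this surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "StructureError",
    "ParseError",
    "EnsembleError",
    "MissingParameterError",
    "parse_structure",
    "write_structure",
    "assign_charges",
    "load_charge_set",
    "default_charge_set",
]

# Base heavy atoms and base hydrogens per residue type; everything else
# (sugar + phosphate) is backbone for the purposes of ``is_base_atom``.
_BASE_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4",
          "H8", "H61", "H62", "H2"},
    "G": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
          "H8", "H1", "H21", "H22"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6",
          "H41", "H42", "H5", "H6", "H3"},
    "T": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6",
          "H3", "H6", "H71", "H72", "H73"},
}

_RES_NAME_TO_BASE = {
    "DA": "A", "DG": "G", "DC": "C", "DT": "T",
    "A": "A", "G": "G", "C": "C", "T": "T",
    "ADE": "A", "GUA": "G", "CYT": "C", "THY": "T",
    "DCP": "C",  # protonated cytosine
}


class StructureError(ValueError):
    """Base class for structure-model errors."""


class ParseError(StructureError):
    """Malformed PDB input."""


class EnsembleError(StructureError):
    """Inconsistent models within an ensemble."""


class MissingParameterError(KeyError):
    """Charge set lacks a parameter for an atom present in the structure."""


def _element_from_name(name: str) -> str:
    name = name.strip()
    if not name:
        return ""
    # PDB convention: leading digits belong to hydrogen naming (e.g. 1H5')
    stripped = name.lstrip("0123456789")
    if stripped[:1] in ("H", "D"):
        return "H"
    if stripped[:1] == "P":
        return "P"
    return stripped[:1]


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    is_base_atom: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if abs(self.charge) > 2:
            raise StructureError(f"atom {self.name}: |charge| > 2 e")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.charge, self.is_base_atom)


@dataclass
class Residue:
    index: int
    base: str
    chain: str
    atoms: list = field(default_factory=list)
    protonated: bool = False

    def __post_init__(self):
        if self.base not in "ACGT":
            raise StructureError(f"unknown base {self.base!r}")
        if self.protonated and self.base != "C":
            raise StructureError("protonated flag is only meaningful for cytosine")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def copy(self) -> "Residue":
        return Residue(self.index, self.base, self.chain,
                       [a.copy() for a in self.atoms], self.protonated)


@dataclass
class Structure:
    residues: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        by_chain: dict[str, int] = {}
        for r in self.residues:
            prev = by_chain.get(r.chain)
            if prev is not None and r.index <= prev:
                raise StructureError(
                    f"residue indices not strictly increasing in chain {r.chain!r}")
            by_chain[r.chain] = r.index

    def __iter__(self):
        return iter(self.residues)

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def residue(self, index: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.index == index and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"residue {index} not in structure")

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        i = 0
        for a in self.atoms():
            a.coords = xyz[i].copy()
            i += 1
        if i != len(xyz):
            raise StructureError("coordinate array length mismatch")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def total_charge(self) -> float:
        return float(sum(r.total_charge() for r in self.residues))

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.label)

    def subset(self, keep) -> "Structure":
        """New structure with residues for which ``keep(residue)`` is true."""
        return Structure([r.copy() for r in self.residues if keep(r)], self.label)


@dataclass
class Ensemble:
    models: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        if not self.models:
            return
        ref = [(a.name, r.index, r.chain)
               for r in self.models[0].residues for a in r.atoms]
        for k, m in enumerate(self.models[1:], start=2):
            cur = [(a.name, r.index, r.chain) for r in m.residues for a in r.atoms]
            if cur != ref:
                raise EnsembleError(
                    f"model {k} differs from model 1 in atom composition/order")

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _validate_atom_lines(pdb_text: str) -> None:
    n_atom = 0
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            n_atom += 1
            if len(line) < 54:
                raise ParseError(f"line {ln}: ATOM record shorter than 54 columns")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(f"line {ln}: malformed coordinate field") from None
    if n_atom == 0:
        raise ParseError("no ATOM/HETATM records found")


def parse_structure(pdb_text: str, label: str = "") -> Ensemble:
    """Parse PDB-format text into an :class:`Ensemble` (one model per MODEL block).

    The first alternate location is kept; residues whose name is not a standard
    DNA nucleotide are skipped.
    """
    _validate_atom_lines(pdb_text)
    pdb = bst_pdb.PDBFile.read(io.StringIO(pdb_text))
    try:
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        raise EnsembleError(f"inconsistent models: {exc}") from exc
    models = []
    for i in range(stack.stack_depth()):
        arr = stack[i]
        models.append(_from_atom_array(arr, label=f"{label}#{i + 1}" if label else ""))
    ens = Ensemble(models, label=label)
    return ens


def _from_atom_array(arr, label: str = "") -> Structure:
    residues = []
    current_key = None
    cur = None
    protonated_names = {"DCP"}
    for i in range(arr.array_length()):
        res_name = arr.res_name[i].strip()
        base = _RES_NAME_TO_BASE.get(res_name)
        if base is None:
            continue
        key = (arr.chain_id[i], int(arr.res_id[i]))
        if key != current_key:
            cur = Residue(index=int(arr.res_id[i]), base=base,
                          chain=str(arr.chain_id[i]),
                          protonated=res_name in protonated_names)
            residues.append(cur)
            current_key = key
        name = arr.atom_name[i].strip()
        cur.atoms.append(Atom(
            name=name,
            element=str(arr.element[i]).strip() or _element_from_name(name),
            coords=np.array(arr.coord[i], dtype=float),
            is_base_atom=name in _BASE_ATOMS[base],
        ))
    # mark cytosines carrying an H3 atom as protonated
    for r in residues:
        if r.base == "C" and r.atom("H3") is not None:
            r.protonated = True
    return Structure(residues, label=label)


def _to_atom_array(structure: Structure):
    n = structure.n_atoms()
    arr = bst.AtomArray(n)
    i = 0
    for r in structure.residues:
        res_name = "D" + r.base
        for a in r.atoms:
            arr.coord[i] = a.coords
            arr.chain_id[i] = r.chain
            arr.res_id[i] = r.index
            arr.res_name[i] = res_name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element or _element_from_name(a.name)
            arr.hetero[i] = False
            i += 1
    return arr


def write_structure(ensemble: Ensemble | Structure) -> str:
    """Serialize a structure or ensemble as PDB text (MODEL blocks for >1 model)."""
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble], label=ensemble.label)
    if not ensemble.models:
        raise StructureError("cannot write an empty ensemble")
    arrays = [_to_atom_array(m) for m in ensemble.models]
    if len(arrays) == 1:
        obj = arrays[0]
    else:
        obj = bst.stack(arrays)
    pdb = bst_pdb.PDBFile()
    pdb.set_structure(obj)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Partial charges
# ---------------------------------------------------------------------------

def load_charge_set(text: str) -> dict:
    """Parse a plain-text charge table.

    Format: ``[RESKEY]`` section headers (DA/DC/DCP/DG/DT) followed by
    ``atom_name charge`` lines; ``#`` starts a comment.
    """
    table: dict[str, dict[str, float]] = {}
    section = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            table[section] = {}
            continue
        parts = line.split()
        if section is None or len(parts) != 2:
            raise ParseError(f"charge table line {ln}: expected 'atom charge'")
        table[section][parts[0]] = float(parts[1])
    return table


def default_charge_set() -> dict:
    """The embedded AMBER-style DNA charge table (see data/charges.txt)."""
    from importlib.resources import files
    text = files("imotif").joinpath("data/charges.txt").read_text()
    return load_charge_set(text)


def _residue_key(residue: Residue) -> str:
    if residue.base == "C" and residue.protonated:
        return "DCP"
    return "D" + residue.base


def assign_charges(structure: Structure, charge_set: dict | None = None) -> Structure:
    """Return a copy of ``structure`` with per-atom partial charges assigned.

    Protonated cytosines use the C+ entry (including the N3-bound proton);
    if the structure lacks the H3 atom, its charge is folded onto N3
    (united-proton fallback).
    """
    if charge_set is None:
        charge_set = default_charge_set()
    out = structure.copy()
    for r in out.residues:
        key = _residue_key(r)
        try:
            entry = charge_set[key]
        except KeyError:
            raise MissingParameterError(
                f"charge set has no entry for residue type {key}") from None
        names = {a.name for a in r.atoms}
        for a in r.atoms:
            if a.name not in entry:
                raise MissingParameterError(
                    f"no charge for atom {a.name!r} in residue "
                    f"{key} {r.chain}{r.index}")
            a.charge = entry[a.name]
        if key == "DCP" and "H3" not in names:
            n3 = r.atom("N3")
            if n3 is None:
                raise MissingParameterError(
                    f"protonated cytosine {r.chain}{r.index} lacks both H3 and N3")
            n3.charge += entry.get("H3", 0.0)
    return out
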