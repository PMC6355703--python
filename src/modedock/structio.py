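"""Structure I/O and residue selections.

A :class:`Structure` is a flat, array-backed collection of atom records with
a derived chain -> residue -> atom hierarchy, the in-memory container used by
every downstream stage (normal modes, SASA, docking, fingerprints). PDB
reading/writing is delegated to biotite; element masses and van der Waals
radii come from the bundled element table.

Residues are addressed by ``(chain_id, residue_number, insertion_code)``
keys throughout, preserving author numbering of the source file.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _chem
from ._geometry import kabsch

__all__ = [
    "AtomRecord",
    "Structure",
    "Selection",
    "BindingSite",
    "read_pdb",
    "read_models",
    "write_pdb",
    "select",
    "define_binding_site",
    "superpose_structures",
    "PDBFormatError",
]


class PDBFormatError(ValueError):
    """Raised for unparseable PDB content."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and physical parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    mass: float
    vdw_radius: float
    partial_charge: Optional[float] = None
    formal_charge: int = 0
    hetero: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.mass <= 0 or self.vdw_radius <= 0:
            raise ValueError("mass and vdW radius must be positive")

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self):
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


class Structure:
    """Array-backed atom collection with a residue/chain hierarchy."""

    def __init__(
        self,
        coords: np.ndarray,
        names: Sequence[str],
        elements: Sequence[str],
        res_names: Sequence[str],
        res_numbers: Sequence[int],
        chain_ids: Sequence[str],
        insertion_codes: Optional[Sequence[str]] = None,
        serials: Optional[Sequence[int]] = None,
        hetero: Optional[Sequence[bool]] = None,
        masses: Optional[np.ndarray] = None,
        vdw_radii: Optional[np.ndarray] = None,
        partial_charges: Optional[np.ndarray] = None,
        formal_charges: Optional[Sequence[int]] = None,
        metadata: str = "",
    ):
        n = len(names)
        self.coords = np.array(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.names = np.array(names, dtype="U6")
        self.elements = np.array([e.upper() for e in elements], dtype="U2")
        self.res_names = np.array(res_names, dtype="U5")
        self.res_numbers = np.array(res_numbers, dtype=int)
        self.chain_ids = np.array(chain_ids, dtype="U4")
        self.insertion_codes = (
            np.array(insertion_codes, dtype="U1")
            if insertion_codes is not None
            else np.full(n, "", dtype="U1")
        )
        self.serials = (
            np.array(serials, dtype=int) if serials is not None else np.arange(1, n + 1)
        )
        self.hetero = (
            np.array(hetero, dtype=bool) if hetero is not None else np.zeros(n, dtype=bool)
        )
        if masses is None:
            masses = np.array([_chem.element_mass(e) for e in self.elements])
        if vdw_radii is None:
            vdw_radii = np.array([_chem.element_vdw(e) for e in self.elements])
        self.masses = np.asarray(masses, dtype=float)
        self.vdw_radii = np.asarray(vdw_radii, dtype=float)
        if np.any(self.masses <= 0) or np.any(self.vdw_radii <= 0):
            raise ValueError("masses and vdW radii must be positive")
        self.partial_charges = (
            np.asarray(partial_charges, dtype=float)
            if partial_charges is not None
            else np.full(n, np.nan)
        )
        self.formal_charges = (
            np.array(formal_charges, dtype=int)
            if formal_charges is not None
            else np.zeros(n, dtype=int)
        )
        self.metadata = metadata
        self._check_unique_keys()

    # -- hierarchy ---------------------------------------------------------
    def _check_unique_keys(self):
        keys = set()
        for i in range(self.n_atoms):
            k = (self.chain_ids[i], self.res_numbers[i], self.insertion_codes[i], self.names[i])
            if k in keys:
                raise ValueError(f"duplicate atom key {k}")
            keys.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def atoms(self) -> list:
        """Atom records (materialised view)."""
        out = []
        for i in range(self.n_atoms):
            pc = self.partial_charges[i]
            out.append(
                AtomRecord(
                    serial=int(self.serials[i]),
                    name=str(self.names[i]),
                    element=str(self.elements[i]),
                    residue_name=str(self.res_names[i]),
                    residue_number=int(self.res_numbers[i]),
                    insertion_code=str(self.insertion_codes[i]),
                    chain_id=str(self.chain_ids[i]),
                    position=self.coords[i].copy(),
                    mass=float(self.masses[i]),
                    vdw_radius=float(self.vdw_radii[i]),
                    partial_charge=None if np.isnan(pc) else float(pc),
                    formal_charge=int(self.formal_charges[i]),
                    hetero=bool(self.hetero[i]),
                )
            )
        return out

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue keys as an (N,) object array of tuples."""
        out = np.empty(self.n_atoms, dtype=object)
        for i in range(self.n_atoms):
            out[i] = (str(self.chain_ids[i]), int(self.res_numbers[i]), str(self.insertion_codes[i]))
        return out

    def unique_residues(self) -> list:
        """Residue keys in atom order (first occurrence)."""
        seen, out = set(), []
        for k in self.residue_keys():
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def chains(self) -> dict:
        """chain_id -> ordered residue keys."""
        out: dict = {}
        for key in self.unique_residues():
            out.setdefault(key[0], []).append(key)
        return out

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "Structure":
        return self.subset(np.ones(self.n_atoms, dtype=bool))

    def subset(self, mask) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_atoms, dtype=bool)
            idx[mask] = True
            mask = idx
        return Structure(
            self.coords[mask],
            self.names[mask],
            self.elements[mask],
            self.res_names[mask],
            self.res_numbers[mask],
            self.chain_ids[mask],
            self.insertion_codes[mask],
            self.serials[mask],
            self.hetero[mask],
            self.masses[mask],
            self.vdw_radii[mask],
            self.partial_charges[mask],
            self.formal_charges[mask],
            self.metadata,
        )

    def with_coords(self, coords: np.ndarray, metadata: Optional[str] = None) -> "Structure":
        new = self.copy()
        new.coords = np.array(coords, dtype=float).reshape(self.n_atoms, 3)
        if metadata is not None:
            new.metadata = metadata
        return new

    def residue_mask(self, keys: Iterable) -> np.ndarray:
        keyset = set(keys)
        return np.array([k in keyset for k in self.residue_keys()])

    def atom_index(self, chain_id: str, res_number: int, name: str, icode: str = "") -> int:
        hits = np.flatnonzero(
            (self.chain_ids == chain_id)
            & (self.res_numbers == res_number)
            & (self.insertion_codes == icode)
            & (self.names == name)
        )
        if len(hits) != 1:
            raise KeyError(f"atom ({chain_id}, {res_number}{icode or ''}, {name}) not found")
        return int(hits[0])

    def concat(self, other: "Structure") -> "Structure":
        """Concatenate two structures (atom keys must stay unique)."""
        return Structure(
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.names, other.names]),
            np.concatenate([self.elements, other.elements]),
            np.concatenate([self.res_names, other.res_names]),
            np.concatenate([self.res_numbers, other.res_numbers]),
            np.concatenate([self.chain_ids, other.chain_ids]),
            np.concatenate([self.insertion_codes, other.insertion_codes]),
            np.concatenate([self.serials, other.serials + self.serials.max()]),
            np.concatenate([self.hetero, other.hetero]),
            np.concatenate([self.masses, other.masses]),
            np.concatenate([self.vdw_radii, other.vdw_radii]),
            np.concatenate([self.partial_charges, other.partial_charges]),
            np.concatenate([self.formal_charges, other.formal_charges]),
            self.metadata,
        )

    def __repr__(self):
        nres = len(self.unique_residues())
        return f"<Structure {self.metadata or 'unnamed'}: {self.n_atoms} atoms, {nres} residues>"


@dataclass(frozen=True)
class Selection:
    """A set of residue keys ``(chain_id, residue_number, insertion_code)``."""

    members: frozenset
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self):
        return len(self.members)

    def __bool__(self):
        return len(self.members) > 0

    def __or__(self, other):
        return Selection(self.members | other.members, f"{self.label}|{other.label}")

    def __and__(self, other):
        return Selection(self.members & other.members, f"{self.label}&{other.label}")

    def validate(self, structure: Structure):
        present = set(structure.unique_residues())
        missing = self.members - present
        if missing:
            raise ValueError(f"selection members not in structure: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class BindingSite:
    """Residues lining a ligand pocket, defined by a contact cutoff."""

    selection: Selection
    defining_ligand: Selection
    contact_cutoff: float = 4.5
    site_name: str = ""


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------


def _from_atom_array(arr, metadata: str) -> Structure:
    import biotite.structure as bst

    n = arr.array_length()
    elements = []
    for i in range(n):
        el = arr.element[i].strip().upper()
        if not el:
            el = _chem.infer_element(arr.atom_name[i], arr.res_name[i])
        if el not in _chem.element_table():
            raise PDBFormatError(
                f"unresolvable element {el!r} for atom {arr.atom_name[i]!r}"
            )
        elements.append(el)
    serials = (
        arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    charges = (
        arr.get_annotation("charge") if "charge" in arr.get_annotation_categories()
        else np.zeros(n, dtype=int)
    )
    return Structure(
        coords=arr.coord,
        names=arr.atom_name,
        elements=elements,
        res_names=arr.res_name,
        res_numbers=arr.res_id,
        chain_ids=arr.chain_id,
        insertion_codes=arr.ins_code if "ins_code" in arr.get_annotation_categories() else None,
        serials=serials,
        hetero=arr.hetero,
        formal_charges=charges,
        metadata=metadata,
    )


def _load_pdb_file(path):
    import biotite.structure.io.pdb as pdb

    try:
        return pdb.PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc


def read_pdb(path, model_index: Optional[int] = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model_index`` is 1-based (PDB MODEL numbering); default is the first
    model. Highest-occupancy altloc is kept; masses and vdW radii are filled
    from the bundled element table; hydrogens are preserved if present.
    """
    pdbfile = _load_pdb_file(path)
    model = 1 if model_index is None else int(model_index)
    n_models = pdbfile.get_model_count()
    if not 1 <= model <= n_models:
        raise IndexError(f"model {model} out of range (file has {n_models})")
    try:
        arr = pdbfile.get_structure(
            model=model, altloc="occupancy", extra_fields=["atom_id", "charge"]
        )
    except Exception as exc:
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"no ATOM/HETATM records in {path}")
    return _from_atom_array(arr, metadata=str(path))


def read_models(path) -> list:
    """Read every model of a multi-model PDB as a list of Structures."""
    pdbfile = _load_pdb_file(path)
    return [
        _from_atom_array(
            pdbfile.get_structure(model=m, altloc="occupancy", extra_fields=["atom_id", "charge"]),
            metadata=f"{path}#model{m}",
        )
        for m in range(1, pdbfile.get_model_count() + 1)
    ]


def _to_atom_array(structure: Structure):
    import biotite.structure as bst

    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.atom_name = structure.names
    arr.element = structure.elements
    arr.res_name = structure.res_names
    arr.res_id = structure.res_numbers
    arr.chain_id = structure.chain_ids
    arr.ins_code = structure.insertion_codes
    arr.hetero = structure.hetero
    arr.set_annotation("atom_id", structure.serials.astype(int))
    arr.set_annotation("charge", structure.formal_charges.astype(int))
    return arr


def write_pdb(obj, path) -> None:
    """Write a Structure (single model) or a sequence of Structures /
    a DisplacedEnsemble (MODEL/ENDMDL multi-model file) as PDB text."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    conformers = getattr(obj, "conformers", None)
    if conformers is not None:
        structures = list(conformers)
    elif isinstance(obj, Structure):
        structures = [obj]
    else:
        structures = list(obj)
    if not structures or structures[0].n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    pdbfile = pdb.PDBFile()
    if len(structures) == 1:
        pdbfile.set_structure(_to_atom_array(structures[0]))
    else:
        stack = bst.stack([_to_atom_array(s) for s in structures])
        pdbfile.set_structure(stack)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------------
# Selection expressions
# ---------------------------------------------------------------------------
# Mini-grammar (documented in the README):
#   expr     := term (("and" | "or") term)*   -- left-associative, and/or equal precedence
#   term     := "not" term | "(" expr ")" | predicate
#   predicate:= "chain" ID | "resnum" N | "resnum" N:M | "resname" NAME
#             | "name" ATOM | "het" | "protein" | "all"


class _SelParser:
    def __init__(self, text: str, structure: Structure):
        self.tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        self.pos = 0
        self.s = structure

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise ValueError("empty selection expression")
        mask = self._expr()
        if self._peek() is not None:
            raise ValueError(f"trailing tokens in selection expression: {self.tokens[self.pos:]}")
        return mask

    def _expr(self):
        mask = self._term()
        while self._peek() in ("and", "or"):
            op = self._next()
            rhs = self._term()
            mask = (mask & rhs) if op == "and" else (mask | rhs)
        return mask

    def _term(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._term()
        if tok == "(":
            self._next()
            mask = self._expr()
            if self._next() != ")":
                raise ValueError("unbalanced parenthesis in selection expression")
            return mask
        return self._predicate()

    def _predicate(self):
        tok = self._next()
        s = self.s
        if tok == "chain":
            return s.chain_ids == self._next()
        if tok == "resnum":
            arg = self._next()
            if ":" in arg:
                lo, hi = arg.split(":")
                return (s.res_numbers >= int(lo)) & (s.res_numbers <= int(hi))
            return s.res_numbers == int(arg)
        if tok == "resname":
            return s.res_names == self._next().upper()
        if tok == "name":
            return s.names == self._next().upper()
        if tok == "het":
            return s.hetero.copy()
        if tok == "protein":
            return np.isin(s.res_names, list(_chem.PROTEIN_RESIDUES))
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        raise ValueError(f"unknown selection token {tok!r}")


def select(structure: Structure, expression: str) -> Selection:
    """Evaluate a selection expression to a residue-level Selection.

    A residue is selected when any of its atoms matches the expression.
    """
    mask = _SelParser(expression, structure).parse()
    keys = {k for k, m in zip(structure.residue_keys(), mask) if m}
    return Selection(frozenset(keys), label=expression)


def selection_atom_mask(structure: Structure, selection: Selection) -> np.ndarray:
    """Per-atom boolean mask for a residue-level selection."""
    return structure.residue_mask(selection.members)


# ---------------------------------------------------------------------------
# Binding sites & superposition
# ---------------------------------------------------------------------------


def define_binding_site(
    structure: Structure,
    ligand: Selection,
    cutoff: float = 4.5,
    site_name: str = "",
) -> BindingSite:
    """Residues with any atom within ``cutoff`` (inclusive) of any ligand
    atom, excluding the ligand's own residues."""
    from scipy.spatial import cKDTree

    if not ligand:
        raise ValueError("defining ligand selection is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand.validate(structure)
    lig_mask = structure.residue_mask(ligand.members)
    lig_tree = cKDTree(structure.coords[lig_mask])
    dmin, _ = lig_tree.query(structure.coords, k=1)
    contact = (dmin <= cutoff) & ~lig_mask
    keys = {k for k, c in zip(structure.residue_keys(), contact) if c}
    return BindingSite(
        selection=Selection(frozenset(keys), label=f"within {cutoff} A of {ligand.label}"),
        defining_ligand=ligand,
        contact_cutoff=cutoff,
        site_name=site_name,
    )


def superpose_structures(mobile: Structure, reference: Structure, mapping):
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    ``mapping`` is a sequence of paired atom keys
    ``((chain, resnum, name) | (chain, resnum, icode, name), same-for-reference)``.
    Returns ``(transformed_mobile, rmsd)`` where the RMSD is over the mapping.
    """

    def _index(s: Structure, key):
        if len(key) == 3:
            chain, num, name = key
            icode = ""
        else:
            chain, num, icode, name = key
        return s.atom_index(chain, num, name, icode)

    pairs = list(mapping)
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired atoms")
    mi = [_index(mobile, a) for a, _ in pairs]
    ri = [_index(reference, b) for _, b in pairs]
    rot, trans, rmsd = kabsch(mobile.coords[mi], reference.coords[ri])
    moved = mobile.with_coords(mobile.coords @ rot.T + trans)
    return moved, rmsd


def ca_mapping(mobile: Structure, reference: Structure) -> list:
    """Convenience pairing of shared C-alpha atom keys (same chain/resnum)."""
    mob = {
        (c, int(r), str(ic)): None
        for c, r, ic, nm in zip(
            mobile.chain_ids, mobile.res_numbers, mobile.insertion_codes, mobile.names
        )
        if nm == "CA"
    }
    pairs = []
    for c, r, ic, nm in zip(
        reference.chain_ids, reference.res_numbers, reference.insertion_codes, reference.names
    ):
        if nm == "CA" and (c, int(r), str(ic)) in mob:
            key = (str(c), int(r), str(ic), "CA")
            pairs.append((key, key))
    return pairs
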