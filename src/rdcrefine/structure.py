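"""Protein structure model and PDB input/output.

The in-memory model is deliberately small: ordered chains of residues, each
residue an ordered mapping of named atoms with Cartesian coordinates in
Angstroms.  Author (PDB) residue numbering is authoritative throughout the
package — internal indices never appear in any interface — because the
analyses this package supports cite residues by author numbering
(e.g. "Ala 230", "Thr 43").

PDB reading and writing are delegated to biotite's fixed-width PDB codec;
this module adds a light validation pass (insertion codes are rejected,
malformed ATOM records are reported with their line number) and the
conversion to and from the domain model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import ParseError, ValidationError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SecondaryStructureMap",
    "BondVectorSet",
    "read_structure",
    "write_structure",
    "write_ensemble",
    "extract_nh_vectors",
    "apply_numbering_offset",
]

#: Atom names that may carry the amide proton, in order of preference.
AMIDE_H_NAMES = ("H", "HN")

#: Residues without an amide proton.
_NO_AMIDE_H = {"PRO"}


@dataclass(frozen=True)
class Atom:
    """A named atom with a Cartesian coordinate in Angstroms."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValidationError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """A residue in author numbering with an ordered atom collection."""

    seq_id: int
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    hetero: bool = False

    def add(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise ValidationError(
                f"residue {self.name} {self.seq_id}: duplicate atom {atom.name!r}"
            )
        self.atoms[atom.name] = atom

    def get(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def coord(self, name: str) -> np.ndarray:
        atom = self.atoms.get(name)
        if atom is None:
            raise ValidationError(f"residue {self.name} {self.seq_id}: no atom {name!r}")
        return atom.coord

    @property
    def amide_h(self) -> Atom | None:
        for name in AMIDE_H_NAMES:
            if name in self.atoms:
                return self.atoms[name]
        return None


@dataclass(frozen=True)
class SecondaryStructureMap:
    """Labelled helix/strand ranges in author numbering.

    Ranges are supplied externally (annotation is an input of the analyses,
    not something derived from geometry here).
    """

    elements: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self):
        labels = set()
        for label, start, end, kind in self.elements:
            if kind not in ("helix", "strand"):
                raise ValidationError(f"element {label!r}: kind must be helix or strand")
            if start > end:
                raise ValidationError(f"element {label!r}: start {start} > end {end}")
            if label in labels:
                raise ValidationError(f"duplicate element label {label!r}")
            labels.add(label)
        for kind in ("helix", "strand"):
            spans = sorted(
                (s, e) for (_, s, e, k) in self.elements if k == kind
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValidationError(
                        f"overlapping {kind} ranges: {s1}-{e1} and {s2}-{e2}"
                    )

    def shifted(self, offset: int) -> "SecondaryStructureMap":
        return SecondaryStructureMap(
            tuple((l, s + offset, e + offset, k) for (l, s, e, k) in self.elements)
        )

    def residues(self, labels) -> list[int]:
        """Seq ids covered by the given element labels (author numbering)."""
        wanted = set(labels)
        known = {l for (l, _, _, _) in self.elements}
        missing = wanted - known
        if missing:
            raise ValidationError(f"unknown annotation labels: {sorted(missing)}")
        out: list[int] = []
        for label, start, end, _ in self.elements:
            if label in wanted:
                out.extend(range(start, end + 1))
        return sorted(set(out))


@dataclass
class Structure:
    """Ordered chains of residues for one model of a structure."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    model_id: int = 1
    annotation: SecondaryStructureMap | None = None
    numbering_offset: int = 0

    def __post_init__(self):
        for chain_id, residues in self.chains.items():
            seq_ids = [r.seq_id for r in residues]
            if len(set(seq_ids)) != len(seq_ids):
                raise ValidationError(f"chain {chain_id}: duplicate residue seq_ids")
            if seq_ids != sorted(seq_ids):
                raise ValidationError(f"chain {chain_id}: residues not ordered by seq_id")

    # -- iteration / lookup -------------------------------------------------

    def residues(self, include_hetero: bool = False):
        for residues in self.chains.values():
            for res in residues:
                if res.hetero and not include_hetero:
                    continue
                yield res

    def get_residue(self, seq_id: int, chain_id: str | None = None) -> Residue | None:
        chains = [self.chains[chain_id]] if chain_id else self.chains.values()
        for residues in chains:
            for res in residues:
                if res.seq_id == seq_id and not res.hetero:
                    return res
        return None

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def sequence(self, chain_id: str | None = None) -> str:
        """One-letter sequence of polymer residues (unknown codes map to X)."""
        out = []
        chains = [self.chains[chain_id]] if chain_id else self.chains.values()
        for residues in chains:
            for res in residues:
                if not res.hetero:
                    out.append(_THREE_TO_ONE.get(res.name, "X"))
        return "".join(out)

    # -- geometry -----------------------------------------------------------

    def coords(self, seq_ids=None, atom_names=("CA",), include_hetero=False) -> np.ndarray:
        """Stacked coordinates for the selection, in residue order."""
        wanted = None if seq_ids is None else set(seq_ids)
        rows = []
        for res in self.residues(include_hetero=include_hetero):
            if wanted is not None and res.seq_id not in wanted:
                continue
            for name in atom_names:
                atom = res.get(name)
                if atom is not None:
                    rows.append(atom.coord)
        return np.array(rows, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        chains = {
            cid: [
                Residue(r.seq_id, r.name, dict(r.atoms), r.hetero) for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(chains, self.model_id, self.annotation, self.numbering_offset)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with every atom mapped x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = self.copy()
        for residues in out.chains.values():
            for res in residues:
                for name, atom in list(res.atoms.items()):
                    res.atoms[name] = replace(atom, coord=rotation @ atom.coord + translation)
        return out

    def with_coords(self, flat: np.ndarray, include_hetero: bool = False) -> "Structure":
        """A copy with coordinates replaced from an (n_atoms, 3) array.

        Atom order matches iteration order of :meth:`residues` and each
        residue's atom insertion order.
        """
        flat = np.asarray(flat, float).reshape(-1, 3)
        out = self.copy()
        i = 0
        for res in out.residues(include_hetero=include_hetero):
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = replace(atom, coord=flat[i])
                i += 1
        if i != len(flat):
            raise ValidationError(f"coordinate array has {len(flat)} rows, structure has {i} atoms")
        return out

    def flat_coords(self, include_hetero: bool = False) -> np.ndarray:
        rows = []
        for res in self.residues(include_hetero=include_hetero):
            for atom in res.atoms.values():
                rows.append(atom.coord)
        return np.array(rows, float)


@dataclass(frozen=True)
class BondVectorSet:
    """Unit N->H bond vectors keyed by residue seq_id."""

    entries: tuple[tuple[int, np.ndarray], ...]
    skipped: tuple[int, ...] = ()

    def __post_init__(self):
        seen = set()
        for seq_id, vec in self.entries:
            vec = np.asarray(vec, float)
            if abs(np.linalg.norm(vec) - 1.0) > 1e-8:
                raise ValidationError(f"residue {seq_id}: bond vector is not unit norm")
            if seq_id in seen:
                raise ValidationError(f"residue {seq_id}: duplicate bond vector")
            seen.add(seq_id)

    def __len__(self):
        return len(self.entries)

    def as_dict(self) -> dict[int, np.ndarray]:
        return {seq_id: vec for seq_id, vec in self.entries}


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    """Reject records biotite would silently mangle; report line numbers."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError("ATOM record truncated before coordinates", lineno)
        if line[26].strip():
            raise ParseError(f"insertion code {line[26]!r} not supported", lineno)
        try:
            int(line[22:26])
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError:
            raise ParseError("unparsable residue number or coordinate field", lineno) from None


def read_structure(pdb_text: str, model_index: int = 0, keep_hetero: bool = False) -> Structure:
    """Parse one model of a PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    pdb_text : str
        PDB-format text (ATOM/HETATM/MODEL/ENDMDL/TER records).
    model_index : int
        0-based index of the model to extract (0 = first model).
    keep_hetero : bool
        Retain HETATM residues (heme, waters, ions).  They are excluded
        from bond-vector and superposition selections regardless.
    """
    _validate_pdb_lines(pdb_text)
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ParseError("no ATOM records found")
    if not 0 <= model_index < n_models:
        raise ValidationError(f"model index {model_index} not found ({n_models} models present)")
    arr = pdb.get_structure(model=model_index + 1)
    return _from_atom_array(arr, model_id=model_index + 1, keep_hetero=keep_hetero)


def _from_atom_array(arr: bst.AtomArray, model_id: int, keep_hetero: bool) -> Structure:
    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    current_key = None
    for i in range(arr.array_length()):
        hetero = bool(arr.hetero[i])
        if hetero and not keep_hetero:
            continue
        chain_id = str(arr.chain_id[i]) or "A"
        key = (chain_id, int(arr.res_id[i]), str(arr.res_name[i]), hetero)
        if key != current_key:
            current = Residue(int(arr.res_id[i]), str(arr.res_name[i]), hetero=hetero)
            chains.setdefault(chain_id, []).append(current)
            current_key = key
        current.add(Atom(str(arr.atom_name[i]), str(arr.element[i]), arr.coord[i]))
    if not any(chains.values()):
        raise ParseError("no ATOM records found")
    for chain_id in chains:  # hetero groups (e.g. waters) may share seq ids; keep polymer ordered
        polymer = [r for r in chains[chain_id] if not r.hetero]
        seq_ids = [r.seq_id for r in polymer]
        if seq_ids != sorted(seq_ids):
            polymer_sorted = sorted(polymer, key=lambda r: r.seq_id)
            hets = [r for r in chains[chain_id] if r.hetero]
            chains[chain_id] = polymer_sorted + hets
    return Structure(chains, model_id=model_id)


def _to_atom_array(s: Structure) -> bst.AtomArray:
    atoms = []
    for chain_id, residues in s.chains.items():
        for res in residues:
            for atom in res.atoms.values():
                if np.any(np.abs(atom.coord) >= 10000.0):
                    raise ValidationError(
                        f"residue {res.seq_id} atom {atom.name}: coordinate magnitude "
                        ">= 10000 A cannot be written in fixed-width PDB columns"
                    )
                atoms.append(
                    bst.Atom(
                        atom.coord,
                        chain_id=chain_id,
                        res_id=res.seq_id,
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element,
                        hetero=res.hetero,
                    )
                )
    if not atoms:
        raise ValidationError("cannot write an empty structure")
    return bst.array(atoms)


def write_structure(s: Structure) -> str:
    """Serialize a structure to PDB-format text (fixed-width columns)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def write_ensemble(members) -> str:
    """Serialize several conformers of one structure as MODEL/ENDMDL blocks."""
    members = list(members)
    if not members:
        raise ValidationError("cannot write an empty ensemble")
    arrays = [_to_atom_array(m) for m in members]
    stack = bst.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Bond vectors and numbering
# ---------------------------------------------------------------------------

def extract_nh_vectors(s: Structure) -> BondVectorSet:
    """Unit N->H amide bond vectors, one per residue that has both atoms.

    Prolines and residues lacking an amide proton are skipped (and listed in
    ``skipped``); no hydrogen building is attempted.
    """
    entries = []
    skipped = []
    for res in s.residues():
        n = res.get("N")
        h = res.amide_h
        if res.name in _NO_AMIDE_H or n is None or h is None:
            skipped.append(res.seq_id)
            continue
        vec = h.coord - n.coord
        norm = np.linalg.norm(vec)
        if norm == 0:
            skipped.append(res.seq_id)
            continue
        entries.append((res.seq_id, vec / norm))
    if not entries:
        raise ValidationError("no N-H bond vectors could be extracted")
    return BondVectorSet(tuple(entries), tuple(skipped))


def apply_numbering_offset(s: Structure, offset: int) -> Structure:
    """Shift all residue seq_ids (and annotation ranges) by ``offset``.

    Offsets compose additively, so shifting by a then b equals shifting by
    a + b; the cumulative offset is recorded on the returned structure.
    """
    chains = {
        cid: [
            Residue(r.seq_id + offset, r.name, dict(r.atoms), r.hetero)
            for r in residues
        ]
        for cid, residues in s.chains.items()
    }
    annotation = s.annotation.shifted(offset) if s.annotation is not None else None
    return Structure(chains, s.model_id, annotation, s.numbering_offset + offset)
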