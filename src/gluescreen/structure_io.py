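"""Macromolecular structure input/output.

Reads PDB and mmCIF coordinate files (via gemmi) and decomposes them into
the package's working representation: chains of polymer residues plus a flat
list of small-molecule ligand instances.  Waters are never ligands, hydrogens
are dropped on parse, and only the first model of a multi-model file is kept.
Structures (optionally with transferred ligand poses) are written back as
standard fixed-width PDB records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueUnit",
    "LigandInstance",
    "ChainRecord",
    "StructureModel",
    "ParseError",
    "parse_structure",
    "write_structure",
]

#: residue names treated as water (never ligands)
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "OH2"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ParseError(ValueError):
    """Raised for malformed or empty (no polymer chain) structure files."""


@dataclass
class AtomRecord:
    """A single heavy atom: label, element symbol and Cartesian position (Å)."""

    name: str
    element: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class ResidueUnit:
    """One residue (polymer or hetero) with its heavy atoms."""

    chain_id: str
    seq_position: int
    comp_id: str
    atoms: list[AtomRecord]
    is_polymer: bool = True
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_position, insertion code) — unique within a model."""
        return (self.chain_id, self.seq_position, self.icode)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandInstance:
    """A bound small molecule (non-water hetero group), possibly a metal ion."""

    comp_id: str
    instance_key: tuple[str, int]
    atoms: list[AtomRecord]
    is_metal: bool = False
    known_iap: bool | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class ChainRecord:
    """A polymer chain: ordered residues and the matching one-letter sequence."""

    chain_id: str
    residues: list[ResidueUnit]
    sequence: str

    def coords(self) -> np.ndarray:
        return np.concatenate([r.coords() for r in self.residues])


@dataclass
class StructureModel:
    """Parsed structure: polymer chains + ligand instances.

    ``source`` distinguishes experimental coordinates from predicted dimer
    models; ``confidence`` carries an optional interface-confidence score in
    [0, 1] supplied with predicted models (it is input metadata, never
    computed here).
    """

    model_id: str
    chains: list[ChainRecord]
    ligands: list[LigandInstance] = field(default_factory=list)
    source: str = "experimental"
    confidence: float | None = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id!r}")

    def protein_coords(self) -> np.ndarray:
        """Heavy-atom coordinates of all polymer residues."""
        return np.concatenate([c.coords() for c in self.chains])

    def polymer_residues(self) -> list[ResidueUnit]:
        return [r for c in self.chains for r in c.residues]


def one_letter(comp_id: str) -> str:
    if comp_id in _THREE_TO_ONE:
        return _THREE_TO_ONE[comp_id]
    info = gemmi.find_tabulated_residue(comp_id)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    # ATOM records are polymer by definition; HETATM residues count as polymer
    # only when they are tabulated amino acids (e.g. phosphoserine in a chain).
    if res.het_flag == "A":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info is not None and info.is_amino_acid() and not info.is_water())


def _dedup_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties broken by label order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        if atom.is_hydrogen():
            continue
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def parse_structure(path: str | os.PathLike, dialect: str = "auto",
                    source: str = "experimental",
                    confidence: float | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is read; hydrogens are dropped;
    for alternate locations the highest-occupancy conformer is kept; waters
    are excluded from the ligand list.

    Parameters
    ----------
    path : file path
    dialect : {"auto", "pdb", "mmcif"}
        File format; "auto" detects from contents/extension.
    source, confidence
        Passed through to the model (predicted-model metadata).
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise FileNotFoundError(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(path)
        elif dialect == "mmcif":
            st = gemmi.cif.read(path)
            st = gemmi.make_structure_from_block(st.sole_block())
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")

    model = st[0]
    chains: list[ChainRecord] = []
    ligands: list[LigandInstance] = []
    for ch in model:
        poly: list[ResidueUnit] = []
        for res in ch:
            atoms = [
                AtomRecord(a.name, a.element.name or "C",
                           np.array([a.pos.x, a.pos.y, a.pos.z]),
                           is_hetero=res.het_flag == "H")
                for a in _dedup_altloc(res)
            ]
            if not atoms:
                continue
            if res.name in WATER_NAMES or res.is_water():
                continue
            if _is_polymer_residue(res):
                poly.append(ResidueUnit(ch.name, res.seqid.num, res.name, atoms,
                                        is_polymer=True,
                                        icode=(res.seqid.icode or "").strip()))
            else:
                is_metal = (len(atoms) == 1
                            and gemmi.Element(atoms[0].element).is_metal)
                ligands.append(LigandInstance(res.name, (ch.name, res.seqid.num),
                                              atoms, is_metal=is_metal))
        if poly:
            seq = "".join(one_letter(r.comp_id) for r in poly)
            chains.append(ChainRecord(ch.name, poly, seq))

    if not chains:
        raise ParseError(f"{path}: no polymer chains")
    model_id = os.path.splitext(os.path.basename(path))[0]
    return StructureModel(model_id, chains, ligands, source=source,
                          confidence=confidence)


def _pdb_line(record: str, serial: int, atom: AtomRecord, comp: str,
              chain_id: str, seq: int, icode: str = "") -> str:
    name = atom.name
    # standard PDB alignment: 1/2-char element names start in column 13/14
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    x, y, z = atom.position
    return (f"{record:<6}{serial:>5} {name:<4} {comp:>3} {chain_id:1}"
            f"{seq:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2}\n")


def write_structure(model: StructureModel,
                    path: str | os.PathLike,
                    placed: list[tuple[str, list[AtomRecord]]] | None = None) -> None:
    """Write a model as a PDB file.

    ``placed`` is an optional list of ``(comp_id, atoms)`` transferred ligand
    poses; each is emitted as a HETATM group on chain ``Z`` numbered from 901.
    """
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            rec = "HETATM" if res.atoms[0].is_hetero else "ATOM"
            for atom in res.atoms:
                serial += 1
                lines.append(_pdb_line(rec, serial, atom, res.comp_id,
                                       res.chain_id, res.seq_position, res.icode))
        serial += 1
        lines.append(f"TER   {serial:>5}\n")
    for lig in model.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(_pdb_line("HETATM", serial, atom, lig.comp_id,
                                   lig.instance_key[0], lig.instance_key[1]))
    for i, (comp_id, atoms) in enumerate(placed or []):
        for atom in atoms:
            serial += 1
            lines.append(_pdb_line("HETATM", serial, atom, comp_id, "Z", 901 + i))
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
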