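"""Path-based 2D fingerprints and Tanimoto leader clustering of ligands.

Fingerprints are Daylight-style hashed linear-path bitsets: every simple
path of 1–7 bonds is serialized from atom invariants (element, heavy
degree, formal charge) and bond orders, canonicalized by direction, and
hashed onto 2 of 2048 bits; isolated atoms contribute one atom-type bit.
Clustering is leader (Butina-style): the unassigned ligand with the most
unassigned neighbors at Tanimoto ≥ threshold repeatedly becomes a centroid
and absorbs those neighbors.

Chemical graphs come from an explicit atom/bond list, from an RDKit Mol,
or from coordinates with covalent-radius bond perception.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .structure_io import LigandInstance

__all__ = [
    "MolGraph",
    "FingerprintBits",
    "LigandCluster",
    "ligand_fingerprint",
    "tanimoto",
    "cluster_at_threshold",
    "graph_from_rdkit",
    "graph_from_ligand",
]

# single-bond covalent radii (Å) for distance-based bond perception
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                  "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39}
_BOND_SLACK = 0.45


@dataclass
class MolGraph:
    """Minimal chemical graph: per-atom element/charge and bonded pairs."""

    elements: list[str]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    charges: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty chemical graph")
        if self.charges is None:
            self.charges = [0] * len(self.elements)
        self.bonds = [(min(i, j), max(i, j), o) for i, j, o in self.bonds]

    @property
    def degree(self) -> list[int]:
        deg = [0] * len(self.elements)
        for i, j, _ in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self) -> list[list[tuple[int, int]]]:
        adj: list[list[tuple[int, int]]] = [[] for _ in self.elements]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


@dataclass
class FingerprintBits:
    ligand_comp_id: str
    bits: np.ndarray  # bool, fixed length

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_bits(self) -> int:
        return self.bits.size


@dataclass
class LigandCluster:
    centroid: str
    members: list[str]


def graph_from_rdkit(mol) -> MolGraph:
    """Convert an RDKit Mol (hydrogens implicit/stripped) to a MolGraph."""
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    remap = {k: i for i, k in enumerate(idx)}
    elements = [mol.GetAtomWithIdx(k).GetSymbol().upper() for k in idx]
    charges = [mol.GetAtomWithIdx(k).GetFormalCharge() for k in idx]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            bonds.append((remap[i], remap[j],
                          max(1, int(round(b.GetBondTypeAsDouble())))))
    return MolGraph(elements, bonds, charges)


def graph_from_ligand(ligand: LigandInstance) -> MolGraph:
    """Perceive bonds from coordinates: bonded iff within summed covalent
    radii + 0.45 Å (all orders taken as single)."""
    elements = [a.element.upper() for a in ligand.atoms]
    xyz = ligand.coords()
    bonds = []
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            rmax = (COVALENT_RADII.get(elements[i], 0.76)
                    + COVALENT_RADII.get(elements[j], 0.76) + _BOND_SLACK)
            if np.linalg.norm(xyz[i] - xyz[j]) < rmax:
                bonds.append((i, j, 1))
    return MolGraph(elements, bonds)


def _atom_invariant(graph: MolGraph, deg: list[int], i: int) -> str:
    return f"{graph.elements[i]}/{deg[i]}/{graph.charges[i]}"


def _hash_bits(key: str, n_bits: int, n_per_hash: int = 2) -> list[int]:
    return [zlib.crc32(f"{salt}|{key}".encode()) % n_bits
            for salt in range(n_per_hash)]


def ligand_fingerprint(graph: MolGraph, comp_id: str = "",
                       n_bits: int = 2048, max_path: int = 7
                       ) -> FingerprintBits:
    """Hashed linear-path fingerprint; deterministic for identical graphs."""
    deg = graph.degree
    inv = [_atom_invariant(graph, deg, i) for i in range(len(graph.elements))]
    adj = graph.neighbors()
    bits = np.zeros(n_bits, dtype=bool)

    for i in range(len(inv)):  # 0-bond paths: one atom-type bit each
        bits[_hash_bits(inv[i], n_bits, 1)] = True

    def extend(path: list[int], labels: list[str]) -> None:
        if 1 <= len(path) - 1 <= max_path:
            reverse = labels[::-1]
            key = "|".join(min(labels, reverse))
            bits[_hash_bits(key, n_bits)] = True
        if len(path) - 1 == max_path:
            return
        for nb, order in adj[path[-1]]:
            if nb in path:
                continue
            extend(path + [nb], labels + [str(order), inv[nb]])

    for start in range(len(inv)):
        extend([start], [inv[start]])
    return FingerprintBits(comp_id, bits)


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """|a ∧ b| / |a ∨ b|; 1.0 when both fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint length mismatch")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


def cluster_at_threshold(fingerprints: list[FingerprintBits],
                         threshold: float = 0.8) -> list[LigandCluster]:
    """Leader clustering at a Tanimoto threshold.

    Repeatedly the unassigned ligand with the most unassigned neighbors at
    T ≥ threshold (ties: input order) becomes a centroid and absorbs those
    neighbors; clusters are returned sorted by size descending.
    """
    if not fingerprints:
        raise ValueError("no fingerprints to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = len(fingerprints)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fingerprints[i], fingerprints[j])
    neighbor = sim >= threshold

    unassigned = list(range(n))
    clusters: list[LigandCluster] = []
    while unassigned:
        counts = [int(neighbor[i, unassigned].sum()) for i in unassigned]
        leader = unassigned[int(np.argmax(counts))]
        members = [i for i in unassigned if neighbor[leader, i]]
        clusters.append(LigandCluster(
            fingerprints[leader].ligand_comp_id,
            [fingerprints[i].ligand_comp_id for i in members]))
        unassigned = [i for i in unassigned if i not in members]
    clusters.sort(key=lambda c: -len(c.members))
    return clusters
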