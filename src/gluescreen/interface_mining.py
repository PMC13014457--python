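"""Chain–chain interface detection and interface-adjacent (IAP) ligand calls.

A chain pair is a *valid dimer* when each chain contributes at least five
interacting residues to its partner, and a bound ligand is *interface
adjacent* when it contacts at least five residues on each chain.  "Contact"
is a heavy-atom/heavy-atom distance within a cutoff (default 4.5 Å, the
standard van-der-Waals contact convention); a residue counts once no matter
how many of its atoms are in contact.

Contact search uses a k-d tree but is contractually identical to the
all-pairs brute force (see the test-suite oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import ChainRecord, LigandInstance, StructureModel

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "ContactPair",
    "InterfaceAnnotation",
    "IapLigandCall",
    "residue_contacts",
    "annotate_interface",
    "call_iap_ligands",
    "iap_census",
]

#: heavy-atom contact cutoff in Å for residue–residue and ligand–residue contacts
DEFAULT_CONTACT_CUTOFF = 4.5

#: minimum interacting residues per chain for a valid dimer / qualifying ligand
MIN_INTERFACE_RESIDUES = 5

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float


@dataclass
class InterfaceAnnotation:
    """Interface of one chain pair; ``valid_dimer`` applies the ≥5/≥5 rule."""

    chain_pair: tuple[str, str]
    interacting_residues_a: set[ResidueKey]
    interacting_residues_b: set[ResidueKey]
    contacts: list[ContactPair] = field(default_factory=list)

    @property
    def valid_dimer(self) -> bool:
        return (len(self.interacting_residues_a) >= MIN_INTERFACE_RESIDUES
                and len(self.interacting_residues_b) >= MIN_INTERFACE_RESIDUES)


@dataclass
class IapLigandCall:
    ligand: LigandInstance
    contacted_a: int
    contacted_b: int

    @property
    def qualifies(self) -> bool:
        return (self.contacted_a >= MIN_INTERFACE_RESIDUES
                and self.contacted_b >= MIN_INTERFACE_RESIDUES)


def _chain_atom_index(chain: ChainRecord) -> tuple[np.ndarray, list[ResidueKey]]:
    """Flat coordinate array + parallel residue-key list for a chain."""
    coords: list[np.ndarray] = []
    keys: list[ResidueKey] = []
    for res in chain.residues:
        for atom in res.atoms:
            coords.append(atom.position)
            keys.append(res.key)
    return np.asarray(coords, dtype=float).reshape(-1, 3), keys


def residue_contacts(chain_a: ChainRecord, chain_b: ChainRecord,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[ContactPair]:
    """All residue pairs with any heavy-atom pair within ``cutoff`` Å.

    ``min_distance`` is the minimum heavy-atom distance of the pair.  Empty
    chains yield an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz_a, keys_a = _chain_atom_index(chain_a)
    xyz_b, keys_b = _chain_atom_index(chain_b)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return []
    tree_a, tree_b = cKDTree(xyz_a), cKDTree(xyz_b)
    dist = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for i, j, d in zip(dist.row, dist.col, dist.data):
        pair = (keys_a[i], keys_b[j])
        if d < best.get(pair, np.inf):
            best[pair] = d
    return sorted(
        (ContactPair(a, b, d) for (a, b), d in best.items()),
        key=lambda c: (c.residue_a, c.residue_b),
    )


def annotate_interface(model: StructureModel, chain_pair: tuple[str, str],
                       cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InterfaceAnnotation:
    """Annotate one chain pair; symmetric under swapping the pair."""
    chain_a = model.chain(chain_pair[0])
    chain_b = model.chain(chain_pair[1])
    contacts = residue_contacts(chain_a, chain_b, cutoff)
    return InterfaceAnnotation(
        chain_pair=tuple(chain_pair),
        interacting_residues_a={c.residue_a for c in contacts},
        interacting_residues_b={c.residue_b for c in contacts},
        contacts=contacts,
    )


def call_iap_ligands(model: StructureModel, annotation: InterfaceAnnotation,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[IapLigandCall]:
    """Per-ligand contacted-residue counts on each chain of a valid dimer.

    A ligand qualifies as interface adjacent when it contacts ≥5 residues on
    each chain.
    """
    if not annotation.valid_dimer:
        raise ValueError("IAP calls require a valid dimer (≥5 interface "
                         "residues on each chain)")
    calls: list[IapLigandCall] = []
    indexes = {
        cid: _chain_atom_index(model.chain(cid)) for cid in annotation.chain_pair
    }
    for lig in model.ligands:
        lig_xyz = lig.coords()
        tree = cKDTree(lig_xyz)
        counts = []
        for cid in annotation.chain_pair:
            xyz, keys = indexes[cid]
            hits = tree.query_ball_point(xyz, cutoff)
            counts.append(len({keys[i] for i, h in enumerate(hits) if h}))
        calls.append(IapLigandCall(lig, counts[0], counts[1]))
    return calls


def iap_census(models: list[StructureModel],
               cutoff: float = DEFAULT_CONTACT_CUTOFF) -> pd.DataFrame:
    """TSV-ready census over models: one row per (chain pair, ligand).

    Chain pairs with no ligands still get a row (ligand columns empty) so the
    dimer-validity census is complete.
    """
    rows = []
    for model in models:
        ids = [c.chain_id for c in model.chains]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ann = annotate_interface(model, (ids[i], ids[j]), cutoff)
                base = {
                    "model_id": model.model_id,
                    "chain_a": ids[i],
                    "chain_b": ids[j],
                    "n_interface_a": len(ann.interacting_residues_a),
                    "n_interface_b": len(ann.interacting_residues_b),
                    "valid_dimer": ann.valid_dimer,
                }
                if not ann.valid_dimer or not model.ligands:
                    rows.append({**base, "ligand": "", "contacted_a": "",
                                 "contacted_b": "", "qualifies": ""})
                    continue
                for call in call_iap_ligands(model, ann, cutoff):
                    rows.append({**base,
                                 "ligand": call.ligand.comp_id,
                                 "contacted_a": call.contacted_a,
                                 "contacted_b": call.contacted_b,
                                 "qualifies": call.qualifies})
    return pd.DataFrame(rows, columns=["model_id", "chain_a", "chain_b",
                                       "n_interface_a", "n_interface_b",
                                       "valid_dimer", "ligand", "contacted_a",
                                       "contacted_b", "qualifies"])
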