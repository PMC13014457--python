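"""Grid-based surface-cavity detection.

A regular grid is laid over the structure; a grid point is *empty* when it
lies farther than (vdW radius + probe) from every heavy-atom center, and
*pocket-like* when enough of 14 fixed ray directions (6 axial + 8 body
diagonals) are blocked by a protein atom within 8 Å along a narrow corridor.
Connected pocket-like points (26-neighbourhood) form a cavity; volume is
point count × spacing³ and lining residues are those with a heavy atom
within the lining cutoff of any cavity point.

The library filter keeps cavities with ≥10 lining residues and volume
≥100 Å³; interface adjacency is decided from the lining set against a dimer
interface annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .interface_mining import InterfaceAnnotation, ResidueKey
from .structure_io import StructureModel

__all__ = [
    "GridSpec",
    "PocketCavity",
    "detect_cavities",
    "filter_pockets",
    "tag_interface_adjacent",
    "cavity_debug_pdb",
    "VDW_RADII",
    "MIN_POCKET_RESIDUES",
    "MIN_POCKET_VOLUME",
]

#: per-element van der Waals radii (Å); anything unlisted falls back to carbon
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_VDW = 1.7

MIN_POCKET_RESIDUES = 10   # library filter: lining residues
MIN_POCKET_VOLUME = 100.0  # library filter: Å³

# 6 axial + 8 body-diagonal unit vectors for the buriedness scan
_AXIAL = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                   [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
_DIAG = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                  for sz in (-1, 1)], dtype=float) / np.sqrt(3.0)
RAY_DIRECTIONS = np.vstack([_AXIAL, _DIAG])


@dataclass(frozen=True)
class GridSpec:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must all be ≥ 1")


@dataclass
class PocketCavity:
    pocket_id: str
    points: np.ndarray            # (n, 3) grid-point coordinates, Å
    spacing: float
    lining_residues: set[ResidueKey]
    interface_adjacent: bool = False

    @property
    def volume(self) -> float:
        return float(len(self.points)) * self.spacing ** 3

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _grid_points(coords: np.ndarray, spacing: float, margin: float) -> GridSpec:
    # origin snapped to a multiple of spacing so grids are translation-stable
    lo = spacing * np.floor((coords.min(axis=0) - margin) / spacing)
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((h - o) / spacing)) + 1 for o, h in zip(lo, hi))
    return GridSpec(lo, spacing, dims)


def detect_cavities(model: StructureModel, spacing: float = 1.0,
                    probe_exclusion: float = 1.4, buried_threshold: int = 9,
                    *, block_range: float = 8.0, corridor: float = 1.2,
                    lining_cutoff: float = 4.5,
                    margin: float = 3.0) -> list[PocketCavity]:
    """Detect cavities on the polymer part of ``model``.

    Returns cavities sorted by volume descending (ties by centroid order).
    Degenerate geometry (too few/collinear atoms) simply yields no cavities.
    """
    residues = model.polymer_residues()
    atom_xyz, atom_keys = [], []
    for res in residues:
        for atom in res.atoms:
            atom_xyz.append(atom.position)
            atom_keys.append((res.key, atom.element))
    if not atom_xyz:
        raise ValueError("model has no polymer heavy atoms")
    atom_xyz = np.asarray(atom_xyz)
    radii = np.array([VDW_RADII.get(el, DEFAULT_VDW) + probe_exclusion
                      for _, el in atom_keys])

    grid = _grid_points(atom_xyz, spacing, margin)
    axes = [grid.origin[k] + spacing * np.arange(grid.dims[k]) for k in range(3)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(atom_xyz)
    # a point farther than block_range from every atom cannot be blocked at all
    dmin, _ = tree.query(mesh, k=1, distance_upper_bound=block_range)
    cand_idx = np.nonzero(np.isfinite(dmin))[0]
    if cand_idx.size == 0:
        return []
    cand = mesh[cand_idx]

    reach = float(np.hypot(block_range, corridor))
    neighbor_lists = tree.query_ball_point(cand, max(radii.max(), reach))
    pocketlike = np.zeros(len(cand), dtype=bool)
    corr2 = corridor * corridor
    for i, neigh in enumerate(neighbor_lists):
        if not neigh:
            continue
        diffs = atom_xyz[neigh] - cand[i]
        d2 = np.einsum("ij,ij->i", diffs, diffs)
        if np.any(d2 <= radii[neigh] ** 2):
            continue  # inside an atom's exclusion shell: not empty
        proj = diffs @ RAY_DIRECTIONS.T
        perp2 = d2[:, None] - proj ** 2
        blocked = np.any((proj > 1e-9) & (proj <= block_range)
                         & (perp2 <= corr2), axis=0)
        pocketlike[i] = int(blocked.sum()) >= buried_threshold
    if not pocketlike.any():
        return []

    # cluster pocket-like points with 26-connectivity on the index grid
    occ = np.zeros(grid.dims, dtype=bool)
    kept = cand[pocketlike]
    ijk = np.rint((kept - grid.origin) / spacing).astype(int)
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    labels, n_comp = ndimage.label(occ, structure=np.ones((3, 3, 3), dtype=int))

    cavities: list[PocketCavity] = []
    comp_of = labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    for comp in range(1, n_comp + 1):
        pts = kept[comp_of == comp]
        ptree = cKDTree(pts)
        lining: set[ResidueKey] = set()
        hits = ptree.query_ball_point(atom_xyz, lining_cutoff)
        for ai, h in enumerate(hits):
            if h:
                lining.add(atom_keys[ai][0])
        cavities.append(PocketCavity("", pts, spacing, lining))
    cavities.sort(key=lambda c: (-c.volume, tuple(np.round(c.centroid, 6))))
    for k, cav in enumerate(cavities):
        cav.pocket_id = f"{model.model_id}:pocket{k}"
    return cavities


def filter_pockets(cavities: list[PocketCavity],
                   min_residues: int = MIN_POCKET_RESIDUES,
                   min_volume: float = MIN_POCKET_VOLUME) -> list[PocketCavity]:
    """Library filter: ≥``min_residues`` lining residues AND ≥``min_volume`` Å³."""
    return [c for c in cavities
            if len(c.lining_residues) >= min_residues and c.volume >= min_volume]


def tag_interface_adjacent(cavities: list[PocketCavity],
                           annotation: InterfaceAnnotation) -> list[PocketCavity]:
    """Flag cavities adjacent to the dimer interface (in place; list returned).

    A cavity is interface adjacent when its lining residues include at least
    one residue from each chain of the pair, or at least three residues that
    are members of the interface residue sets.
    """
    if not annotation.valid_dimer:
        raise ValueError("interface tagging requires a valid dimer")
    iface = annotation.interacting_residues_a | annotation.interacting_residues_b
    ca, cb = annotation.chain_pair
    for cav in cavities:
        chains_lined = {key[0] for key in cav.lining_residues}
        both_chains = ca in chains_lined and cb in chains_lined
        n_iface = len(cav.lining_residues & iface)
        cav.interface_adjacent = both_chains or n_iface >= 3
    return cavities


def cavity_debug_pdb(cavities: list[PocketCavity], path: str) -> None:
    """Write cavity grid points as HETATM pseudo-atoms for visual inspection."""
    with open(path, "w") as fh:
        serial = 0
        for k, cav in enumerate(cavities):
            for pt in cav.points:
                serial += 1
                fh.write(f"HETATM{serial:>5}  O   PKT Z{k + 1:>4}    "
                         f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}"
                         f"{1.0:6.2f}{0.0:6.2f}           O\n")
        fh.write("END\n")
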