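"""Deterministic synthetic structures with exact ground truth.

Every other module is testable offline through three generators:

* :func:`generate_dimer` — two pseudo-protein strands with an exactly
  controlled number of cross-chain contact residues;
* :func:`generate_glue_scenario` — a dimer carrying a planted spherical
  interface cavity (built from a dense double shell of pseudo-atoms grouped
  into residues) plus a monomeric template holding a rotated / noised /
  mutated copy of that pocket with a synthetic ligand bound at its center;
* :func:`generate_decoys` — random compact pocket signatures for fitting
  the alignment null model.

Geometry is idealized (3.8 Å Cα spacing strands, shells sized so the grid
scan recovers the designed cavity) rather than drawn from real folds: the
point is exact, seeded ground truth, not realism.  All randomness flows
from ``numpy.random.default_rng(spec.rng_seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interface_mining import ContactPair, InterfaceAnnotation
from .pocket_alignment import PocketSignature
from .structure_io import (AtomRecord, ChainRecord, LigandInstance,
                           ResidueUnit, StructureModel, one_letter)

__all__ = [
    "ScenarioSpec",
    "ScenarioBundle",
    "generate_dimer",
    "generate_glue_scenario",
    "generate_decoys",
    "carved_cube_model",
    "CUBE_PROBE_EXCLUSION",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# carbon vdW + water probe: exclusion radius around shell atoms in the scan
_CARBON_EXCLUSION = 1.7 + 1.4

#: probe to use with :func:`carved_cube_model` (oxygen walls, thin probe)
CUBE_PROBE_EXCLUSION = 0.5


class GenerationError(ValueError):
    """Raised for geometrically infeasible scenario specs."""


@dataclass
class ScenarioSpec:
    """Study conditions of one synthetic glue scenario."""

    n_residues_per_chain: int = 20
    n_interface_contacts: int = 8
    pocket_size: int = 12            # designed lining residues
    pocket_volume_target: float = 125.0  # Å³
    ligand_n_atoms: int = 8
    noise_sigma: float = 0.0         # Å, isotropic per-atom displacement
    mutation_fraction: float = 0.0   # fraction of lining identities resampled
    rotation: np.ndarray | None = None  # proper rotation; random if None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise GenerationError("mutation_fraction must lie in [0, 1]")
        if self.n_interface_contacts > self.n_residues_per_chain:
            raise GenerationError("more contacts requested than residues")
        if self.pocket_size < 3:
            raise GenerationError("pocket_size must be ≥ 3")


@dataclass
class ScenarioBundle:
    target_dimer: StructureModel
    template: StructureModel
    true_pose: list[AtomRecord]
    truth_annotation: InterfaceAnnotation
    truth_lining: set        # designed lining residue keys in the target
    rotation: np.ndarray     # applied target→template rotation
    translation: np.ndarray


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _strand_residues(chain_id: str, n: int, y_of: list[float],
                     letters: str, x0: float = 0.0,
                     cb_sign: float = -1.0) -> list[ResidueUnit]:
    out = []
    for i in range(n):
        ca = np.array([x0 + 3.8 * i, y_of[i], 0.0])
        cb = ca + np.array([0.0, cb_sign * 1.5, 0.0])
        out.append(ResidueUnit(chain_id, i + 1, _ONE_TO_THREE[letters[i]],
                               [AtomRecord("CA", "C", ca),
                                AtomRecord("CB", "C", cb)]))
    return out


def _brute_force_annotation(chain_a: ChainRecord, chain_b: ChainRecord,
                            cutoff: float = 4.5) -> InterfaceAnnotation:
    """All-pairs contact truth computed directly inside the generator."""
    contacts = []
    for ra in chain_a.residues:
        xa = ra.coords()
        for rb in chain_b.residues:
            d = np.linalg.norm(xa[:, None, :] - rb.coords()[None, :, :],
                               axis=2).min()
            if d <= cutoff:
                contacts.append(ContactPair(ra.key, rb.key, float(d)))
    return InterfaceAnnotation(
        (chain_a.chain_id, chain_b.chain_id),
        {c.residue_a for c in contacts}, {c.residue_b for c in contacts},
        sorted(contacts, key=lambda c: (c.residue_a, c.residue_b)))


def generate_dimer(spec: ScenarioSpec
                   ) -> tuple[StructureModel, InterfaceAnnotation]:
    """Two strands with exactly ``n_interface_contacts`` contact residues each.

    Contact residues of chain B sit 4.0 Å (< 4.5 cutoff) across from their
    chain-A partner; all other cross-chain residue pairs are > 4.5 Å apart.
    Byte-identical output for equal seeds.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_residues_per_chain
    letters_a = "".join(rng.choice(list(_AA20), n))
    letters_b = "".join(rng.choice(list(_AA20), n))
    y_b = [4.0 if i < spec.n_interface_contacts else 9.0 for i in range(n)]
    res_a = _strand_residues("A", n, [0.0] * n, letters_a, cb_sign=-1.0)
    res_b = _strand_residues("B", n, y_b, letters_b, cb_sign=+1.0)
    model = StructureModel(
        f"dimer_s{spec.rng_seed}",
        [ChainRecord("A", res_a, letters_a), ChainRecord("B", res_b, letters_b)])
    truth = InterfaceAnnotation(
        ("A", "B"),
        {res_a[i].key for i in range(spec.n_interface_contacts)},
        {res_b[i].key for i in range(spec.n_interface_contacts)},
        [ContactPair(res_a[i].key, res_b[i].key, 4.0)
         for i in range(spec.n_interface_contacts)])
    return model, truth


def _shell_residues(chain_id: str, first_num: int, atoms_xyz: np.ndarray,
                    centers: np.ndarray, center_mask: np.ndarray,
                    letters: list[str], name_prefix: str
                    ) -> list[ResidueUnit]:
    """Group shell atoms into residues by nearest designed center."""
    assign = np.argmin(np.linalg.norm(
        atoms_xyz[:, None, :] - centers[None, :, :], axis=2), axis=1)
    out = []
    num = first_num
    for c in range(len(centers)):
        if not center_mask[c]:
            continue
        member = atoms_xyz[assign == c]
        atoms = [AtomRecord("CA", "C", centers[c])]
        atoms += [AtomRecord(f"{name_prefix}{k + 1}", "C", pos)
                  for k, pos in enumerate(member)]
        out.append(ResidueUnit(chain_id, num, _ONE_TO_THREE[letters[c]], atoms))
        num += 1
    return out


def generate_glue_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Planted interface cavity + matching ligand-bound monomer template.

    The cavity is the interior of a dense double spherical shell of carbon
    pseudo-atoms grouped into ``pocket_size`` lining residues (inner shell;
    shared between the two chains by hemisphere) plus non-lining backing
    residues (outer shell).  The shell radii are derived from
    ``pocket_volume_target`` so the grid scan recovers the designed volume.
    The template monomer is the whole shell mapped by a rigid rotation and
    translation, optionally coordinate-noised and sequence-mutated, with a
    synthetic ligand (comp id LIG) at the pocket center; ``true_pose`` is
    that ligand in the target frame.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rc = (3.0 * spec.pocket_volume_target / (4.0 * math.pi)) ** (1.0 / 3.0)
    if rc < 2.0:
        raise GenerationError("pocket_volume_target too small to carve")
    # clearance of 2σ keeps the planted cavity above the volume filter after
    # the template's coordinate noise pushes shell atoms inward
    r_inner = rc + _CARBON_EXCLUSION + 2.0 * spec.noise_sigma
    r_outer = r_inner + 2.1

    def shell_atoms(radius: float) -> np.ndarray:
        n = int(math.ceil(4.0 * math.pi * radius ** 2 / 2.0))
        return radius * _fibonacci_sphere(n)

    inner_xyz = shell_atoms(r_inner)
    outer_xyz = shell_atoms(r_outer)
    inner_centers = r_inner * _fibonacci_sphere(spec.pocket_size)
    n_backing = max(spec.pocket_size, 8)
    outer_centers = r_outer * _fibonacci_sphere(n_backing)
    inner_letters = list(rng.choice(list(_AA20), spec.pocket_size))
    outer_letters = list(rng.choice(list(_AA20), n_backing))

    # hemispheres: chain A takes z<0 centers, chain B the rest
    res_a: list[ResidueUnit] = []
    res_b: list[ResidueUnit] = []
    for centers, letters, first, prefix, xyz in (
            (inner_centers, inner_letters, 101, "C", inner_xyz),
            (outer_centers, outer_letters, 201, "D", outer_xyz)):
        mask_a = centers[:, 2] < 0
        res_a += _shell_residues("A", first, xyz, centers, mask_a,
                                 letters, prefix)
        res_b += _shell_residues("B", first, xyz, centers, ~mask_a,
                                 letters, prefix)
    lining_keys = {r.key for r in res_a + res_b if 101 <= r.seq_position < 200}
    if sum(1 for r in res_a if r.seq_position < 200) < 1 \
            or sum(1 for r in res_b if r.seq_position < 200) < 1:
        raise GenerationError("degenerate hemisphere split")

    # interface strands, clear of the shell
    n = spec.n_residues_per_chain
    x0 = r_outer + 6.0
    letters_sa = "".join(rng.choice(list(_AA20), n))
    letters_sb = "".join(rng.choice(list(_AA20), n))
    y_b = [4.0 if i < spec.n_interface_contacts else 9.0 for i in range(n)]
    res_a = _strand_residues("A", n, [0.0] * n, letters_sa, x0=x0,
                             cb_sign=-1.0) + res_a
    res_b = _strand_residues("B", n, y_b, letters_sb, x0=x0,
                             cb_sign=+1.0) + res_b

    chain_a = ChainRecord("A", sorted(res_a, key=lambda r: r.seq_position),
                          "")
    chain_b = ChainRecord("B", sorted(res_b, key=lambda r: r.seq_position),
                          "")
    chain_a.sequence = "".join(one_letter(r.comp_id) for r in chain_a.residues)
    chain_b.sequence = "".join(one_letter(r.comp_id) for r in chain_b.residues)
    target = StructureModel(f"target_s{spec.rng_seed}", [chain_a, chain_b])
    truth_annotation = _brute_force_annotation(chain_a, chain_b)

    # synthetic ligand at the pocket center (target frame)
    n_lig = max(spec.ligand_n_atoms, 2)
    lig_xyz = np.vstack([[0.0, 0.0, 0.0],
                         2.2 * _fibonacci_sphere(n_lig - 1)])
    elements = ["C" if k % 2 == 0 else "O" for k in range(n_lig)]
    true_pose = [AtomRecord(f"L{k + 1}", elements[k], lig_xyz[k],
                            is_hetero=True) for k in range(n_lig)]

    # template: whole shell as one chain, rigidly moved, noised, mutated
    R = spec.rotation if spec.rotation is not None else _random_rotation(rng)
    R = np.asarray(R, dtype=float)
    if not (np.allclose(R @ R.T, np.eye(3), atol=1e-8)
            and np.linalg.det(R) > 0):
        raise GenerationError("rotation must be proper orthonormal")
    v = np.array([40.0, -15.0, 25.0])

    pocket_res = [r for r in chain_a.residues + chain_b.residues
                  if r.seq_position >= 101]
    pocket_res.sort(key=lambda r: (0 if 101 <= r.seq_position < 200 else 1,
                                   r.chain_id, r.seq_position))
    n_inner = sum(1 for r in pocket_res if r.seq_position < 200)
    n_mut = int(round(spec.mutation_fraction * n_inner))
    mutate_idx = set(rng.choice(n_inner, size=n_mut, replace=False).tolist()) \
        if n_mut else set()

    t_res = []
    for k, r in enumerate(pocket_res):
        comp = r.comp_id
        if k < n_inner and k in mutate_idx:
            old = one_letter(comp)
            choices = [a for a in _AA20 if a != old]
            comp = _ONE_TO_THREE[str(rng.choice(choices))]
        atoms = []
        for a in r.atoms:
            pos = R @ a.position + v
            if spec.noise_sigma > 0:
                pos = pos + rng.normal(0.0, spec.noise_sigma, 3)
            atoms.append(AtomRecord(a.name, a.element, pos))
        # inner residues first (1..n_inner) so signature order matches target
        t_res.append(ResidueUnit("T", k + 1 if k < n_inner else 501 + k,
                                 comp, atoms))
    t_seq = "".join(one_letter(r.comp_id) for r in t_res)
    ligand = LigandInstance("LIG", ("T", 900),
                            [AtomRecord(a.name, a.element,
                                        R @ a.position + v, is_hetero=True)
                             for a in true_pose])
    template = StructureModel(f"template_s{spec.rng_seed}",
                              [ChainRecord("T", t_res, t_seq)], [ligand])
    return ScenarioBundle(target, template, true_pose, truth_annotation,
                          lining_keys, R, v)


def generate_decoys(n: int, size_range: tuple[int, int] = (10, 30),
                    rng_seed: int = 0) -> list[PocketSignature]:
    """Random compact decoy pocket signatures (Cα–Cα ≥ 3.5 Å)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n):
        m = int(rng.integers(size_range[0], size_range[1] + 1))
        radius = 1.75 * (3.3 * m) ** (1.0 / 3.0)
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < m:
            cand = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(cand) > radius:
                continue
            if all(np.linalg.norm(cand - p) >= 3.5 for p in pts):
                pts.append(cand)
            attempts += 1
            if attempts > 4000:
                radius *= 1.1
                attempts = 0
        reps = np.array(pts)
        dirs = rng.normal(size=(m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        sides = reps + 1.5 * dirs
        aa = "".join(rng.choice(list(_AA20), m))
        out.append(PocketSignature(f"decoy{rng_seed}_{i}", reps, sides, aa,
                                   source_model=f"decoy{rng_seed}_{i}"))
    return out


def carved_cube_model(half_width: float = 4.5,
                      spacing: float = 1.0,
                      center: np.ndarray | None = None,
                      model_id: str = "cube") -> StructureModel:
    """Hollow cube of oxygen pseudo-atoms enclosing an empty interior.

    With the default geometry and ``probe_exclusion=CUBE_PROBE_EXCLUSION``
    the grid scan carves a 5×5×5 Å cavity (125 grid points at 1 Å spacing).
    Each face is one residue.
    """
    center = np.zeros(3) if center is None else np.asarray(center, float)
    grid = np.arange(-half_width, half_width + 1e-9, spacing)
    residues = []
    for fi, (axis, sign) in enumerate([(0, 1), (0, -1), (1, 1), (1, -1),
                                       (2, 1), (2, -1)]):
        atoms = []
        k = 0
        for u in grid:
            for w in grid:
                pos = np.zeros(3)
                pos[axis] = sign * half_width
                pos[(axis + 1) % 3] = u
                pos[(axis + 2) % 3] = w
                k += 1
                atoms.append(AtomRecord(f"O{k}", "O", center + pos))
        residues.append(ResidueUnit("W", fi + 1, "GLY", atoms))
    chain = ChainRecord("W", residues, "G" * 6)
    return StructureModel(model_id, [chain])
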