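"""Template-based molecular-glue screening.

Builds a library of ligand-bound template pockets (≥10 lining residues,
≥100 Å³), screens the interface-adjacent pockets of a target dimer against
it by pocket alignment, transfers each significant template's ligand into
the target frame through the alignment's rigid transform, and assigns a
predicted binding precision — the calibrated probability that the ligand
binds with at worst 10 μM affinity — from a (p-value, identical-residue
count) lookup table.

An optional sequence-identity filter removes templates whose parent chain
exceeds a cutoff identity against either target chain, mimicking homolog
exclusion in benchmarking.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .interface_mining import (DEFAULT_CONTACT_CUTOFF, InterfaceAnnotation)
from .pocket_alignment import (AlignmentParams, NullModel, AlignmentError,
                               PocketAlignmentResult, PocketSignature,
                               align_pockets, build_signature, pocket_pvalue)
from .pocket_detection import (MIN_POCKET_RESIDUES, MIN_POCKET_VOLUME,
                               PocketCavity, detect_cavities, filter_pockets,
                               tag_interface_adjacent)
from .structure_io import AtomRecord, StructureModel

__all__ = [
    "GridParams",
    "ScreeningParams",
    "TemplateRecord",
    "TemplateLibrary",
    "CalibrationTable",
    "GluePrediction",
    "TargetSummary",
    "build_library",
    "sequence_identity",
    "transfer_pose",
    "predict_precision",
    "screen_target",
    "summarize_target",
    "default_calibration_table",
    "predictions_frame",
    "save_library",
    "load_library",
]

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


@dataclass(frozen=True)
class GridParams:
    """Cavity-detection settings shared by library building and screening."""

    spacing: float = 1.0
    probe_exclusion: float = 1.4
    buried_threshold: int = 9
    lining_cutoff: float = 4.5

    def detect(self, model: StructureModel) -> list[PocketCavity]:
        return detect_cavities(model, spacing=self.spacing,
                               probe_exclusion=self.probe_exclusion,
                               buried_threshold=self.buried_threshold,
                               lining_cutoff=self.lining_cutoff)


@dataclass
class ScreeningParams:
    pvalue_threshold: float = 0.05
    seq_identity_cutoff: float | None = None   # benchmark grid: 0.30/0.40/0.50/0.70
    precision_threshold: float = 0.15
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    report_clashes: bool = True
    filter_clashes: bool = False
    clash_fraction_max: float = 0.2
    clash_distance: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue_threshold <= 1.0:
            raise ValueError("pvalue_threshold must lie in (0, 1]")
        if self.seq_identity_cutoff is not None \
                and not 0.0 < self.seq_identity_cutoff <= 1.0:
            raise ValueError("seq_identity_cutoff must lie in (0, 1]")
        if not 0.0 <= self.precision_threshold <= 1.0:
            raise ValueError("precision_threshold must lie in [0, 1]")


@dataclass
class TemplateRecord:
    template_id: str
    signature: PocketSignature
    ligand_comp_id: str
    ligand_atoms: list[AtomRecord]
    parent_sequences: tuple[str, ...]
    known_iap: bool = False


@dataclass
class TemplateLibrary:
    records: list[TemplateRecord]
    index: dict[str, list[int]] = field(default_factory=dict)
    known_iap_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.index:
            for k, rec in enumerate(self.records):
                self.index.setdefault(rec.ligand_comp_id, []).append(k)

    def __len__(self) -> int:
        return len(self.records)


class CalibrationError(ValueError):
    """Raised for a non-monotone precision calibration table."""


@dataclass
class CalibrationTable:
    """Binned (p-value, identical-residue count) → predicted precision.

    ``pvalue_bin_edges`` are ascending upper edges (most significant bin
    first); ``n_identical_bin_edges`` are ascending lower edges of the
    non-first bins.  Precision must not increase with the p-value bin and
    must not decrease with the identical-count bin.
    """

    pvalue_bin_edges: list[float]       # e.g. [1e-4, 1e-3, 1e-2, 0.05]
    n_identical_bin_edges: list[int]    # e.g. [4, 8] → bins <4, 4–7, ≥8
    precision: np.ndarray               # (n_id_bins, p_bins)

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        n_rows = len(self.n_identical_bin_edges) + 1
        if self.precision.shape != (n_rows, len(self.pvalue_bin_edges)):
            raise CalibrationError("precision matrix shape mismatch")
        if np.any((self.precision < 0) | (self.precision > 1)):
            raise CalibrationError("precision values must lie in [0, 1]")
        if np.any(np.diff(self.precision, axis=1) > 1e-12):
            raise CalibrationError("precision must be non-increasing with p-value")
        if np.any(np.diff(self.precision, axis=0) < -1e-12):
            raise CalibrationError("precision must be non-decreasing with "
                                   "identical-residue count")
        if list(self.pvalue_bin_edges) != sorted(self.pvalue_bin_edges):
            raise CalibrationError("p-value bin edges must ascend")

    def lookup(self, p_value: float, n_identical: int) -> float:
        if p_value > self.pvalue_bin_edges[-1]:
            return 0.0  # beyond the last supported bin: no support
        col = int(np.searchsorted(self.pvalue_bin_edges, p_value, side="left"))
        row = int(np.searchsorted(self.n_identical_bin_edges, n_identical,
                                  side="right"))
        return float(self.precision[row, col])

    @classmethod
    def from_json(cls, path: str) -> "CalibrationTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["pvalue_bin_edges"], d["n_identical_bin_edges"],
                   np.asarray(d["precision"]))


def default_calibration_table() -> CalibrationTable:
    """The packaged placeholder table (synthetic; see its JSON docstring).

    Users screening real structures should supply a table calibrated on
    their own retrospective benchmark.
    """
    return CalibrationTable.from_json(
        os.path.join(_DATA_DIR, "calibration_default.json"))


@dataclass
class GluePrediction:
    target_id: str
    pocket_id: str
    ligand_comp_id: str
    placed_atoms: list[AtomRecord]
    precision: float
    p_value: float
    n_identical: int
    template_id: str
    clash_fraction: float = 0.0
    known_iap: bool = False


@dataclass
class TargetSummary:
    target_id: str
    n_predictions: int
    avg_precision: float | None
    best_precision: float | None
    fraction_known_iap: float | None


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def _ligand_contact_residues(ligand_xyz: np.ndarray, model: StructureModel,
                             cutoff: float) -> set:
    tree = cKDTree(ligand_xyz)
    touched = set()
    for res in model.polymer_residues():
        if any(tree.query_ball_point(a.position, cutoff)
               for a in res.atoms):
            touched.add(res.key)
    return touched


def build_library(structures: list[StructureModel],
                  grid: GridParams | None = None,
                  min_residues: int = MIN_POCKET_RESIDUES,
                  min_volume: float = MIN_POCKET_VOLUME,
                  contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  known_iap: set[str] | None = None) -> TemplateLibrary:
    """Extract ligand-bound pockets from template structures.

    Each ligand is assigned to the detected cavity sharing the most
    ligand-contacting residues with its lining (≥1 required; ties go to the
    larger cavity), and the (pocket, ligand) pair survives only if the
    cavity passes the ≥10-residue / ≥100-Å³ library filter.
    """
    grid = grid or GridParams()
    known_iap = known_iap or set()
    records: list[TemplateRecord] = []
    for model in structures:
        if not model.ligands:
            continue
        cavities = grid.detect(model)
        if not cavities:
            continue
        for lig in model.ligands:
            touched = _ligand_contact_residues(lig.coords(), model,
                                               contact_cutoff)
            best = None
            for cav in cavities:
                overlap = len(cav.lining_residues & touched)
                if overlap < 1:
                    continue
                key = (overlap, cav.volume)
                if best is None or key > best[0]:
                    best = (key, cav)
            if best is None:
                continue
            cav = best[1]
            if len(cav.lining_residues) < min_residues or cav.volume < min_volume:
                continue
            sig = build_signature(cav, model)
            tid = f"{model.model_id}:{lig.comp_id}:{lig.instance_key[0]}" \
                  f"{lig.instance_key[1]}"
            records.append(TemplateRecord(
                template_id=tid,
                signature=sig,
                ligand_comp_id=lig.comp_id,
                ligand_atoms=list(lig.atoms),
                parent_sequences=tuple(c.sequence for c in model.chains),
                known_iap=lig.comp_id in known_iap))
    return TemplateLibrary(records, known_iap_set=set(known_iap))


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity in [0, 1], excluding terminal gaps.

    BLOSUM62 with affine gaps (open −11, extend −1); identity is the number
    of identical aligned positions over the alignment length between the
    first and last aligned pair.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    ia, ib = aln.indices  # (2, L) with -1 at gaps
    both = np.nonzero((ia >= 0) & (ib >= 0))[0]
    if both.size == 0:
        return 0.0
    lo, hi = both[0], both[-1]
    cols = range(lo, hi + 1)
    matches = sum(1 for c in cols
                  if ia[c] >= 0 and ib[c] >= 0 and seq_a[ia[c]] == seq_b[ib[c]])
    return matches / (hi - lo + 1)


# ---------------------------------------------------------------------------
# Pose transfer & precision
# ---------------------------------------------------------------------------

def transfer_pose(alignment: PocketAlignmentResult,
                  template_ligand: list[AtomRecord]) -> list[AtomRecord]:
    """Map a template ligand into the target frame via the rigid transform."""
    return [AtomRecord(a.name, a.element,
                       alignment.rotation @ a.position + alignment.translation,
                       is_hetero=True)
            for a in template_ligand]


def predict_precision(p_value: float, n_identical: int,
                      table: CalibrationTable) -> float:
    """Calibrated binding precision for one screened template."""
    return table.lookup(p_value, n_identical)


def _clash_fraction(placed: list[AtomRecord], protein_xyz: np.ndarray,
                    distance: float) -> float:
    tree = cKDTree(protein_xyz)
    n_clash = sum(1 for a in placed
                  if tree.query_ball_point(a.position, distance))
    return n_clash / len(placed)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def target_interface_pockets(model: StructureModel,
                             annotation: InterfaceAnnotation,
                             grid: GridParams | None = None,
                             min_residues: int = MIN_POCKET_RESIDUES,
                             min_volume: float = MIN_POCKET_VOLUME
                             ) -> list[PocketCavity]:
    """Filtered, interface-adjacent cavities of a target dimer."""
    grid = grid or GridParams()
    cavities = filter_pockets(grid.detect(model), min_residues, min_volume)
    tag_interface_adjacent(cavities, annotation)
    return [c for c in cavities if c.interface_adjacent]


def screen_target(model: StructureModel, annotation: InterfaceAnnotation,
                  library: TemplateLibrary, params: ScreeningParams,
                  null: NullModel, table: CalibrationTable,
                  grid: GridParams | None = None,
                  align_params: AlignmentParams | None = None
                  ) -> list[GluePrediction]:
    """Screen every interface-adjacent pocket of a dimer against the library.

    Emits at most one prediction per (pocket, ligand), keeping the highest
    precision (ties: lower p-value, then template order), with p ≤ the
    p-value threshold and precision ≥ the precision threshold.
    """
    if not annotation.valid_dimer:
        raise ValueError("screening requires a valid dimer")
    if not library.records:
        import warnings
        warnings.warn("empty template library: no predictions", stacklevel=2)
        return []
    align_params = align_params or AlignmentParams()
    pockets = target_interface_pockets(model, annotation, grid)
    protein_xyz = model.protein_coords()
    chain_seqs = [model.chain(cid).sequence for cid in annotation.chain_pair]

    best: dict[tuple[str, str], GluePrediction] = {}
    for cav in pockets:
        query = build_signature(cav, model)
        for k, rec in enumerate(library.records):
            if params.seq_identity_cutoff is not None:
                if any(sequence_identity(tseq, cseq) > params.seq_identity_cutoff
                       for tseq in rec.parent_sequences
                       for cseq in chain_seqs):
                    continue
            try:
                res = align_pockets(query, rec.signature, align_params)
            except AlignmentError:
                continue
            res.p_value = pocket_pvalue(res.score, len(query),
                                        len(rec.signature), null)
            if res.p_value > params.pvalue_threshold:
                continue
            placed = transfer_pose(res, rec.ligand_atoms)
            precision = predict_precision(res.p_value, res.n_identical, table)
            clash = (_clash_fraction(placed, protein_xyz, params.clash_distance)
                     if params.report_clashes else 0.0)
            pred = GluePrediction(
                target_id=model.model_id, pocket_id=cav.pocket_id,
                ligand_comp_id=rec.ligand_comp_id, placed_atoms=placed,
                precision=precision, p_value=res.p_value,
                n_identical=res.n_identical, template_id=rec.template_id,
                clash_fraction=clash, known_iap=rec.known_iap)
            key = (cav.pocket_id, rec.ligand_comp_id)
            cur = best.get(key)
            # ties on precision then p-value keep the earlier template
            if (cur is None or pred.precision > cur.precision
                    or (pred.precision == cur.precision
                        and pred.p_value < cur.p_value)):
                best[key] = pred
    out = [p for p in best.values() if p.precision >= params.precision_threshold]
    if params.filter_clashes:
        out = [p for p in out if p.clash_fraction <= params.clash_fraction_max]
    out.sort(key=lambda p: (-p.precision, p.p_value, p.pocket_id,
                            p.ligand_comp_id))
    return out


def summarize_target(predictions: list[GluePrediction],
                     params: ScreeningParams | None = None) -> TargetSummary:
    """Per-target roll-up of emitted predictions."""
    if not predictions:
        return TargetSummary("", 0, None, None, None)
    target_id = predictions[0].target_id
    precisions = [p.precision for p in predictions]
    by_ligand: dict[str, bool] = {}
    for p in predictions:
        by_ligand[p.ligand_comp_id] = by_ligand.get(p.ligand_comp_id, False) \
            or p.known_iap
    return TargetSummary(
        target_id=target_id,
        n_predictions=len(predictions),
        avg_precision=float(np.mean(precisions)),
        best_precision=float(np.max(precisions)),
        fraction_known_iap=sum(by_ligand.values()) / len(by_ligand))


def predictions_frame(predictions: list[GluePrediction]) -> pd.DataFrame:
    """TSV-ready table of predictions."""
    return pd.DataFrame(
        [{"target_id": p.target_id, "pocket_id": p.pocket_id,
          "ligand": p.ligand_comp_id, "precision": p.precision,
          "p_value": p.p_value, "n_identical": p.n_identical,
          "template_id": p.template_id, "clash_fraction": p.clash_fraction,
          "known_iap": p.known_iap} for p in predictions],
        columns=["target_id", "pocket_id", "ligand", "precision", "p_value",
                 "n_identical", "template_id", "clash_fraction", "known_iap"])


# ---------------------------------------------------------------------------
# Library serialization (JSON index + per-template PDB fragments)
# ---------------------------------------------------------------------------

def save_library(library: TemplateLibrary, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    index = []
    for k, rec in enumerate(library.records):
        sig = rec.signature
        index.append({
            "template_id": rec.template_id,
            "ligand_comp_id": rec.ligand_comp_id,
            "known_iap": rec.known_iap,
            "parent_sequences": list(rec.parent_sequences),
            "signature": {
                "pocket_id": sig.pocket_id,
                "rep_points": sig.rep_points.tolist(),
                "side_points": sig.side_points.tolist(),
                "aa": sig.aa,
                "source_model": sig.source_model,
            },
            "ligand_atoms": [[a.name, a.element, *map(float, a.position)]
                             for a in rec.ligand_atoms],
            "fragment": f"template_{k:05d}.pdb",
        })
        _write_fragment(rec, os.path.join(directory, f"template_{k:05d}.pdb"))
    with open(os.path.join(directory, "index.json"), "w") as fh:
        json.dump({"records": index,
                   "known_iap_set": sorted(library.known_iap_set)}, fh)


def _write_fragment(rec: TemplateRecord, path: str) -> None:
    with open(path, "w") as fh:
        serial = 0
        for i, (pt, aa) in enumerate(zip(rec.signature.rep_points,
                                         rec.signature.aa)):
            serial += 1
            fh.write(f"ATOM  {serial:>5}  CA  ALA P{i + 1:>4}    "
                     f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}"
                     f"{1.0:6.2f}{0.0:6.2f}           C\n")
        for a in rec.ligand_atoms:
            serial += 1
            x, y, z = a.position
            fh.write(f"HETATM{serial:>5} {a.name:<4} {rec.ligand_comp_id:>3} "
                     f"L 901    {x:8.3f}{y:8.3f}{z:8.3f}"
                     f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}\n")
        fh.write("END\n")


def load_library(directory: str) -> TemplateLibrary:
    with open(os.path.join(directory, "index.json")) as fh:
        d = json.load(fh)
    records = []
    for e in d["records"]:
        s = e["signature"]
        sig = PocketSignature(
            pocket_id=s["pocket_id"],
            rep_points=np.asarray(s["rep_points"]),
            side_points=np.asarray(s["side_points"]),
            aa=s["aa"], source_model=s["source_model"],
            parent_sequences=tuple(e["parent_sequences"]))
        atoms = [AtomRecord(n, el, np.array([x, y, z]), is_hetero=True)
                 for n, el, x, y, z in e["ligand_atoms"]]
        records.append(TemplateRecord(e["template_id"], sig,
                                      e["ligand_comp_id"], atoms,
                                      tuple(e["parent_sequences"]),
                                      e["known_iap"]))
    return TemplateLibrary(records, known_iap_set=set(d["known_iap_set"]))
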