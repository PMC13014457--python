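"""Benchmarking predictions against native interface-adjacent ligands.

A target is *recovered* when some prediction shares a chemical component id
with a native interface-adjacent ligand; pose quality is the deviation
between centers of mass (unweighted over heavy atoms) of the placed and
native poses, minimized over native copies.  Aggregation mirrors a
benchmark grid over (sequence-identity cutoff, p-value threshold)
conditions: recall, mean matched precision and mean COM deviation over
recovered targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glue_screening import GluePrediction
from .structure_io import AtomRecord

__all__ = [
    "NativeAnnotation",
    "BenchmarkRow",
    "TargetEvaluation",
    "center_of_mass",
    "evaluate_target",
    "benchmark_table",
    "cumulative_precision_curve",
]


@dataclass
class NativeAnnotation:
    """Ground-truth IAP ligands of one benchmark target."""

    target_id: str
    native_ligands: list[tuple[str, list[AtomRecord], bool]]  # (comp, atoms, qualifies)


@dataclass
class TargetEvaluation:
    target_id: str
    recovered: bool
    matched_precision: float | None
    com_deviation: float | None


@dataclass
class BenchmarkRow:
    condition: tuple[float | None, float]   # (seq_identity_cutoff, pvalue_threshold)
    recall: float
    avg_precision_per_native: float | None
    avg_com_rmsd: float | None
    n_targets: int


def center_of_mass(atoms: list[AtomRecord]) -> np.ndarray:
    """Unweighted mean of heavy-atom positions."""
    if not atoms:
        raise ValueError("center of mass of zero atoms is undefined")
    return np.mean([a.position for a in atoms], axis=0)


def evaluate_target(predictions: list[GluePrediction],
                    native: NativeAnnotation) -> TargetEvaluation:
    """Chemical-identity recall and best COM deviation for one target.

    ``com_deviation`` is the minimum COM distance over all (matching
    prediction, native copy) pairs; ``matched_precision`` is the precision
    of the prediction achieving it (ties: highest precision).
    """
    best: tuple[float, float] | None = None  # (deviation, -precision)
    for pred in predictions:
        for comp, atoms, _qual in native.native_ligands:
            if pred.ligand_comp_id != comp:
                continue
            dev = float(np.linalg.norm(center_of_mass(pred.placed_atoms)
                                       - center_of_mass(atoms)))
            cand = (dev, -pred.precision)
            if best is None or cand < best:
                best = cand
    if best is None:
        return TargetEvaluation(native.target_id, False, None, None)
    return TargetEvaluation(native.target_id, True, -best[1], best[0])


def benchmark_table(per_condition: dict[tuple[float | None, float],
                                        list[TargetEvaluation]]
                    ) -> list[BenchmarkRow]:
    """Aggregate per-target evaluations into one row per condition."""
    rows = []
    for condition, evals in per_condition.items():
        n = len(evals)
        rec = [e for e in evals if e.recovered]
        rows.append(BenchmarkRow(
            condition=condition,
            recall=len(rec) / n if n else 0.0,
            avg_precision_per_native=(
                float(np.mean([e.matched_precision for e in rec]))
                if rec else None),
            avg_com_rmsd=(float(np.mean([e.com_deviation for e in rec]))
                          if rec else None),
            n_targets=n))
    return rows


def benchmark_frame(rows: list[BenchmarkRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"seq_identity_cutoff": r.condition[0],
          "pvalue_threshold": r.condition[1],
          "recall": r.recall,
          "avg_precision_per_native": r.avg_precision_per_native,
          "avg_com_rmsd": r.avg_com_rmsd,
          "n_targets": r.n_targets} for r in rows])


def cumulative_precision_curve(predictions: list[GluePrediction]
                               ) -> list[tuple[float, float]]:
    """Non-increasing step curve: fraction of predictions with precision ≥ level.

    Levels are the distinct predicted precisions; the fraction at the lowest
    level is 1.0.
    """
    if not predictions:
        raise ValueError("need ≥1 prediction for a cumulative curve")
    precisions = np.array(sorted(p.precision for p in predictions))
    levels = np.unique(precisions)
    n = len(precisions)
    return [(float(lv), float((precisions >= lv).sum()) / n) for lv in levels]
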