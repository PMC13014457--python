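"""Library construction, identity filter, pose transfer, precision, screening."""

import numpy as np
import pytest

from gluescreen import (AlignmentParams, ScenarioSpec, ScreeningParams,
                        align_pockets, build_library, generate_decoys,
                        generate_glue_scenario, load_library, save_library,
                        screen_target, sequence_identity, summarize_target,
                        transfer_pose)
from gluescreen.evaluation import center_of_mass
from gluescreen.glue_screening import (CalibrationError, CalibrationTable,
                                       GluePrediction, TemplateLibrary,
                                       TemplateRecord, predict_precision)
from gluescreen.structure_io import AtomRecord
from conftest import rigid_copy


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def test_library_from_planted_template(exact_bundle):
    lib = build_library([exact_bundle.template])
    assert len(lib) == 1
    rec = lib.records[0]
    assert rec.ligand_comp_id == "LIG"
    assert len(rec.signature) >= 10
    assert lib.index == {"LIG": [0]}


def test_library_rejects_small_pocket():
    bundle = generate_glue_scenario(ScenarioSpec(pocket_size=9, rng_seed=6))
    lib = build_library([bundle.template])
    assert len(lib) == 0


def test_library_indexes_duplicate_comp_ids():
    b1 = generate_glue_scenario(ScenarioSpec(rng_seed=30))
    b2 = generate_glue_scenario(ScenarioSpec(rng_seed=31))
    lib = build_library([b1.template, b2.template])
    assert len(lib.index["LIG"]) == 2


def test_library_roundtrip(tmp_path, exact_bundle):
    lib = build_library([exact_bundle.template], known_iap={"LIG"})
    save_library(lib, str(tmp_path / "lib"))
    loaded = load_library(str(tmp_path / "lib"))
    assert len(loaded) == 1
    assert loaded.records[0].known_iap
    assert np.allclose(loaded.records[0].signature.rep_points,
                       lib.records[0].signature.rep_points)
    assert loaded.records[0].signature.aa == lib.records[0].signature.aa


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def test_sequence_identity_values():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"[:30]
    assert sequence_identity(seq, seq) == pytest.approx(1.0)
    ten = "ACDEFGHIKL"
    mutated = "ACWEFGHVKM"  # 3 substitutions, no gaps
    assert sum(a != b for a, b in zip(ten, mutated)) == 3
    assert sequence_identity(ten, mutated) == pytest.approx(0.7)
    assert sequence_identity("AAAA", "GGGG") == 0.0
    with pytest.raises(ValueError):
        sequence_identity("", "ACD")


# ---------------------------------------------------------------------------
# Pose transfer
# ---------------------------------------------------------------------------

def make_ligand(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return [AtomRecord(f"C{i}", "C", rng.uniform(-2, 2, 3), is_hetero=True)
            for i in range(n)]


def test_transfer_pose_identity_and_known_transform(decoy_signatures):
    sig = decoy_signatures[3]
    identity = align_pockets(sig, sig)
    ligand = make_ligand()
    placed = transfer_pose(identity, ligand)
    assert np.allclose([a.position for a in placed],
                       [a.position for a in ligand], atol=1e-9)

    moved, R, v = rigid_copy(sig, rng_seed=17)
    res = align_pockets(moved, sig)  # transform maps sig frame -> moved frame
    placed = transfer_pose(res, ligand)
    expected = [R @ a.position + v for a in ligand]
    assert np.abs(np.array([a.position for a in placed])
                  - np.array(expected)).max() < 1e-3
    # rigidity: pairwise distances preserved
    orig = np.array([a.position for a in ligand])
    new = np.array([a.position for a in placed])
    d0 = np.linalg.norm(orig[:, None] - orig[None, :], axis=2)
    d1 = np.linalg.norm(new[:, None] - new[None, :], axis=2)
    assert np.abs(d0 - d1).max() < 1e-6


# ---------------------------------------------------------------------------
# Calibration table
# ---------------------------------------------------------------------------

def test_precision_lookup_and_clamps(calibration_table):
    assert predict_precision(0.5, 12, calibration_table) == 0.0  # beyond last bin
    assert predict_precision(1e-4, 8, calibration_table) == \
        calibration_table.precision[2, 0]
    assert predict_precision(1e-6, 0, calibration_table) == \
        calibration_table.precision[0, 0]  # clamps to most significant bin
    # monotone in p at fixed n_identical
    ps = [1e-5, 1e-4, 1e-3, 1e-2, 0.05]
    vals = [predict_precision(p, 5, calibration_table) for p in ps]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_malformed_table_rejected():
    with pytest.raises(CalibrationError):
        CalibrationTable([1e-3, 1e-2], [4],
                         np.array([[0.1, 0.2], [0.3, 0.2]]))  # rises with p
    with pytest.raises(CalibrationError):
        CalibrationTable([1e-3, 1e-2], [4],
                         np.array([[0.3, 0.2], [0.1, 0.05]]))  # falls with n_id


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def test_screen_recovers_planted_ligand(exact_bundle, null_model,
                                        calibration_table):
    b = exact_bundle
    lib = build_library([b.template])
    preds = screen_target(b.target_dimer, b.truth_annotation, lib,
                          ScreeningParams(), null_model, calibration_table)
    assert len(preds) == 1
    p = preds[0]
    assert p.ligand_comp_id == "LIG"
    assert p.p_value <= 0.05
    assert p.precision >= 0.15
    dev = np.linalg.norm(center_of_mass(p.placed_atoms)
                         - center_of_mass(b.true_pose))
    assert dev < 0.5
    assert p.clash_fraction == 0.0


def test_identity_filter_excludes_homologous_template(exact_bundle, null_model,
                                                      calibration_table):
    b = exact_bundle
    lib = build_library([b.template])
    tseq = lib.records[0].parent_sequences[0]
    idents = [sequence_identity(tseq, c.sequence)
              for c in b.target_dimer.chains]
    assert max(idents) > 0.3  # the template pocket is carved from the target
    preds = screen_target(b.target_dimer, b.truth_annotation, lib,
                          ScreeningParams(seq_identity_cutoff=0.3),
                          null_model, calibration_table)
    assert preds == []


def decoy_library(n, seed):
    sigs = generate_decoys(n, size_range=(10, 20), rng_seed=seed)
    records = [TemplateRecord(f"decoy{k}", s, f"D{k:02d}", make_ligand(seed=k),
                              ("ACDEFGHIKLMNPQRSTVWY",))
               for k, s in enumerate(sigs)]
    return TemplateLibrary(records)


def test_decoy_library_rarely_yields_predictions(exact_bundle, null_model,
                                                 calibration_table):
    """Null behavior: unrelated template pockets almost never pass screening."""
    b = exact_bundle
    zero_runs = 0
    for seed in range(10):
        lib = decoy_library(10, seed=200 + seed)
        preds = screen_target(b.target_dimer, b.truth_annotation, lib,
                              ScreeningParams(), null_model, calibration_table,
                              align_params=AlignmentParams(rng_seed=seed))
        zero_runs += not preds
    assert zero_runs >= 9


def test_predictions_respect_thresholds_and_dedup(exact_bundle, null_model,
                                                  calibration_table):
    b = exact_bundle
    lib = build_library([b.template, b.template])  # duplicate template
    params = ScreeningParams()
    preds = screen_target(b.target_dimer, b.truth_annotation, lib, params,
                          null_model, calibration_table)
    keys = [(p.pocket_id, p.ligand_comp_id) for p in preds]
    assert len(keys) == len(set(keys))  # dedup per (pocket, ligand)
    for p in preds:
        assert p.p_value <= params.pvalue_threshold
        assert p.precision >= params.precision_threshold
        assert len(p.placed_atoms) == len(lib.records[0].ligand_atoms)


def test_empty_library_warns(exact_bundle, null_model, calibration_table):
    with pytest.warns(UserWarning):
        out = screen_target(exact_bundle.target_dimer,
                            exact_bundle.truth_annotation,
                            TemplateLibrary([]), ScreeningParams(),
                            null_model, calibration_table)
    assert out == []


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def fake_prediction(comp, precision, known_iap=False):
    return GluePrediction("t", "t:pocket0", comp, make_ligand(3), precision,
                          1e-3, 5, "tmpl", 0.0, known_iap)


def test_summarize_target_arithmetic():
    empty = summarize_target([])
    assert empty.n_predictions == 0 and empty.avg_precision is None

    preds = [fake_prediction("AAA", 0.15, known_iap=True),
             fake_prediction("BBB", 0.25)]
    s = summarize_target(preds)
    assert s.n_predictions == 2
    assert s.avg_precision == pytest.approx(0.20)
    assert s.best_precision == pytest.approx(0.25)
    assert s.fraction_known_iap == pytest.approx(0.5)
    assert s.best_precision >= s.avg_precision
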