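"""Alignment fixed points, rigid recovery, matching oracle, significance."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from gluescreen import (AlignmentParams, NullModel, align_pockets,
                        build_signature, detect_cavities, filter_pockets,
                        fit_null, generate_decoys, pocket_pvalue)
from gluescreen.pocket_alignment import (AlignmentError, DegeneratePocketError,
                                         PocketSignature, kabsch)
from conftest import rigid_copy


def test_self_alignment_is_fixed_point(decoy_signatures):
    for sig in decoy_signatures[:5]:
        res = align_pockets(sig, sig)
        assert res.score == pytest.approx(1.0, abs=1e-6)
        assert res.n_aligned == len(sig)
        assert res.n_identical == len(sig)
        assert res.correspondences == [(i, i) for i in range(len(sig))]
        assert np.allclose(res.rotation, np.eye(3), atol=1e-6)


def test_known_rigid_transform_recovery(decoy_signatures):
    for k, sig in enumerate(decoy_signatures[:5]):
        moved, R, v = rigid_copy(sig, rng_seed=100 + k)
        res = align_pockets(sig, moved)
        assert res.n_aligned == len(sig)
        # matched-point RMSD after superposition
        t_pts = moved.rep_points @ res.rotation.T + res.translation
        d = [np.linalg.norm(sig.rep_points[i] - t_pts[j])
             for i, j in res.correspondences]
        assert np.sqrt(np.mean(np.square(d))) < 0.1
        # recovered transform undoes the applied one
        assert np.abs(res.rotation - R.T).max() < 1e-3
        assert abs(res.score - 1.0) < 1e-4


def test_transform_is_proper_rigid(decoy_signatures):
    a, b = decoy_signatures[0], decoy_signatures[1]
    res = align_pockets(a, b)
    R = res.rotation
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-6)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-6)
    assert res.n_identical <= res.n_aligned <= min(len(a), len(b))
    qs = [i for i, _ in res.correspondences]
    ts = [j for _, j in res.correspondences]
    assert len(set(qs)) == len(qs) and len(set(ts)) == len(ts)


def test_score_symmetry(decoy_signatures):
    for a, b in zip(decoy_signatures[:4], decoy_signatures[4:8]):
        fwd = align_pockets(a, b)
        rev = align_pockets(b, a)
        assert fwd.score == pytest.approx(rev.score, abs=1e-4)
        assert sorted((j, i) for i, j in fwd.correspondences) == \
            sorted(rev.correspondences)
        # transforms are mutual inverses
        assert np.allclose(fwd.rotation, rev.rotation.T, atol=1e-6)


def test_mutated_copy_bookkeeping(decoy_signatures):
    sig = decoy_signatures[2]
    n_mut = max(1, int(0.3 * len(sig)))
    rng = np.random.default_rng(0)
    idx = rng.choice(len(sig), n_mut, replace=False)
    aa = list(sig.aa)
    for i in idx:
        aa[i] = "W" if aa[i] != "W" else "F"
    mutated = PocketSignature(sig.pocket_id + "_mut", sig.rep_points.copy(),
                              sig.side_points.copy(), "".join(aa))
    res = align_pockets(sig, mutated)
    assert res.correspondences == [(i, i) for i in range(len(sig))]
    assert res.n_identical == len(sig) - n_mut


def test_matching_is_optimal_assignment_on_small_pockets(small_decoys):
    """Matching oracle: on pockets of size ≤ 8 the emitted correspondence
    maximizes ΣS over one-to-one maps (greedy alone can be suboptimal here,
    which is why the matcher falls back to the optimal assignment below
    size 9; the oracle is an independent linear_sum_assignment call)."""
    from gluescreen.pocket_alignment import _score_matrix
    params = AlignmentParams()
    for a in small_decoys[:6]:
        for b in small_decoys[6:12]:
            res = align_pockets(a, b, params)
            chem = (a.chem_class[:, None] == b.chem_class[None, :]).astype(float)
            t_pts = b.rep_points @ res.rotation.T + res.translation
            S, D = _score_matrix(a.rep_points, t_pts, chem, params)
            masked = np.where(D <= 2 * params.d0, S, 0.0)
            rows, cols = linear_sum_assignment(masked, maximize=True)
            opt_total = float(masked[rows, cols].sum())
            got_total = sum(S[i, j] for i, j in res.correspondences)
            assert got_total == pytest.approx(opt_total, abs=1e-9)


def test_collinear_pocket_rejected():
    pts = np.stack([np.arange(5, dtype=float) * 4.0,
                    np.zeros(5), np.zeros(5)], axis=1)
    sig = PocketSignature("line", pts, pts, "AAAAA")
    with pytest.raises(AlignmentError):
        align_pockets(sig, sig)


def test_too_small_signature_rejected():
    with pytest.raises(DegeneratePocketError):
        PocketSignature("tiny", np.zeros((2, 3)), np.zeros((2, 3)), "AA")


def test_build_signature_geometry(exact_bundle):
    model = exact_bundle.target_dimer
    cav = filter_pockets(detect_cavities(model))[0]
    sig = build_signature(cav, model)
    assert len(sig) == len(cav.lining_residues)
    assert set(sig.residue_keys) == cav.lining_residues
    # rigid rotation of the model rotates the signature points exactly
    from conftest import rigid_copy
    moved, R, v = rigid_copy(sig, rng_seed=4)
    assert np.allclose(moved.rep_points, sig.rep_points @ R.T + v, atol=1e-6)


def test_glycine_like_side_point_falls_back_to_ca():
    from gluescreen.pocket_detection import PocketCavity
    from gluescreen.structure_io import (AtomRecord, ChainRecord, ResidueUnit,
                                         StructureModel)
    residues = [ResidueUnit("A", i + 1, "GLY",
                            [AtomRecord("CA", "C",
                                        np.array([4.0 * i, float(i % 2), 0.0]))])
                for i in range(4)]
    model = StructureModel("gly", [ChainRecord("A", residues, "GGGG")])
    cav = PocketCavity("p", np.zeros((1, 3)), 1.0, {r.key for r in residues})
    sig = build_signature(cav, model)
    assert np.allclose(sig.rep_points, sig.side_points)


def test_kabsch_recovers_exact_transform():
    rng = np.random.default_rng(8)
    P = rng.uniform(-10, 10, (12, 3))
    from gluescreen.synthetic_fixtures import _random_rotation
    R = _random_rotation(rng)
    t = rng.uniform(-5, 5, 3)
    Rk, tk = kabsch(P, P @ R.T + t)
    assert np.abs(Rk - R).max() < 1e-9
    assert np.abs(tk - t).max() < 1e-9


# ---------------------------------------------------------------------------
# Significance model
# ---------------------------------------------------------------------------

def test_pvalue_closed_form_and_monotonicity(null_model):
    n = 15
    p_at_mu = pocket_pvalue(null_model.mu(n), n, 40, null_model)
    assert p_at_mu == pytest.approx(1.0 - np.exp(-1.0), abs=1e-9)
    scores = np.linspace(0.0, 1.0, 21)
    ps = [pocket_pvalue(s, n, n, null_model) for s in scores]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
    assert ps[-1] < 0.01  # perfect score is highly significant


def test_pvalue_clamps_out_of_range_sizes(null_model):
    with pytest.warns(UserWarning):
        p = pocket_pvalue(0.5, 4, 4, null_model)
    assert 0.0 < p <= 1.0


def test_fit_null_deterministic_and_positive_scale():
    decoys = generate_decoys(25, size_range=(10, 18), rng_seed=3)
    n1 = fit_null(decoys, n_pairs=60, rng_seed=5)
    n2 = fit_null(decoys, n_pairs=60, rng_seed=5)
    assert n1 == n2
    for size in (10, 20, 40):
        assert n1.sigma(size) > 0.0
    with pytest.raises(ValueError):
        fit_null(decoys[:10], n_pairs=10, rng_seed=0)


def test_self_alignment_outranks_decoy_pairs(decoy_signatures, null_model):
    sig = decoy_signatures[0]
    self_p = pocket_pvalue(align_pockets(sig, sig).score, len(sig), len(sig),
                           null_model)
    rng = np.random.default_rng(21)
    worse = 0
    for _ in range(50):
        i, j = rng.choice(len(decoy_signatures), 2, replace=False)
        a, b = decoy_signatures[i], decoy_signatures[j]
        p = pocket_pvalue(align_pockets(a, b).score, len(a), len(b), null_model)
        worse += p > self_p
    assert worse >= 49  # below ~the 99th percentile of decoy p-values


def test_null_roundtrip_json(tmp_path, null_model):
    path = tmp_path / "null.json"
    null_model.to_json(path)
    assert NullModel.from_json(path) == null_model
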