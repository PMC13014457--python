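"""Path fingerprints and Tanimoto leader clustering."""

import numpy as np
import pytest

from gluescreen import cluster_at_threshold, ligand_fingerprint, tanimoto
from gluescreen.ligand_clustering import (FingerprintBits, MolGraph,
                                          graph_from_ligand, graph_from_rdkit)
from gluescreen.structure_io import AtomRecord, LigandInstance


def bitset(positions, n_bits=16, comp="x"):
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(positions)] = True
    return FingerprintBits(comp, bits)


def test_single_atom_sets_one_bit():
    fp = ligand_fingerprint(MolGraph(["C"]), comp_id="C1")
    assert int(fp.bits.sum()) == 1


def test_fingerprint_deterministic_and_graph_sensitive():
    ethane = MolGraph(["C", "C"], [(0, 1, 1)])
    ethanol = MolGraph(["C", "C", "O"], [(0, 1, 1), (1, 2, 1)])
    f1 = ligand_fingerprint(ethane)
    f2 = ligand_fingerprint(ethane)
    f3 = ligand_fingerprint(ethanol)
    assert np.array_equal(f1.bits, f2.bits)
    assert not np.array_equal(f1.bits, f3.bits)
    assert f3.bits.sum() >= 1


def test_rdkit_graphs_match_hand_built():
    rdkit_chem = pytest.importorskip("rdkit.Chem")
    mol = rdkit_chem.MolFromSmiles("CCO")
    via_rdkit = ligand_fingerprint(graph_from_rdkit(mol))
    by_hand = ligand_fingerprint(MolGraph(["C", "C", "O"],
                                          [(0, 1, 1), (1, 2, 1)]))
    assert np.array_equal(via_rdkit.bits, by_hand.bits)


def test_bond_perception_from_coordinates():
    atoms = [AtomRecord("C1", "C", np.array([0.0, 0.0, 0.0]), is_hetero=True),
             AtomRecord("C2", "C", np.array([1.5, 0.0, 0.0]), is_hetero=True),
             AtomRecord("O1", "O", np.array([2.9, 0.3, 0.0]), is_hetero=True)]
    graph = graph_from_ligand(LigandInstance("ETO", ("A", 1), atoms))
    assert sorted((i, j) for i, j, _ in graph.bonds) == [(0, 1), (1, 2)]


def test_tanimoto_arithmetic():
    assert tanimoto(bitset({1, 2, 3}), bitset({1, 2, 3})) == 1.0
    assert tanimoto(bitset({0, 1}), bitset({2, 3})) == 0.0
    assert tanimoto(bitset({1, 2, 3}), bitset({2, 3, 4})) == pytest.approx(0.5)
    assert tanimoto(bitset(set()), bitset(set())) == 1.0
    with pytest.raises(ValueError):
        tanimoto(bitset({1}), bitset({1}, n_bits=32))


def brute_force_leader(fps, threshold):
    """Independent re-implementation of leader clustering for the oracle."""
    n = len(fps)
    sim = [[tanimoto(fps[i], fps[j]) for j in range(n)] for i in range(n)]
    unassigned = list(range(n))
    out = []
    while unassigned:
        best, best_count = None, -1
        for i in unassigned:
            count = sum(1 for j in unassigned if sim[i][j] >= threshold)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in unassigned if sim[best][j] >= threshold]
        out.append((fps[best].ligand_comp_id,
                    [fps[j].ligand_comp_id for j in members]))
        unassigned = [j for j in unassigned if j not in members]
    return out


def test_cluster_degenerate_cases():
    same = [bitset({1, 2, 3}, comp=f"m{i}") for i in range(5)]
    clusters = cluster_at_threshold(same, 0.8)
    assert len(clusters) == 1 and len(clusters[0].members) == 5

    apart = [bitset({i}, comp=f"s{i}") for i in range(4)]
    clusters = cluster_at_threshold(apart, 0.8)
    assert len(clusters) == 4
    assert all(len(c.members) == 1 for c in clusters)


def test_cluster_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    fps = [bitset(set(rng.choice(24, rng.integers(4, 10), replace=False)),
                  n_bits=24, comp=f"L{i}") for i in range(8)]
    got = cluster_at_threshold(fps, 0.5)
    expected = brute_force_leader(fps, 0.5)
    assert sorted((c.centroid, sorted(c.members)) for c in got) == \
        sorted((c, sorted(m)) for c, m in expected)


@pytest.mark.parametrize("threshold", [0.3, 0.5, 0.8])
def test_partition_and_centroid_radius(threshold):
    rng = np.random.default_rng(int(threshold * 100))
    fps = [bitset(set(rng.choice(32, rng.integers(5, 12), replace=False)),
                  n_bits=32, comp=f"L{i}") for i in range(15)]
    clusters = cluster_at_threshold(fps, threshold)
    all_members = [m for c in clusters for m in c.members]
    assert sorted(all_members) == sorted(f.ligand_comp_id for f in fps)
    by_id = {f.ligand_comp_id: f for f in fps}
    for c in clusters:
        assert c.centroid in c.members
        for m in c.members:
            assert tanimoto(by_id[c.centroid], by_id[m]) >= threshold
    sizes = [len(c.members) for c in clusters]
    assert sizes == sorted(sizes, reverse=True)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 31)), st.sets(st.integers(0, 31)))
    def test_tanimoto_is_a_bounded_symmetric_similarity(sa, sb):
        a, b = bitset(sa, n_bits=32), bitset(sb, n_bits=32)
        t = tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(b, a)
        assert tanimoto(a, a) == 1.0
        if sa and sb and not (sa & sb):
            assert t == 0.0
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_threshold_monotonicity():
    rng = np.random.default_rng(4)
    fps = [bitset(set(rng.choice(32, 8, replace=False)), n_bits=32,
                  comp=f"L{i}") for i in range(12)]
    counts = [len(cluster_at_threshold(fps, t)) for t in (0.2, 0.5, 0.8, 1.0)]
    assert counts == sorted(counts)
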