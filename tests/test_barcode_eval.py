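import math

import numpy as np
import pytest

from plastobarcode.barcode_eval import (
    DistanceMatrix,
    SitePairCounts,
    classify_site_pairs,
    distance_matrix,
    evaluate_combinations,
    intra_inter_summary,
    isr_nearest_neighbor,
    isr_tree_monophyly,
    k2p_distance,
)
from plastobarcode.seq_io import LabelledAlignment, SequenceRecord


def _aln(pairs):
    return LabelledAlignment([SequenceRecord(sid, seq, sp) for sid, seq, sp in pairs])


# ------------------------------------------------------------------ site pairs

def test_classify_site_pairs_cases():
    assert classify_site_pairs("ACGT", "GCGT") == SitePairCounts(4, 1, 0)
    assert classify_site_pairs("ACGT", "TCGT") == SitePairCounts(4, 0, 1)
    # gap column dropped under pairwise masking; T<->A is a transversion
    assert classify_site_pairs("AC-T", "ACGA") == SitePairCounts(3, 0, 1)


def test_classify_site_pairs_complete_masking_needs_columns():
    with pytest.raises(ValueError, match="usable"):
        classify_site_pairs("ACGT", "ACGA", masking="complete")
    counts = classify_site_pairs("ACGT", "ACGA", masking="complete", usable=[0, 1, 2])
    assert counts == SitePairCounts(3, 0, 0)


# ------------------------------------------------------------------------- k2p

def test_k2p_closed_form_against_sympy():
    import sympy as sp

    P, Q = sp.Rational(10, 100), sp.Rational(5, 100)
    oracle = float(sp.N(-sp.Rational(1, 2) * sp.log((1 - 2 * P - Q) * sp.sqrt(1 - 2 * Q)), 30))
    assert k2p_distance(SitePairCounts(100, 10, 5)) == pytest.approx(oracle, abs=1e-12)


def test_k2p_identity_and_saturation():
    assert k2p_distance(SitePairCounts(100, 0, 0)) == 0.0
    assert k2p_distance(SitePairCounts(0, 0, 0)) is None
    assert k2p_distance(SitePairCounts(100, 48, 4)) is None  # 1-2P-Q <= 0
    assert k2p_distance(SitePairCounts(100, 0, 50)) is None  # 1-2Q <= 0


def test_k2p_jukes_cantor_family():
    """With P = x, Q = 2x the K2P form collapses to -3/4 ln(1 - 4x)."""
    for x in np.arange(0.01, 0.201, 0.01):
        n = 10000
        counts = SitePairCounts(n, int(round(x * n)), int(round(2 * x * n)))
        x_eff = counts.ts / n
        expected = -0.75 * math.log(1 - 4 * x_eff)
        assert k2p_distance(counts) == pytest.approx(expected, abs=1e-12)


def test_k2p_one_parameter_limits():
    for p in (0.02, 0.1, 0.2):
        assert k2p_distance(SitePairCounts(1000, int(1000 * p), 0)) == pytest.approx(
            -0.5 * math.log(1 - 2 * p), abs=1e-12
        )
    for q in (0.02, 0.1, 0.2):
        # P = 0 limit: d = -1/2 ln((1-Q) sqrt(1-2Q))
        assert k2p_distance(SitePairCounts(1000, 0, int(1000 * q))) == pytest.approx(
            -0.5 * math.log((1 - q) * math.sqrt(1 - 2 * q)), abs=1e-12
        )


def test_k2p_dominates_p_distance():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = 1000
        ts = int(rng.integers(0, 200))
        tv = int(rng.integers(0, 200))
        d = k2p_distance(SitePairCounts(n, ts, tv))
        p_dist = (ts + tv) / n
        assert d is not None and d >= p_dist - 1e-15
        if ts + tv == 0:
            assert d == 0.0


# ------------------------------------------------------------ distance matrix

def test_distance_matrix_matches_per_pair_recomputation():
    aln = _aln([("a", "AAAA", "x"), ("b", "AAGA", "x"), ("c", "TTGT", "y")])
    D = distance_matrix(aln)
    for i in range(3):
        for j in range(3):
            if i == j:
                assert D.d[i, i] == 0.0
                continue
            counts = classify_site_pairs(
                aln.records[i].sequence, aln.records[j].sequence
            )
            expected = k2p_distance(counts)
            if expected is None:
                assert not D.defined[i, j] and np.isnan(D.d[i, j])
            else:
                assert D.d[i, j] == pytest.approx(expected, abs=1e-15)
    assert np.allclose(D.d, D.d.T, equal_nan=True)


def test_distance_matrix_complete_masking_drops_column_globally():
    aln = _aln([("a", "AC-T", "x"), ("b", "ACGT", "x"), ("c", "ACGA", "y")])
    D = distance_matrix(aln, masking="complete")
    # column 2 excluded for every pair: b vs c compare over ACT vs ACA
    counts_bc = classify_site_pairs("ACT", "ACA")
    assert D.d[1, 2] == pytest.approx(k2p_distance(counts_bc))
    Dp = distance_matrix(aln, masking="pairwise")
    assert Dp.d[1, 2] == pytest.approx(k2p_distance(classify_site_pairs("ACGT", "ACGA")))


def test_distance_matrix_permutation_equivariant(rng):
    mat = rng.choice(list("ACGT"), size=(6, 400))
    seqs = ["".join(r) for r in mat]
    aln = _aln([(f"s{i}", s, "sp") for i, s in enumerate(seqs)])
    D = distance_matrix(aln)
    perm = rng.permutation(6)
    aln2 = _aln([(f"s{i}", seqs[i], "sp") for i in perm])
    D2 = distance_matrix(aln2)
    np.testing.assert_allclose(D2.d, D.d[np.ix_(perm, perm)], atol=1e-15)


def _toy_matrix():
    ids = ("a1", "a2", "b1", "b2")
    part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    d = np.array(
        [
            [0, 0.001, 0.01, 0.01],
            [0.001, 0, 0.01, 0.01],
            [0.01, 0.01, 0, 0.001],
            [0.01, 0.01, 0.001, 0],
        ]
    )
    return DistanceMatrix(ids, d, np.ones_like(d, dtype=bool)), part


def test_intra_inter_summary_and_gap_margin():
    D, part = _toy_matrix()
    s = intra_inter_summary(D, part)
    assert s.intra_mean == pytest.approx(0.001)
    assert s.inter_mean == pytest.approx(0.01)
    assert s.gap_margin == pytest.approx(0.009)


def test_summary_single_species_inter_undefined():
    ids = ("a1", "a2")
    d = np.array([[0, 0.1], [0.1, 0]])
    D = DistanceMatrix(ids, d, np.ones_like(d, dtype=bool))
    with pytest.warns(UserWarning, match="interspecific"):
        s = intra_inter_summary(D, {"a1": "A", "a2": "A"})
    assert s.inter_mean is None and s.intra_mean == pytest.approx(0.1)


def test_negative_gap_margin_detected(rng):
    # one species pair made more divergent within than between
    ids = ("a1", "a2", "b1")
    d = np.array([[0, 0.02, 0.005], [0.02, 0, 0.006], [0.005, 0.006, 0]])
    D = DistanceMatrix(ids, d, np.ones_like(d, dtype=bool))
    s = intra_inter_summary(D, {"a1": "A", "a2": "A", "b1": "B"})
    assert s.gap_margin < 0


# ------------------------------------------------------------------------- ISR

def test_isr_clean_gap_is_one():
    D, part = _toy_matrix()
    res = isr_nearest_neighbor(D, part)
    assert res.isr == 1.0 and res.n_evaluated == 4


def test_isr_tie_with_heterospecific_fails():
    ids = ("a1", "a2", "b1")
    d = np.array([[0, 0.01, 0.01], [0.01, 0, 0.02], [0.01, 0.02, 0]])
    D = DistanceMatrix(ids, d, np.ones_like(d, dtype=bool))
    part = {"a1": "A", "a2": "A", "b1": "B"}
    res = isr_nearest_neighbor(D, part, singleton_policy="count_fail")
    assert res.per_sample["a1"] is False  # tie between a2 and b1
    assert res.per_sample["a2"] is True


def test_isr_singleton_policies():
    ids = ("a1", "a2", "b1")
    d = np.array([[0, 0.001, 0.01], [0.001, 0, 0.01], [0.01, 0.01, 0]])
    D = DistanceMatrix(ids, d, np.ones_like(d, dtype=bool))
    part = {"a1": "A", "a2": "A", "b1": "B"}
    assert isr_nearest_neighbor(D, part, "exclude").n_evaluated == 2
    res = isr_nearest_neighbor(D, part, "count_fail")
    assert res.n_evaluated == 3 and res.isr == pytest.approx(2 / 3)


def test_isr_scaling_invariance():
    D, part = _toy_matrix()
    scaled = DistanceMatrix(D.sample_ids, D.d * 7.3, D.defined)
    assert isr_nearest_neighbor(scaled, part).isr == isr_nearest_neighbor(D, part).isr


def test_isr_55_sample_granularity(rng):
    """An engineered panel with 39/55 nearest-neighbour-conspecific samples."""
    n = 55
    ids = tuple(f"s{i:02d}" for i in range(n))
    # species of size 5: 11 species; first 39 samples get a conspecific at
    # distance 0.001, the rest have their nearest neighbour heterospecific
    part = {ids[i]: f"sp{i // 5}" for i in range(n)}
    d = np.full((n, n), 0.05)
    for i in range(n):
        d[i, i] = 0.0
        mate = i + 1 if (i + 1) // 5 == i // 5 else i - 1
        d[i, mate] = d[mate, i] = 0.001
    for i in range(39, n):
        foreign = (i + 7) % 39  # guaranteed different species block
        d[i, foreign] = d[foreign, i] = 0.0001
    d = np.minimum(d, d.T)
    D = DistanceMatrix(ids, d, np.ones_like(d, dtype=bool))
    per = isr_nearest_neighbor(D, part).per_sample
    # brute-force oracle
    expected = {}
    for i in range(n):
        row = [(d[i, j], j) for j in range(n) if j != i]
        best = min(v for v, _ in row)
        expected[ids[i]] = all(part[ids[j]] == part[ids[i]] for v, j in row if v == best)
    assert per == expected
    isr = sum(expected.values()) / n
    got = isr_nearest_neighbor(D, part).isr
    assert got == pytest.approx(isr)


def test_isr_tree_agrees_on_clean_panel(small_panel):
    from plastobarcode import bionj
    from plastobarcode.seq_io import concat_loci

    full, _ = concat_loci(small_panel.loci, list(small_panel.loci))
    D = distance_matrix(full)
    nn = isr_nearest_neighbor(D, small_panel.partition).isr
    tree_isr = isr_tree_monophyly(bionj(D), small_panel.partition).isr
    assert nn == 1.0 and tree_isr == 1.0


def test_isr_tree_leaf_mismatch_raises():
    from plastobarcode.trees import Tree

    tree = Tree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
    with pytest.raises(ValueError, match="partition"):
        isr_tree_monophyly(tree, {"a1": "A", "a2": "A", "b1": "B"})


# ------------------------------------------------------------- combinations

def test_evaluate_combinations_structure(small_panel):
    table = evaluate_combinations(small_panel.loci, small_panel.partition, isr="nn")
    assert len(table) == 15
    assert list(table["n_loci"]) == [1] * 4 + [2] * 6 + [3] * 4 + [4]
    names = list(small_panel.loci)
    assert list(table["combination"][:4]) == names
    assert table["combination"].iloc[-1] == " + ".join(names)


def test_single_locus_rows_equal_standalone(small_panel):
    table = evaluate_combinations(small_panel.loci, small_panel.partition, isr="nn")
    for locus, aln in small_panel.loci.items():
        row = table[table["combination"] == locus].iloc[0]
        D = distance_matrix(aln)
        s = intra_inter_summary(D, small_panel.partition)
        assert row["intra_mean"] == s.intra_mean  # bit-for-bit
        assert row["inter_mean"] == s.inter_mean
        assert row["inter_max"] == s.inter_max
        assert row["isr_nn"] == isr_nearest_neighbor(D, small_panel.partition).isr


def test_constant_locus_dilutes_distances(small_panel):
    from plastobarcode.seq_io import SequenceRecord

    base = small_panel.loci["R"]
    const = LabelledAlignment(
        [SequenceRecord(r.sample_id, "A" * 200, r.species) for r in base.records]
    )
    d_alone = distance_matrix(base).d
    from plastobarcode.seq_io import concat_loci

    diluted, _ = concat_loci({"R": base, "Z": const}, ["R", "Z"])
    d_diluted = distance_matrix(diluted).d
    assert (d_diluted <= d_alone + 1e-15).all()
    order_before = np.argsort(d_alone, axis=1, kind="stable")
    order_after = np.argsort(d_diluted, axis=1, kind="stable")
    np.testing.assert_array_equal(order_before, order_after)
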