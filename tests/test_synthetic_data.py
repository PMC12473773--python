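import numpy as np
import pytest

from plastobarcode.barcode_eval import classify_site_pairs, k2p_distance
from plastobarcode.synthetic_data import (
    SimulationConfig,
    attach_individuals,
    evolve_alignment,
    inject_missing,
    make_paper_like_panel,
    simulate_species_tree,
)
from plastobarcode.trees import Node, Tree


def test_species_tree_two_taxa_cherry():
    tree = simulate_species_tree(2, 0.005, seed=0)
    leaves = tree.leaves()
    assert len(leaves) == 2
    assert all(leaf.length == pytest.approx(0.005) for leaf in leaves)


def test_species_tree_deterministic():
    a = simulate_species_tree(12, 0.005, seed=9).to_newick()
    b = simulate_species_tree(12, 0.005, seed=9).to_newick()
    assert a == b
    assert a != simulate_species_tree(12, 0.005, seed=10).to_newick()


def test_species_tree_is_ultrametric_at_depth():
    tree = simulate_species_tree(15, 0.01, seed=4)
    _, d = tree.path_length_matrix()
    assert d.max() == pytest.approx(0.02, rel=1e-9)  # deepest pair spans the root


def test_species_tree_shape_matches_independent_simulator():
    """Mean/max pairwise distance ratio vs dendropy's pure-birth trees."""
    import random

    import dendropy

    def ratio(v):
        return v.mean() / v.max()

    ours = []
    for s in range(100):
        t = simulate_species_tree(20, 1.0, seed=s)
        _, d = t.path_length_matrix()
        ours.append(ratio(d[np.triu_indices(20, 1)]))
    theirs = []
    for s in range(100):
        bt = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=20, rng=random.Random(s)
        )
        pdm = bt.phylogenetic_distance_matrix()
        taxa = list(bt.taxon_namespace)
        dd = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
        theirs.append(ratio(dd[np.triu_indices(20, 1)]))
    ours, theirs = np.array(ours), np.array(theirs)
    se = np.hypot(ours.std(ddof=1) / 10, theirs.std(ddof=1) / 10)
    assert abs(ours.mean() - theirs.mean()) < 3 * se


def test_attach_individuals_structure():
    tree = simulate_species_tree(4, 0.01, seed=1)
    counts = {"sp01": 1, "sp02": 2, "sp03": 3, "sp04": 2}
    genealogy = attach_individuals(tree, counts, 0.002)
    names = genealogy.leaf_names()
    assert sorted(names) == sorted(
        ["sp01_1", "sp02_1", "sp02_2", "sp03_1", "sp03_2", "sp03_3", "sp04_1", "sp04_2"]
    )
    _, d = genealogy.path_length_matrix(order=sorted(names))
    # conspecific pairwise divergence equals the intraspecific depth
    i, j = sorted(names).index("sp02_1"), sorted(names).index("sp02_2")
    assert d[i, j] == pytest.approx(0.002)


def test_intra_below_inter_in_genealogy():
    tree = simulate_species_tree(6, 0.01, seed=2)
    genealogy = attach_individuals(tree, {f"sp{i:02d}": 2 for i in range(1, 7)}, 0.001)
    names, d = genealogy.path_length_matrix()
    species = [n.rsplit("_", 1)[0] for n in names]
    intra = [d[i, j] for i in range(len(names)) for j in range(i + 1, len(names)) if species[i] == species[j]]
    inter = [d[i, j] for i in range(len(names)) for j in range(i + 1, len(names)) if species[i] != species[j]]
    assert max(intra) < min(inter)


def test_evolve_zero_branches_identical():
    root = Node()
    for name in ("a", "b", "c"):
        root.add(Node(name, 0.0))
    aln = evolve_alignment(Tree(root), 500, seed=3)
    assert len({r.sequence for r in aln.records}) == 1


def test_evolve_recovers_k2p_distance():
    """Estimator consistency: K2P distance on a simulated 2-taxon pair."""
    t = 0.1
    root = Node()
    root.add(Node("a", t / 2))
    root.add(Node("b", t / 2))
    n_sites = 100_000
    aln = evolve_alignment(Tree(root), n_sites, kappa=2.0, seed=7)
    d = k2p_distance(classify_site_pairs(aln.records[0].sequence, aln.records[1].sequence))
    se = np.sqrt(t / n_sites)  # Poisson-scale error on the substitution count
    assert abs(d - t) < 3 * se


def test_evolve_kappa_limit_suppresses_transversions():
    root = Node()
    root.add(Node("a", 0.05))
    root.add(Node("b", 0.05))
    aln = evolve_alignment(Tree(root), 50_000, kappa=1e9, seed=8)
    counts = classify_site_pairs(aln.records[0].sequence, aln.records[1].sequence)
    assert counts.tv == 0 and counts.ts > 0


def test_evolve_rate_profile_validated():
    root = Node()
    root.add(Node("a", 0.1))
    root.add(Node("b", 0.1))
    with pytest.raises(ValueError, match="rate_profile"):
        evolve_alignment(Tree(root), 100, rate_profile=np.ones(50))


def test_inject_missing_identity_and_bounds(default_panel):
    aln = default_panel.loci["R"]
    same, mask = inject_missing(aln, 0.0, seed=1)
    assert same is aln and not mask.any()
    injected, mask = inject_missing(aln, 0.05, seed=1)
    total = aln.n_records * aln.length
    realized = mask.sum() / total
    # ~90% independent cells + ~10% in runs of 3: compound-binomial 99.9% band
    var = 0.05 * (0.9 + 0.1 * 3) / total
    assert abs(realized - 0.05) < 3.3 * np.sqrt(var) + 3 / total
    # injected cells really are N or -
    for r, c in zip(*np.nonzero(mask)):
        assert injected.records[r].sequence[c] in "N-"


def test_complete_masking_excludes_injected_columns(default_panel):
    from plastobarcode.diversity_scan import usable_columns

    aln = default_panel.loci["R"]
    injected, mask = inject_missing(aln, 0.02, seed=5)
    ok = usable_columns(injected.to_codes())
    touched_columns = np.unique(np.nonzero(mask)[1])
    assert not ok[touched_columns].any()


def test_panel_shape_and_determinism():
    p1 = make_paper_like_panel(SimulationConfig(seed=2))
    assert len(p1.partition) == 55
    assert len(set(p1.partition.values())) == 20
    for locus, aln in p1.loci.items():
        assert aln.n_records == 55
    counts = {}
    for sp in p1.partition.values():
        counts[sp] = counts.get(sp, 0) + 1
    assert all(2 <= c <= 6 for c in counts.values())
    p2 = make_paper_like_panel(SimulationConfig(seed=2))
    assert all(
        p1.loci[k].records == p2.loci[k].records for k in p1.loci
    )
    assert p1.truth.to_json() == p2.truth.to_json()


def test_panel_mean_pi_in_band_over_seeds():
    from plastobarcode.diversity_scan import mean_pi
    from plastobarcode.seq_io import concat_loci

    for seed in range(10):
        panel = make_paper_like_panel(SimulationConfig(seed=seed))
        full, _ = concat_loci(panel.loci, list(panel.loci))
        assert 0.0005 <= mean_pi(full) <= 0.002


def test_hotspot_windows_exceed_threshold(default_panel):
    from plastobarcode.diversity_scan import nucleotide_diversity

    for locus, spans in default_panel.truth.hotspots.items():
        for start, end, mult in spans:
            pi = nucleotide_diversity(default_panel.loci[locus], columns=range(start, end))
            assert pi > 0.005


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(intraspecific_depth=0.01, interspecific_depth=0.005)
    with pytest.raises(ValueError):
        SimulationConfig(n_individuals=500)
    with pytest.raises(ValueError):
        SimulationConfig(hotspots=[("P", 0, 99999, 10.0)])
    with pytest.raises(ValueError):
        SimulationConfig(hotspots=[("P", 0, 100, 0.5)])
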