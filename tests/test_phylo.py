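"""Distance matrices, neighbor joining, bootstrap and clade statistics."""

import itertools

import dendropy
import numpy as np
import pytest

from corvmhc import ng86, phylo, selection

from conftest import make_alignment


# ---------------------------------------------------------------------------
# Distances


def test_jc_identical_pair_zero():
    dm = phylo.jc_distance_matrix(["a", "b"], ["ATGATG", "ATGATG"])
    assert dm.matrix[0, 1] == 0.0


def test_jc_closed_form_246_sites():
    s1 = "A" * 246
    s2 = "C" * 10 + "A" * 236
    dm = phylo.jc_distance_matrix(["a", "b"], [s1, s2])
    p = 10 / 246
    assert dm.matrix[0, 1] == pytest.approx(-0.75 * np.log(1 - 4 * p / 3), abs=1e-12)


def test_jc_matrix_matches_elementwise_brute_force(neutral_alignment):
    aln = neutral_alignment.subset(list(range(10)))
    dm = phylo.jc_distance_matrix(aln.ids, aln.sequences)
    for i, j in itertools.combinations(range(10), 2):
        p = sum(a != b for a, b in zip(aln.sequences[i], aln.sequences[j])) / 246
        assert dm.matrix[i, j] == pytest.approx(ng86.jukes_cantor(p), abs=1e-12)
        assert dm.matrix[i, j] == dm.matrix[j, i]
    assert np.all(np.diag(dm.matrix) == 0)


def test_gamma_corrected_jc_exceeds_plain_jc():
    s1 = "A" * 246
    s2 = "C" * 20 + "A" * 226
    plain = phylo.jc_distance_matrix(["a", "b"], [s1, s2]).matrix[0, 1]
    gamma = phylo.jc_distance_matrix(["a", "b"], [s1, s2], gamma_alpha=0.5).matrix[0, 1]
    p = 20 / 246
    want = 0.75 * 0.5 * ((1 - 4 * p / 3) ** -2.0 - 1)
    assert gamma == pytest.approx(want, abs=1e-12)
    assert gamma > plain  # rate heterogeneity inflates corrected distances


def test_dn_ds_matrices_separate_synonymous_only_divergence():
    # CTT->CTG (L->L, synonymous), repeated: dN must be 0, dS positive
    s1 = "CTT" * 10
    s2 = "CTG" * 3 + "CTT" * 7
    aln = make_alignment([s1, s2, "CTT" * 10], ids=["a", "b", "c"])
    dn = phylo.dn_ds_distance_matrix(aln, "dN")
    ds = phylo.dn_ds_distance_matrix(aln, "dS")
    assert dn.matrix[0, 1] == 0.0
    assert ds.matrix[0, 1] > 0.0


def test_dn_ds_matrix_axioms(small_alignment):
    for which in ("dN", "dS"):
        dm = phylo.dn_ds_distance_matrix(small_alignment, which)
        assert np.allclose(dm.matrix, dm.matrix.T, equal_nan=True)
        assert np.all(np.diag(dm.matrix) == 0)


def test_dn_ds_matrix_matches_pairwise_calls(small_alignment):
    dm = phylo.dn_ds_distance_matrix(small_alignment, "dN")
    s = small_alignment.sequences
    for i, j in itertools.combinations(range(len(s)), 2):
        want = selection.nei_gojobori_pair(s[i], s[j]).dN
        assert dm.matrix[i, j] == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# Neighbor joining


def _random_additive(rng, n):
    """Distance matrix from a random tree with positive branch lengths."""
    import random
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in taxa]
    mat = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i != j:
                mat[i, j] = pdm.distance(ti, tj)
    return tree, phylo.DistanceMatrix(ids, mat, "jc_nt")


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        out[(a.label, b.label)] = pdm.distance(a, b)
    return out


def test_three_taxon_solves_three_point_equations():
    mat = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    dm = phylo.DistanceMatrix(["a", "b", "c"], mat, "jc_nt")
    tree = phylo.neighbor_joining(dm)
    got = _patristic(tree)
    assert got[("a", "b")] == pytest.approx(0.3, abs=1e-12)
    assert got[("a", "c")] == pytest.approx(0.5, abs=1e-12)
    assert got[("b", "c")] == pytest.approx(0.6, abs=1e-12)


def test_nj_exact_on_additive_matrices():
    rng = np.random.default_rng(0)
    for rep in range(20):
        n = int(rng.integers(4, 13))
        true_tree, dm = _random_additive(rng, n)
        tree = phylo.neighbor_joining(dm)
        # additivity: patristic distances reproduce the input exactly
        got = _patristic(tree)
        for (a, b), d in got.items():
            i, j = dm.ids.index(a), dm.ids.index(b)
            assert d == pytest.approx(dm.matrix[i, j], abs=1e-9)
        # topology identical
        want_bips = phylo.tree_bipartitions(true_tree)
        assert phylo.tree_bipartitions(tree) == want_bips


def test_nj_requires_three_taxa():
    dm = phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]), "jc_nt")
    with pytest.raises(ValueError):
        phylo.neighbor_joining(dm)


def test_nj_deterministic_under_ties():
    # 4-taxon matrix violating the four-point condition minimally
    mat = np.array([
        [0.0, 1.0, 1.0, 1.0],
        [1.0, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 1.0],
        [1.0, 1.0, 1.0, 0.0],
    ])
    dm = phylo.DistanceMatrix(list("abcd"), mat, "jc_nt")
    t1 = phylo.neighbor_joining(dm).as_string(schema="newick")
    t2 = phylo.neighbor_joining(dm).as_string(schema="newick")
    assert t1 == t2


def test_missing_entries_require_imputation():
    mat = np.array([
        [0.0, np.nan, 1.0], [np.nan, 0.0, 1.0], [1.0, 1.0, 0.0],
    ])
    dm = phylo.DistanceMatrix(list("abc"), mat, "dS")
    with pytest.raises(ValueError):
        phylo.neighbor_joining(dm)
    imp = dm.imputed()
    assert imp.matrix[0, 1] == 1.0
    phylo.neighbor_joining(imp)


# ---------------------------------------------------------------------------
# Bootstrap


def _two_group_alignment():
    """Two 4-leaf groups; between-group divergence ~10x within-group."""
    rng = np.random.default_rng(9)
    from corvmhc.simulate import _mutate_neutral, _random_sense_codon
    root = "".join(_random_sense_codon(rng) for _ in range(60))
    all_nt = np.arange(180)
    g1 = _mutate_neutral(root, 30, all_nt, rng)
    g2 = _mutate_neutral(root, 0, all_nt, rng)
    seqs, ids, species = [], [], []
    for gi, g in enumerate((g1, g2)):
        for k in range(4):
            seqs.append(_mutate_neutral(g, 3, all_nt, rng))
            ids.append(f"g{gi}_{k}")
            species.append(f"sp{gi}")
    return make_alignment(seqs, species=species, ids=ids)


def test_bootstrap_central_edge_strongly_supported():
    aln = _two_group_alignment()
    st = phylo.bootstrap_support(aln, "jc_nt", reps=200, seed=4)
    central = frozenset(f"g0_{k}" for k in range(4))
    assert st.supports[central] >= 95.0


def test_bootstrap_reps_zero_returns_unsupported_topology():
    aln = _two_group_alignment()
    st = phylo.bootstrap_support(aln, "jc_nt", reps=0, seed=4)
    assert st.supports == {}
    assert st.replicates_used == 0


def test_bootstrap_deterministic_and_leaf_order_invariant():
    aln = _two_group_alignment()
    a = phylo.bootstrap_support(aln, "jc_nt", reps=50, seed=4)
    b = phylo.bootstrap_support(aln, "jc_nt", reps=50, seed=4)
    assert a.supports == b.supports
    perm = list(reversed(range(aln.n_sequences)))
    c = phylo.bootstrap_support(aln.subset(perm), "jc_nt", reps=50, seed=4)
    assert a.supports == c.supports


# ---------------------------------------------------------------------------
# Interspecific clade statistic


def _supported(newick, supports, species_of):
    ids = sorted(species_of)
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)
    return phylo.SupportedTree(tree, supports, 100)


def test_reciprocal_monophyly_gives_zero_fraction():
    species_of = {f"{s}{i}": s for s in "xyz" for i in range(2)}
    newick = "((x0,x1),(y0,y1),(z0,z1));"
    supports = {
        frozenset({"x0", "x1"}): 100.0,
        frozenset({"y0", "y1"}): 100.0,
        frozenset({"z0", "z1"}): 100.0,
    }
    stat = phylo.interspecific_cluster_stat(
        _supported(newick, supports, species_of), species_of)
    assert stat.n_clades_maximal == 0
    assert stat.fraction == 0.0


def test_single_mixed_clade_counts_half_the_leaves():
    species_of = {f"{s}{i}": s for s in "xyz" for i in range(4)}
    mixed = ["x0", "x1", "y0", "y1", "z0", "z1"]
    rest = sorted(set(species_of) - set(mixed))
    newick = f"(({','.join(mixed)}),({','.join(rest)}));"
    supports = {frozenset(mixed): 80.0}
    stat = phylo.interspecific_cluster_stat(
        _supported(newick, supports, species_of), species_of)
    assert stat.n_clades_maximal == 1
    assert stat.variants_in_clades == 6
    assert stat.fraction == pytest.approx(0.5)


def test_threshold_above_hundred_counts_nothing():
    species_of = {f"{s}{i}": s for s in "xyz" for i in range(4)}
    mixed = ["x0", "x1", "y0", "y1", "z0", "z1"]
    rest = sorted(set(species_of) - set(mixed))
    newick = f"(({','.join(mixed)}),({','.join(rest)}));"
    stat = phylo.interspecific_cluster_stat(
        _supported(newick, {frozenset(mixed): 80.0}, species_of),
        species_of, threshold=101.0)
    assert stat.n_clades_maximal == 0
    assert stat.fraction == 0.0


def test_nested_qualifying_clades_collapse_to_maximal():
    species_of = {f"{s}{i}": s for s in "xy" for i in range(3)}
    inner = frozenset({"x0", "y0"})
    outer = frozenset({"x0", "y0", "x1", "y1"})
    newick = "(((x0,y0),(x1,y1)),(x2,y2));"
    supports = {inner: 90.0, outer: 90.0}
    stat = phylo.interspecific_cluster_stat(
        _supported(newick, supports, species_of), species_of,
        required_species={"x", "y"})
    assert stat.n_clades_any == 2
    assert stat.n_clades_maximal == 1
    assert stat.variants_in_clades == 4


def test_unlabelled_leaf_rejected():
    species_of = {"x0": "x", "x1": "x", "y0": "y"}
    newick = "(x0,x1,y0);"
    st = _supported(newick, {}, species_of)
    with pytest.raises(ValueError):
        phylo.interspecific_cluster_stat(st, {"x0": "x", "x1": "x"})
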