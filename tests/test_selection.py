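"""Wu-Kabat, dN/dS Z test, ancestral reconstruction, SLAC and diversity."""

import itertools

import dendropy
import numpy as np
import pytest

from corvmhc import ng86, selection
from corvmhc.selection import CodonAlignment, PartitionMask

from conftest import make_alignment


# ---------------------------------------------------------------------------
# Wu-Kabat


@pytest.mark.parametrize(
    "column,expected",
    [
        (list("AAAA"), 1.0),
        (list("AAAB"), 2 / 0.75),
        (list("ABCD"), 4 / 0.25),
    ],
)
def test_wu_kabat_column_values(column, expected):
    assert selection.wu_kabat_column(column) == pytest.approx(expected)


def test_wu_kabat_invariant_iff_one_residue():
    assert selection.wu_kabat_column(list("WWW")) == 1.0
    assert selection.wu_kabat_column(list("WWV")) > 1.0


def test_wu_kabat_relabeling_invariance():
    a = selection.wu_kabat_column(list("AABBC"))
    b = selection.wu_kabat_column(list("NNQQP"))
    assert a == pytest.approx(b)


def test_wu_kabat_rejects_gaps():
    with pytest.raises(ValueError):
        selection.wu_kabat(["A-C", "AAC"])


def test_wu_kabat_sites_intersection_across_species():
    # site 1 hypervariable in both species, site 2 only in the second;
    # eight invariant sites keep the 2x-mean cutoff below the peak
    x1, x2 = "ACDE", "AAAA"
    y1, y2 = "ACDE", "ACDE"
    tail = "G" * 8
    seqs = [a + b + tail for a, b in zip(x1, x2)] + \
           [a + b + tail for a, b in zip(y1, y2)]
    species = ["x"] * 4 + ["y"] * 4
    prof = selection.wu_kabat(seqs, species)
    assert set(prof.per_species_sites["x"]) == {1}
    assert set(prof.per_species_sites["y"]) == {1, 2}
    assert prof.sites == (1,)


# ---------------------------------------------------------------------------
# Pairwise NG86 and the Z test


def test_nei_gojobori_identical_sequences():
    r = selection.nei_gojobori_pair("ATGATG", "ATGATG")
    assert (r.Sd, r.Nd, r.dN, r.dS) == (0, 0, 0, 0)


def test_nei_gojobori_single_codon_spec_example():
    r = selection.nei_gojobori_pair("TTT", "TTA")
    assert (r.Sd, r.Nd) == (0.0, 1.0)
    assert r.S == pytest.approx(0.5)
    assert r.N == pytest.approx(2.5)
    assert r.pN == pytest.approx(0.4)
    assert r.dN == pytest.approx(-0.75 * np.log(1 - 4 * 0.4 / 3), abs=1e-12)
    assert r.dS == 0.0


def test_nei_gojobori_symmetry():
    r1 = selection.nei_gojobori_pair("TTTGGGCCA", "TTAGGACCA")
    r2 = selection.nei_gojobori_pair("TTAGGACCA", "TTTGGGCCA")
    assert (r1.Sd, r1.Nd, r1.S, r1.N) == (r2.Sd, r2.Nd, r2.S, r2.N)


def test_z_test_on_identical_sequences_reports_p_one():
    aln = make_alignment(["ATGGCTACTAAACTGGGG"] * 4)
    res = selection.z_test_selection(aln, selection.full_mask(6), boot_reps=50, seed=0)
    assert res.p_value == 1.0


def test_z_test_requires_minimum_mask():
    aln = make_alignment(["ATGGCTACTAAACTGGGG"] * 4)
    with pytest.raises(ValueError):
        selection.z_test_selection(aln, PartitionMask("tiny", (1, 2)))


def test_z_test_detects_planted_nonsynonymous_excess(neutral_alignment):
    """Strong nonsynonymous excess at masked codons yields small p."""
    rng = np.random.default_rng(1)
    mask_codons = tuple(range(1, 12))
    alphabet = {"A": "GCT", "S": "TCT", "T": "ACT", "P": "CCT"}
    seqs = []
    for seq in neutral_alignment.sequences:
        chars = list(seq)
        for c in mask_codons:
            aa = sorted(alphabet)[rng.integers(4)]
            chars[3 * (c - 1): 3 * c] = list(alphabet[aa])
        seqs.append("".join(chars))
    aln = make_alignment(seqs)
    res = selection.z_test_selection(aln, PartitionMask("m", mask_codons), 300, seed=2)
    assert res.mean_dn > res.mean_ds
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# Ancestral reconstruction


def _tree(newick, ids):
    taxa = dendropy.TaxonNamespace(ids)
    return dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)


def test_ancestor_of_identical_leaves_is_identical():
    aln = make_alignment(["ATGCCC", "ATGCCC"], ids=["a", "b"])
    tree = _tree("(a:0.1,b:0.1);", ["a", "b"])
    anc = selection.ancestral_codons(tree, aln)
    assert set(anc.values()) == {"ATGCCC"}


def test_single_derived_leaf_reconstructs_ancestral_base():
    ids = ["a", "b", "c", "d"]
    aln = make_alignment(["ATG", "ATG", "ATG", "TTG"], ids=ids)
    tree = _tree("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);", ids)
    anc = selection.ancestral_codons(tree, aln)
    assert all(seq == "ATG" for seq in anc.values())


def test_marginal_ml_matches_exhaustive_state_search():
    """Reconstruction agrees with brute-force ML over all joint assignments.

    Marginal and joint ML can differ in principle; on clearly resolved
    sites they coincide, so agreement is required at >= 99% of sites.
    """
    rng = np.random.default_rng(5)
    ids = [f"t{i}" for i in range(8)]
    newick = "(((t0:0.05,t1:0.08):0.04,(t2:0.06,t3:0.05):0.07):0.03," \
             "((t4:0.05,t5:0.04):0.06,(t6:0.07,t7:0.05):0.04):0.05);"
    n_sites = 60
    seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, n_sites)) for _ in ids]
    # keep frame valid: replace any in-frame stop by AAA
    fixed = []
    for s in seqs:
        codons = [s[i:i + 3] for i in range(0, n_sites, 3)]
        fixed.append("".join("AAA" if ng86.is_stop(c) else c for c in codons))
    aln = make_alignment(fixed, ids=ids)
    tree = _tree(newick, ids)
    anc = selection.ancestral_codons(tree, aln)

    # independent oracle: enumerate all internal-node state assignments
    # per site and sum likelihoods to exact per-node marginals
    internal = [n for n in tree.preorder_internal_node_iter()]
    node_pos = {id(n): i for i, n in enumerate(internal)}
    assigns = np.asarray(list(itertools.product(range(4), repeat=len(internal))))
    seq_of = dict(zip(aln.ids, aln.sequences))

    edges = []  # (parent_col, child_col_or_None, leaf_label, pmatrix)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        pm = selection._jc_pmatrix(node.edge.length or 0.0)
        pcol = node_pos[id(node.parent_node)]
        if node.is_leaf():
            edges.append((pcol, None, node.taxon.label, pm))
        else:
            edges.append((pcol, node_pos[id(node)], None, pm))

    n_match = n_total = 0
    for site in range(n_sites):
        like = np.full(len(assigns), 0.25)
        for pcol, ccol, leaf, pm in edges:
            if leaf is None:
                like = like * pm[assigns[:, pcol], assigns[:, ccol]]
            else:
                state = "ACGT".index(seq_of[leaf][site])
                like = like * pm[assigns[:, pcol], state]
        for ni, node in enumerate(internal):
            margs = np.asarray([like[assigns[:, ni] == b].sum() for b in range(4)])
            want = int(np.argmax(margs))
            got = "ACGT".index(anc[node.label][site])
            n_total += 1
            if got == want or np.isclose(margs[got], margs[want]):
                n_match += 1
    assert n_match / n_total >= 0.99


# ---------------------------------------------------------------------------
# SLAC


def test_slac_invariant_codon_is_neutral():
    aln = make_alignment(["ATGCCC", "ATGCCC", "ATGCCC"], ids=["a", "b", "c"])
    tree = _tree("(a:0.1,b:0.1,c:0.1);", ["a", "b", "c"])
    results = selection.slac_per_codon(tree, aln)
    assert all(r.dn_minus_ds == 0 and r.p_value == 1.0 for r in results)


def test_slac_localises_single_nonsynonymous_change():
    # codon 5 differs nonsynonymously between the two halves of a star tree
    base = "ATGGCTACTAAACTGGGG"
    mutated = base[:12] + "ATG" + base[15:]   # codon 5 CTG -> ATG (L -> M)
    aln = make_alignment([base, base, mutated], ids=["a", "b", "c"])
    tree = _tree("(a:0.1,b:0.1,c:0.1);", ["a", "b", "c"])
    results = selection.slac_per_codon(tree, aln)
    assert results[4].Nd == pytest.approx(1.0)
    assert results[4].Sd == 0.0
    for r in results:
        if r.codon != 5:
            assert r.Nd + r.Sd == 0.0


def test_slac_totals_match_reconstructed_changes(small_alignment):
    from corvmhc import phylo
    aln = small_alignment
    dm = phylo.jc_distance_matrix(aln.ids, aln.sequences).imputed()
    tree = phylo.neighbor_joining(dm)
    anc = selection.ancestral_codons(tree, aln)
    results = selection.slac_per_codon(tree, aln, anc)
    total = sum(r.Nd + r.Sd for r in results)

    seq_of = dict(zip(aln.ids, aln.sequences))
    expect = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        child = seq_of[node.taxon.label] if node.is_leaf() else anc[node.label]
        parent = anc[node.parent_node.label]
        for k in range(aln.n_codons):
            c1, c2 = parent[3 * k: 3 * k + 3], child[3 * k: 3 * k + 3]
            if c1 != c2:
                expect += sum(ng86.pathway_differences(c1, c2))
    assert total == pytest.approx(expect, abs=1e-9)


# ---------------------------------------------------------------------------
# Diversity and partitions


def test_diversity_identical_sequences_zero():
    aln = make_alignment(["ATGCCC"] * 3)
    assert selection.nucleotide_diversity(aln, seed=0).value == 0.0


def test_diversity_single_difference_closed_form():
    s1 = "ATG" * 82
    s2 = "ATG" * 81 + "ATC"  # one of 246 sites differs
    aln = make_alignment([s1, s2])
    res = selection.nucleotide_diversity(aln, seed=0)
    assert res.value == pytest.approx(1 / 246)


def test_diversity_matches_brute_force_over_pairs(neutral_alignment):
    aln = neutral_alignment.subset(list(range(11)))
    res = selection.nucleotide_diversity(aln, seed=0)
    dists = []
    for a, b in itertools.combinations(aln.sequences, 2):
        dists.append(sum(x != y for x, y in zip(a, b)) / len(a))
    assert res.value == pytest.approx(np.mean(dists), abs=1e-12)


def test_synonymous_diversity_matches_pairwise_ps(neutral_alignment):
    aln = neutral_alignment.subset(list(range(6)))
    mask = selection.full_mask(aln.n_codons)
    res = selection.nucleotide_diversity(aln, mask, "synonymous", seed=0)
    ps = []
    for a, b in itertools.combinations(aln.sequences, 2):
        ps.append(selection.nei_gojobori_pair(a, b).pS)
    assert res.value == pytest.approx(np.mean(ps), abs=1e-12)


def test_partition_extract_full_identity(small_alignment):
    out = selection.partition_extract(small_alignment, selection.full_mask(20))
    assert out.sequences == small_alignment.sequences


def test_partition_lengths_match_design():
    seqs = ["".join(ng86.SENSE_CODONS[i % 60] for i in range(82))] * 2
    aln = make_alignment(seqs)
    wuk = PartitionMask("WuK_PS", tuple(range(1, 12)))        # 11 codons
    assert len(selection.partition_extract(aln, wuk).sequences[0]) == 33
    pbr = selection.hla_pbr_mask()                            # 22 codons
    assert len(pbr) == 22
    assert len(selection.partition_extract(aln, pbr).sequences[0]) == 66
    assert len(wuk.complement(82)) == 71
    assert len(pbr.complement(82)) == 60


def test_empty_mask_rejected(small_alignment):
    with pytest.raises(ValueError):
        selection.partition_extract(small_alignment, PartitionMask("e", ()))


def test_amino_acid_p_distance_pairwise():
    assert selection.amino_acid_p_distance(["AAA", "AAV"]) == pytest.approx(1 / 3)
    assert selection.amino_acid_p_distance(["AA-", "AAV", "AVV"]) == pytest.approx(
        np.mean([0.0, 0.5, 1 / 3])
    )
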