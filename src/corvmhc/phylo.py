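"""Distance-based phylogenetics and the interspecific-clade statistic.

Neighbor-joining trees are built from Jukes-Cantor nucleotide distances
or from pairwise NG86 dN / dS, with nonparametric bootstrap support
(column resampling: nucleotide sites for the JC metric, codons for the
dN/dS metrics) mapped onto the bipartitions of the original tree. The
headline statistic counts well-supported clades containing every
species of interest and the fraction of variants falling inside at
least one such clade — the signal that separates trans-species
polymorphism (shared ancestral allelic lineages: interspecific clades
in both dN and dS trees) from convergence (interspecific clades in the
dN tree only).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import ng86
from .selection import CodonAlignment

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    kind: str  # {"jc_nt", "dN", "dS"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if np.nanmax(np.abs(np.diag(m))) > 1e-12:
            raise ValueError("nonzero diagonal")
        self.matrix = m

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.matrix).sum() // 2)

    def imputed(self) -> "DistanceMatrix":
        """Replace flagged-missing (saturated) entries by the matrix maximum."""
        m = self.matrix.copy()
        if np.isnan(m).any():
            fill = np.nanmax(m)
            logger.warning(
                "imputing %d saturated %s distances with matrix maximum %.4f",
                self.n_missing, self.kind, fill,
            )
            m[np.isnan(m)] = fill
            np.fill_diagonal(m, 0.0)
        return DistanceMatrix(list(self.ids), m, self.kind)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.matrix):
                fh.write(name + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


_NT_CODE = {b: i for i, b in enumerate("ACGT")}


def _nt_matrix(ids: list[str], seqs: list[str]) -> np.ndarray:
    arr = np.empty((len(seqs), len(seqs[0])), dtype=np.int8)
    for i, s in enumerate(seqs):
        for j, b in enumerate(s):
            arr[i, j] = _NT_CODE[b]
    return arr


def jc_distance_matrix(
    ids: list[str], seqs: list[str], gamma_alpha: float | None = None
) -> DistanceMatrix:
    """Jukes-Cantor distances from pairwise p-distances (gap-free input).

    With ``gamma_alpha`` set, applies the gamma-rate-corrected JC
    transform ``d = (3a/4) ((1 - 4p/3)^(-1/a) - 1)``.
    """
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("unequal sequence lengths")
    nt = _nt_matrix(ids, seqs)
    p = _pairwise_p(nt)
    if gamma_alpha is None:
        d = ng86.jukes_cantor(p)
    else:
        if gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")
        arg = 1.0 - (4.0 / 3.0) * p
        with np.errstate(invalid="ignore"):
            d = np.where(
                arg > 0.0,
                0.75 * gamma_alpha * (np.where(arg > 0, arg, 1.0) ** (-1.0 / gamma_alpha) - 1.0),
                np.nan,
            )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ids), d, "jc_nt")


def _pairwise_p(nt: np.ndarray) -> np.ndarray:
    n = nt.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        diff = (nt[i] != nt[i + 1:]).mean(axis=1) if i + 1 < n else []
        p[i, i + 1:] = diff
        p[i + 1:, i] = diff
    return p


def dn_ds_distance_matrix(aln: CodonAlignment, which: str) -> DistanceMatrix:
    """Pairwise NG86 dN or dS matrix (JC-corrected; saturation flagged NaN)."""
    if which not in {"dN", "dS"}:
        raise ValueError("which must be 'dN' or 'dS'")
    t = ng86.counting_tables()
    mat = aln.codon_matrix
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        sd = t.sd[mat[i], mat[j]].sum()
        nd = t.nd[mat[i], mat[j]].sum()
        s = 0.5 * (t.s_pot[mat[i]].sum() + t.s_pot[mat[j]].sum())
        npot = 0.5 * (t.n_pot[mat[i]].sum() + t.n_pot[mat[j]].sum())
        p = (nd / npot) if which == "dN" else (sd / s)
        d[i, j] = d[j, i] = ng86.jukes_cantor(p)
    return DistanceMatrix(list(aln.ids), d, which)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest
    index pair. Negative branch lengths are clamped to zero with the
    deficit transferred to the sibling branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(dm.matrix).any():
        raise ValueError("missing entries; call .imputed() first")

    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest (i, j) among minima
        flat = np.argmin(q)
        qmin = q.flat[flat]
        cand = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        cand = [tuple(sorted(c)) for c in cand]
        ai, aj = sorted(set(cand))[0]
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        # clamp negatives, transfer deficit to the sibling branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)

        new_node = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        new_node.add_child(ni)
        new_node.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj

        # distances from the new node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dnew])
        dnew2 = np.append(dnew, 0.0)
        d = np.hstack([d, dnew2[:, None]])
        nodes.append(new_node)
        new_index = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [new_index]

    i, j = active
    root = dendropy.Node()
    ni, nj = nodes[i], nodes[j]
    root.add_child(ni)
    root.add_child(nj)
    half = d[i, j] / 2.0
    ni.edge.length = max(d[i, j] - half, 0.0)
    nj.edge.length = half
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as frozensets of the smaller-side leaf labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < len(all_leaves) - 1:
            other = all_leaves - clade
            bips.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
    return bips


@dataclass
class SupportedTree:
    """An NJ tree whose internal nodes carry bootstrap percentages."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    replicates_used: int = 0

    def newick(self) -> str:
        self.annotate()
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def annotate(self) -> None:
        all_leaves = frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())
        for node in self.tree.preorder_internal_node_iter():
            if node is self.tree.seed_node:
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            key = min(clade, all_leaves - clade, key=lambda s: (len(s), sorted(s)))
            if key in self.supports:
                node.label = f"{self.supports[key]:.0f}"


def _resample_columns(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, size=n)


def bootstrap_support(
    aln: CodonAlignment,
    distance_kind: str = "jc_nt",
    reps: int = 500,
    seed: int | None = None,
) -> SupportedTree:
    """NJ tree with bootstrap percentages on the original tree's bipartitions.

    Columns are resampled with replacement — nucleotide sites for
    ``jc_nt``, whole codons for ``dN``/``dS`` — and each replicate tree's
    bipartitions are matched against the original topology. Replicates
    whose distance matrices contain undefined (saturated) entries after
    imputation are dropped and supports normalised by the retained
    count; saturated entries within a replicate are imputed by the
    replicate's maximum.
    """
    ids = sorted(aln.ids)
    order = [aln.ids.index(i) for i in ids]
    aln = aln.subset(order)  # leaf-order invariance

    def build(dm: DistanceMatrix) -> dendropy.Tree | None:
        if np.isnan(dm.matrix).all():
            return None
        if np.isnan(dm.matrix).any():
            dm = dm.imputed()
        return neighbor_joining(dm)

    def matrix_from(codon_cols: np.ndarray | None, nt_cols: np.ndarray | None) -> DistanceMatrix:
        if distance_kind == "jc_nt":
            seqs = aln.sequences
            nt = _nt_matrix(aln.ids, seqs)
            if nt_cols is not None:
                nt = nt[:, nt_cols]
            p = _pairwise_p(nt)
            d = ng86.jukes_cantor(p)
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(list(aln.ids), d, "jc_nt")
        sub = aln if codon_cols is None else _subset_codons(aln, codon_cols)
        return dn_ds_distance_matrix(sub, distance_kind)

    original_dm = matrix_from(None, None)
    if np.isnan(original_dm.matrix).any():
        original_dm = original_dm.imputed()
    original = neighbor_joining(original_dm)
    target_bips = tree_bipartitions(original)

    if reps == 0:
        return SupportedTree(original, {}, 0)

    rng = np.random.default_rng(seed)
    counts = {bip: 0 for bip in target_bips}
    used = 0
    n_nt = len(aln.sequences[0])
    n_codons = aln.n_codons
    for _ in range(reps):
        if distance_kind == "jc_nt":
            dm = matrix_from(None, _resample_columns(rng, n_nt))
        else:
            dm = matrix_from(_resample_columns(rng, n_codons), None)
        tree = build(dm)
        if tree is None:
            continue
        used += 1
        for bip in tree_bipartitions(tree) & target_bips:
            counts[bip] += 1
    if used == 0:
        warnings.warn("all bootstrap replicates dropped", RuntimeWarning)
        return SupportedTree(original, {}, 0)
    supports = {bip: 100.0 * c / used for bip, c in counts.items()}
    return SupportedTree(original, supports, used)


def _subset_codons(aln: CodonAlignment, cols: np.ndarray) -> CodonAlignment:
    seqs = []
    for seq in aln.sequences:
        seqs.append("".join(seq[3 * c: 3 * c + 3] for c in cols))
    return CodonAlignment(list(aln.ids), list(aln.species), seqs)


# ---------------------------------------------------------------------------
# Interspecific clade statistic


@dataclass
class ClusterStatistic:
    threshold: float
    n_clades_maximal: int
    n_clades_any: int
    n_variants: int
    variants_in_clades: int
    fraction: float
    per_pair_clades: dict[tuple[str, str], int]


def interspecific_cluster_stat(
    stree: SupportedTree,
    species_of: dict[str, str],
    threshold: float = 50.0,
    required_species: set[str] | None = None,
) -> ClusterStatistic:
    """Count supported clades containing every required species.

    For each internal edge with bootstrap support >= ``threshold`` the
    smaller bipartition side is a supported clade. Qualifying clades
    (leaf species set covering ``required_species``) are collapsed to
    maximal ones for the clade count; the variant fraction counts each
    leaf once however many qualifying clades contain it.
    """
    leaves = [lf.taxon.label for lf in stree.tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in species_of]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing[:5]}")
    if required_species is None:
        required_species = set(species_of[l] for l in leaves)

    supported = [
        clade for clade, sup in stree.supports.items() if sup >= threshold
    ]
    qualifying = [
        clade for clade in supported
        if set(species_of[l] for l in clade) >= required_species
    ]
    maximal = [
        c for c in qualifying
        if not any(c < other for other in qualifying)
    ]
    in_clades = set().union(*qualifying) if qualifying else set()

    species_present = sorted(set(species_of[l] for l in leaves))
    per_pair = {}
    for a, b in itertools.combinations(species_present, 2):
        per_pair[(a, b)] = sum(
            1 for clade in supported
            if {a, b} <= set(species_of[l] for l in clade)
        )
    return ClusterStatistic(
        threshold=threshold,
        n_clades_maximal=len(maximal),
        n_clades_any=len(qualifying),
        n_variants=len(leaves),
        variants_in_clades=len(in_clades),
        fraction=len(in_clades) / len(leaves) if leaves else 0.0,
        per_pair_clades=per_pair,
    )
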