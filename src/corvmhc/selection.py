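"""Codon-level tests for selection on the 246 bp exon-2 fragment.

Covers the Wu-Kabat site-variability profile with its 2x-mean cutoff,
pairwise Nei-Gojobori dN/dS with Jukes-Cantor correction and a
bootstrap Z test for positive selection, marginal maximum-likelihood
ancestral reconstruction under JC69, SLAC-style per-codon counting
against a neutral binomial expectation, nucleotide diversity, and
extraction of named codon partitions (Wu-Kabat polymorphic sites, the
human class-II peptide binding region mapping, their complements, and
the full fragment).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
from scipy import special, stats

from . import ng86

# ---------------------------------------------------------------------------
# Alignments and partitions


@dataclass
class CodonAlignment:
    """Species-labelled, in-frame, gap-free codon alignment."""

    ids: list[str]
    species: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.species) == len(self.sequences)):
            raise ValueError("ids, species and sequences must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self._codon_matrix = np.vstack([ng86.encode_codons(s) for s in self.sequences])

    @property
    def n_codons(self) -> int:
        return self._codon_matrix.shape[1]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def codon_matrix(self) -> np.ndarray:
        """(sequences x codons) matrix of sense-codon indices."""
        return self._codon_matrix

    def amino_acids(self) -> list[str]:
        table = np.asarray([ng86.translate_codon(c) for c in ng86.SENSE_CODONS])
        return ["".join(row) for row in table[self._codon_matrix]]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        """Read a validated-variant FASTA with ``>id|species=<name>`` headers."""
        ids, species, seqs = [], [], []
        header = None
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            name, _, rest = header.partition("|")
            sp = "unknown"
            for fieldspec in rest.split("|"):
                key, _, val = fieldspec.partition("=")
                if key == "species" and val:
                    sp = val
            ids.append(name)
            species.append(sp)
            seqs.append("".join(chunks).upper())

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    chunks = []
                elif line:
                    chunks.append(line)
        flush()
        return cls(ids, species, seqs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, sp, seq in zip(self.ids, self.species, self.sequences):
                fh.write(f">{name}|species={sp}\n{seq}\n")

    def subset(self, indices: list[int]) -> "CodonAlignment":
        return CodonAlignment(
            [self.ids[i] for i in indices],
            [self.species[i] for i in indices],
            [self.sequences[i] for i in indices],
        )


@dataclass(frozen=True)
class PartitionMask:
    """Named set of 1-based codon indices within the fragment."""

    name: str
    codons: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.codons)) != len(self.codons):
            raise ValueError("duplicate codon indices in mask")
        if self.codons and min(self.codons) < 1:
            raise ValueError("codon indices are 1-based")

    def __len__(self) -> int:
        return len(self.codons)

    def indices0(self) -> np.ndarray:
        """0-based codon column indices, sorted."""
        return np.asarray(sorted(self.codons)) - 1

    def complement(self, n_codons: int, name: str | None = None) -> "PartitionMask":
        comp = tuple(i for i in range(1, n_codons + 1) if i not in set(self.codons))
        return PartitionMask(name or f"non_{self.name}", comp)


def full_mask(n_codons: int) -> PartitionMask:
    return PartitionMask("full", tuple(range(1, n_codons + 1)))


def load_site_set(path: str | Path, name: str | None = None) -> PartitionMask:
    """Read whitespace-separated 1-based codon indices (# comments allowed)."""
    path = Path(path)
    codons: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                codons.extend(int(tok) for tok in line.split())
    return PartitionMask(name or path.stem, tuple(codons))


def hla_pbr_mask() -> PartitionMask:
    """Packaged default peptide-binding-region codon set (22 codons)."""
    ref = resources.files("corvmhc.data") / "hla_pbr_codons.txt"
    with resources.as_file(ref) as path:
        return load_site_set(path, name="HLA_PBR")


def partition_extract(aln: CodonAlignment, mask: PartitionMask) -> CodonAlignment:
    """Restrict an alignment to the mask's codon columns (order preserved)."""
    if not mask.codons:
        raise ValueError("empty partition mask")
    cols = mask.indices0()
    if cols.max() >= aln.n_codons:
        raise ValueError("mask exceeds alignment length")
    seqs = []
    for seq in aln.sequences:
        seqs.append("".join(seq[3 * c: 3 * c + 3] for c in cols))
    return CodonAlignment(list(aln.ids), list(aln.species), seqs)


# ---------------------------------------------------------------------------
# Wu-Kabat variability


@dataclass
class SiteVariabilityProfile:
    variability: np.ndarray            # pooled over all sequences
    threshold: float                   # 2 x mean of the pooled profile
    per_species: dict[str, np.ndarray]
    per_species_sites: dict[str, tuple[int, ...]]
    sites: tuple[int, ...]             # 1-based; intersection across species


def wu_kabat_column(column: list[str]) -> float:
    """Wu-Kabat variability of one residue column: k / f_max."""
    counts = {}
    for aa in column:
        if aa in "-.X*":
            raise ValueError(f"non-residue character {aa!r} in alignment column")
        counts[aa] = counts.get(aa, 0) + 1
    k = len(counts)
    f_max = max(counts.values()) / len(column)
    return k / f_max


def wu_kabat(
    aa_seqs: list[str],
    species: list[str] | None = None,
    multiplier: float = 2.0,
) -> SiteVariabilityProfile:
    """Site variability profile with the ``multiplier x mean`` cutoff.

    When species labels are given, profiles and cutoffs are computed per
    species and the reported polymorphic-site set is the intersection of
    the per-species site sets (sites highly variable in every species);
    otherwise a single pooled profile is used.
    """
    if len({len(s) for s in aa_seqs}) != 1:
        raise ValueError("unequal amino-acid sequence lengths")
    n_sites = len(aa_seqs[0])

    def profile(seqs: list[str]) -> np.ndarray:
        return np.asarray(
            [wu_kabat_column([s[i] for s in seqs]) for i in range(n_sites)]
        )

    pooled = profile(aa_seqs)
    per_species: dict[str, np.ndarray] = {}
    per_sites: dict[str, tuple[int, ...]] = {}
    if species is not None:
        for sp in sorted(set(species)):
            sub = [s for s, lab in zip(aa_seqs, species) if lab == sp]
            prof = profile(sub)
            per_species[sp] = prof
            cut = multiplier * prof.mean()
            per_sites[sp] = tuple(int(i + 1) for i in np.nonzero(prof >= cut)[0])
        sets = [set(s) for s in per_sites.values()]
        sites = tuple(sorted(set.intersection(*sets))) if sets else ()
    else:
        cut = multiplier * pooled.mean()
        sites = tuple(int(i + 1) for i in np.nonzero(pooled >= cut)[0])
    return SiteVariabilityProfile(
        variability=pooled,
        threshold=multiplier * pooled.mean(),
        per_species=per_species,
        per_species_sites=per_sites,
        sites=sites,
    )


def wuk_ps_mask(profile: SiteVariabilityProfile) -> PartitionMask:
    return PartitionMask("WuK_PS", profile.sites)


# ---------------------------------------------------------------------------
# Pairwise Nei-Gojobori


@dataclass
class PairwiseRates:
    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def dS(self) -> float:
        return ng86.jukes_cantor(self.pS)

    @property
    def dN(self) -> float:
        return ng86.jukes_cantor(self.pN)


def nei_gojobori_pair(seq1: str, seq2: str) -> PairwiseRates:
    """NG86 counts and JC-corrected rates for one codon-sequence pair."""
    i1, i2 = ng86.encode_codons(seq1), ng86.encode_codons(seq2)
    if len(i1) != len(i2):
        raise ValueError("sequences have unequal codon counts")
    s, n, sd, nd = ng86.pair_counts(i1, i2)
    return PairwiseRates(S=s, N=n, Sd=sd, Nd=nd)


def _pair_codon_arrays(aln: CodonAlignment, cols: np.ndarray):
    """Per-(pair, codon) Sd/Nd and pair-averaged potential S/N arrays."""
    t = ng86.counting_tables()
    mat = aln.codon_matrix[:, cols]
    pairs = list(itertools.combinations(range(aln.n_sequences), 2))
    ii = np.asarray([p[0] for p in pairs])
    jj = np.asarray([p[1] for p in pairs])
    sd = t.sd[mat[ii], mat[jj]]                      # (pairs, codons)
    nd = t.nd[mat[ii], mat[jj]]
    s_pot = 0.5 * (t.s_pot[mat[ii]] + t.s_pot[mat[jj]])
    n_pot = 0.5 * (t.n_pot[mat[ii]] + t.n_pot[mat[jj]])
    return sd, nd, s_pot, n_pot


def _mean_rates(sd, nd, s_pot, n_pot) -> tuple[float, float]:
    """Mean pairwise dN and dS given per-(pair, codon) arrays (NaN-aware)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = sd.sum(axis=-1) / s_pot.sum(axis=-1)
        pn = nd.sum(axis=-1) / n_pot.sum(axis=-1)
    ds = ng86.jukes_cantor(ps)
    dn = ng86.jukes_cantor(pn)
    return float(np.nanmean(dn)), float(np.nanmean(ds))


@dataclass
class ZTestResult:
    mean_dn: float
    mean_ds: float
    z: float
    p_value: float
    boot_reps: int


def z_test_selection(
    aln: CodonAlignment,
    mask: PartitionMask,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> ZTestResult:
    """Codon-based Z test of positive selection (dN > dS) over a partition.

    Mean dN and dS are taken over all sequence pairs restricted to the
    mask's codons; the standard error of their difference comes from a
    seeded codon-site bootstrap and the one-tailed p-value from the
    normal upper tail. Identical alignments (zero variance) report p=1.
    """
    if aln.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    if len(mask) < 3:
        raise ValueError("mask smaller than 3 codons: variance unstable")
    cols = mask.indices0()
    sd, nd, s_pot, n_pot = _pair_codon_arrays(aln, cols)
    mean_dn, mean_ds = _mean_rates(sd, nd, s_pot, n_pot)

    rng = np.random.default_rng(seed)
    n_codons = len(cols)
    diffs = np.empty(boot_reps)
    for b in range(boot_reps):
        pick = rng.integers(0, n_codons, size=n_codons)
        bdn, bds = _mean_rates(sd[:, pick], nd[:, pick], s_pot[:, pick], n_pot[:, pick])
        diffs[b] = bdn - bds
    se = float(np.nanstd(diffs, ddof=1))
    if not np.isfinite(se) or se == 0.0:
        return ZTestResult(mean_dn, mean_ds, float("nan"), 1.0, boot_reps)
    z = (mean_dn - mean_ds) / se
    p = float(stats.norm.sf(z))
    return ZTestResult(mean_dn, mean_ds, float(z), p, boot_reps)


# ---------------------------------------------------------------------------
# Ancestral reconstruction (JC69 marginal ML)

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_NTS = "ACGT"


def _jc_pmatrix(t: float) -> np.ndarray:
    t = max(t, 0.0)
    same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * math.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def ancestral_codons(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    method: str = "ml",
) -> dict[str, str]:
    """Reconstruct internal-node sequences, reassembled into codons.

    ``ml`` runs per-nucleotide-site marginal maximum likelihood under
    JC69 with a uniform prior (two-pass message passing); near-ties are
    broken toward the parent's reconstructed state, then alphabetically
    (both choices minimise implied changes in the tied set).
    ``parsimony`` uses Fitch states resolved the same way. Internal
    nodes gain ``anc_seq`` annotations; the returned dict maps internal
    node labels (assigned ``anc<i>`` when unlabelled) to sequences.
    """
    leaves = {lf.taxon.label: i for i, lf in enumerate(tree.leaf_node_iter())}
    if set(leaves) != set(aln.ids):
        raise ValueError("tree leaves do not match alignment ids")
    seq_by_id = dict(zip(aln.ids, aln.sequences))
    n_sites = len(aln.sequences[0])

    onehot = {}
    for label in leaves:
        arr = np.zeros((n_sites, 4))
        for s, base in enumerate(seq_by_id[label]):
            arr[s, _NT_INDEX[base]] = 1.0
        onehot[label] = arr

    if method not in {"ml", "parsimony"}:
        raise ValueError(f"unknown method {method!r}")

    # postorder partial likelihoods (ml) or Fitch sets (parsimony)
    partial: dict[int, np.ndarray] = {}
    pmat: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partial[id(node)] = onehot[node.taxon.label]
        else:
            prod = np.ones((n_sites, 4))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                pm = _jc_pmatrix(t)
                pmat[id(child)] = pm
                prod = prod * (partial[id(child)] @ pm.T)
            m = prod.max(axis=1, keepdims=True)
            m[m == 0.0] = 1.0
            partial[id(node)] = prod / m  # rescaled; argmax structure preserved

    if method == "parsimony":
        # Fitch sets encoded as 0/1 vectors
        fitch: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                fitch[id(node)] = onehot[node.taxon.label] > 0
            else:
                kids = [fitch[id(c)] for c in node.child_nodes()]
                inter = np.logical_and.reduce(kids)
                union = np.logical_or.reduce(kids)
                fitch[id(node)] = np.where(inter.any(axis=1, keepdims=True), inter, union)

    # preorder outside messages
    outside: dict[int, np.ndarray] = {id(tree.seed_node): np.full((n_sites, 4), 0.25)}
    marginal: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent = node.parent_node
            msg = outside[id(parent)].copy()
            for sib in parent.child_nodes():
                if sib is not node:
                    msg = msg * (partial[id(sib)] @ pmat[id(sib)].T)
            msg = msg @ pmat[id(node)]
            m = msg.max(axis=1, keepdims=True)
            m[m == 0.0] = 1.0
            outside[id(node)] = msg / m
        if not node.is_leaf():
            if method == "ml":
                marginal[id(node)] = outside[id(node)] * partial[id(node)]
            else:
                marginal[id(node)] = fitch[id(node)].astype(float)

    result: dict[str, str] = {}
    counter = 0
    parent_seq: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        post = marginal[id(node)]
        best = post.max(axis=1, keepdims=True)
        tied = post >= best * (1.0 - 1e-9)
        pseq = parent_seq.get(id(node.parent_node)) if node.parent_node else None
        chars = []
        for s in range(n_sites):
            options = [b for b in range(4) if tied[s, b]]
            if pseq is not None and _NT_INDEX[pseq[s]] in options:
                chars.append(pseq[s])
            else:
                chars.append(_NTS[options[0]])
        seq = "".join(chars)
        label = node.label or f"anc{counter}"
        counter += 1
        node.label = label
        node.annotations["anc_seq"] = seq
        parent_seq[id(node)] = seq
        result[label] = seq
    return result


# ---------------------------------------------------------------------------
# SLAC-style per-codon counting


@dataclass
class CodonSelectionResult:
    codon: int                 # 1-based
    Sd: float
    Nd: float
    pn_expected: float
    dn_minus_ds: float
    p_value: float
    positively_selected: bool


def _codon_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) tolerating stop codons at the endpoints."""
    if c1 == c2:
        return 0.0, 0.0
    return ng86.pathway_differences(c1, c2)


def slac_per_codon(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    ancestors: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[CodonSelectionResult]:
    """Per-codon counting test with reconstructed ancestral states.

    Substitutions on every branch are resolved into synonymous and
    nonsynonymous counts by pathway averaging; each codon's observed
    (Sd, Nd) is compared with the neutral expectation
    ``pN = N / (N + S)`` (potential sites averaged over all node states
    at that codon) through a one-tailed extended binomial test for an
    excess of nonsynonymous change.
    """
    if ancestors is None:
        ancestors = ancestral_codons(tree, aln)
    seq_by_id = dict(zip(aln.ids, aln.sequences))

    def node_seq(node) -> str:
        if node.is_leaf():
            return seq_by_id[node.taxon.label]
        return ancestors[node.label]

    n_codons = aln.n_codons
    sd_tot = np.zeros(n_codons)
    nd_tot = np.zeros(n_codons)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        child = node_seq(node)
        parent = node_seq(node.parent_node)
        for k in range(n_codons):
            c1, c2 = parent[3 * k: 3 * k + 3], child[3 * k: 3 * k + 3]
            if c1 != c2:
                s, d = _codon_pathway_counts(c1, c2)
                sd_tot[k] += s
                nd_tot[k] += d

    # potential sites averaged over all node states per codon
    states: list[str] = [node_seq(nd) for nd in tree.preorder_node_iter()]
    results = []
    for k in range(n_codons):
        pots = [ng86.potential_sites(seq[3 * k: 3 * k + 3]) for seq in states]
        s_pot = float(np.mean([p[0] for p in pots]))
        n_pot = float(np.mean([p[1] for p in pots]))
        pn_exp = n_pot / (n_pot + s_pot)
        sd, nd_ = sd_tot[k], nd_tot[k]
        total = sd + nd_
        dn = nd_ / n_pot if n_pot > 0 else 0.0
        ds = sd / s_pot if s_pot > 0 else 0.0
        if total == 0:
            p = 1.0
        else:
            # P(X >= Nd | n = Sd+Nd, pn_exp), extended to fractional counts
            if nd_ <= 0:
                p = 1.0
            else:
                p = float(special.betainc(nd_, total - nd_ + 1.0, pn_exp))
        results.append(
            CodonSelectionResult(
                codon=k + 1,
                Sd=float(sd),
                Nd=float(nd_),
                pn_expected=pn_exp,
                dn_minus_ds=dn - ds,
                p_value=p,
                positively_selected=bool(p <= alpha and dn - ds > 0),
            )
        )
    return results


def positively_selected_mask(results: list[CodonSelectionResult]) -> PartitionMask:
    return PartitionMask(
        "PSS", tuple(r.codon for r in results if r.positively_selected)
    )


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class DiversityResult:
    value: float
    se: float
    mode: str


def nucleotide_diversity(
    aln: CodonAlignment,
    mask: PartitionMask | None = None,
    mode: str = "nucleotide",
    boot_reps: int = 200,
    seed: int | None = None,
) -> DiversityResult:
    """Mean pairwise diversity over a codon partition.

    ``nucleotide``: per-site p-distance averaged over all pairs;
    ``synonymous`` / ``nonsynonymous``: mean pairwise pS / pN (NG86
    proportions). Standard errors by seeded site (codon) bootstrap.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    cols = (mask or full_mask(aln.n_codons)).indices0()
    rng = np.random.default_rng(seed)
    sd, nd, s_pot, n_pot = _pair_codon_arrays(aln, cols)

    if mode == "nucleotide":
        # p-distance uses raw mismatch counts per site, not pathway averages
        t_mat = aln.codon_matrix[:, cols]
        codons = np.asarray(ng86.SENSE_CODONS)
        # expand to nucleotide characters
        chars = np.array([[c[0], c[1], c[2]] for c in codons])
        nt = chars[t_mat].reshape(aln.n_sequences, -1)  # (seqs, 3*codons)
        pairs = list(itertools.combinations(range(aln.n_sequences), 2))
        ii = np.asarray([p[0] for p in pairs])
        jj = np.asarray([p[1] for p in pairs])
        mismatch = (nt[ii] != nt[jj])                    # (pairs, sites)
        value = float(mismatch.mean())
        boots = np.empty(boot_reps)
        n_sites = mismatch.shape[1]
        for b in range(boot_reps):
            pick = rng.integers(0, n_sites, size=n_sites)
            boots[b] = mismatch[:, pick].mean()
        return DiversityResult(value, float(boots.std(ddof=1)), mode)

    if mode == "synonymous":
        num, den = sd, s_pot
    elif mode == "nonsynonymous":
        num, den = nd, n_pot
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        value = float(np.nanmean(num.sum(axis=1) / den.sum(axis=1)))
    boots = np.empty(boot_reps)
    n_c = num.shape[1]
    for b in range(boot_reps):
        pick = rng.integers(0, n_c, size=n_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = np.nanmean(num[:, pick].sum(axis=1) / den[:, pick].sum(axis=1))
    return DiversityResult(value, float(np.nanstd(boots, ddof=1)), mode)


def amino_acid_p_distance(aa_seqs: list[str]) -> float:
    """Mean pairwise amino-acid p-distance (pairwise deletion of gaps/X)."""
    if len({len(s) for s in aa_seqs}) != 1:
        raise ValueError("unequal sequence lengths")
    dists = []
    for a, b in itertools.combinations(aa_seqs, 2):
        valid = [(x, y) for x, y in zip(a, b) if x not in "-X?" and y not in "-X?"]
        if not valid:
            continue
        dists.append(sum(x != y for x, y in valid) / len(valid))
    return float(np.mean(dists))
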