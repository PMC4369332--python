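"""Synthetic allele histories and pyrosequencing reads.

Generates species-labelled exon-2 allele pools under three scenarios —

``tsp``
    Ancestral allelic classes arise before the species splits; every
    species inherits every class. Class lineages carry both diagnostic
    selected-site motifs and accumulated neutral-site divergence, so
    alleles cluster by class (interspecifically) at selected *and*
    neutral sites. Post-split drift and within-species gene conversion
    slowly erode the signal.

``convergence``
    Species diverge independently at neutral sites after the splits;
    selected-site amino-acid motifs are then drawn from a motif set
    shared across species and realised with per-allele random synonymous
    codon choices. Alleles cluster interspecifically at selected sites
    (nonsynonymously) only.

``null``
    Pure species-level divergence at every site.

A forward, class-structured model is used rather than a coalescent with
balancing selection: the pipeline's discriminating signal (selected- vs
neutral-partition concordance) depends only on the class structure.

Read simulation reproduces the amplicon artifact model: log-normal
amplification bias spanning about one order of magnitude across
variants, PCR chimeras at a configurable per-read rate, per-base
substitution errors calibrated from a per-read error rate for a 171 bp
fragment, a small indel channel (dropped downstream by the length
gate), and double-tag wrapping with MIDs and primers in random
orientation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import ng86
from .amplicon_io import IUPAC_SETS, SequenceRead, TagEntry, TagScheme
from .selection import CodonAlignment

DEFAULT_SELECTED_CODONS = (6, 23, 25, 32, 33, 52, 61, 62, 65, 73, 81)
DEFAULT_SPECIES = ("spA", "spB", "spC")

_PRIMER_F = "GCACGAGCAGGATTACTACAA"
_PRIMER_R = "TGTCCACYGTGACCAGATACA"  # one degenerate position (Y)


# ---------------------------------------------------------------------------
# Allele pools


@dataclass
class AlleleSimConfig:
    scenario: str = "tsp"                       # {"tsp", "convergence", "null"}
    n_species: int = 3
    n_classes: int = 6
    alleles_per_class: int = 4                  # per species
    n_codons: int = 82
    selected_codons: tuple[int, ...] = DEFAULT_SELECTED_CODONS
    class_divergence: float = 0.12              # subst / neutral nt on class branches (tsp)
    species_divergence: float = 0.012           # subst / neutral nt on species branches
    post_split_drift: float = 0.005             # subst / neutral nt per allele
    motif_alphabet_size: int = 4                # residues available per selected site
    gene_conversion_rate: float = 0.3           # events per allele within species
    gc_mean_tract: float = 100.0                # nt, geometric tract length
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in {"tsp", "convergence", "null"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(not 1 <= c <= self.n_codons for c in self.selected_codons):
            raise ValueError("selected codons outside fragment")
        for rate in (self.class_divergence, self.species_divergence,
                     self.post_split_drift, self.gene_conversion_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class Allele:
    allele_id: str
    species: str
    sequence: str
    class_label: int


@dataclass
class AllelePool:
    alleles: list[Allele]
    selected_codons: tuple[int, ...]
    scenario: str

    def by_species(self) -> dict[str, list[Allele]]:
        out: dict[str, list[Allele]] = {}
        for a in self.alleles:
            out.setdefault(a.species, []).append(a)
        return out

    def to_alignment(self) -> CodonAlignment:
        return CodonAlignment(
            [a.allele_id for a in self.alleles],
            [a.species for a in self.alleles],
            [a.sequence for a in self.alleles],
        )

    def to_fasta(self, path) -> None:
        self.to_alignment().to_fasta(path)


@dataclass
class SimTruth:
    scenario: str
    selected_codons: tuple[int, ...]
    class_of_allele: dict[str, int] = field(default_factory=dict)
    genotypes: dict[str, dict[str, int]] = field(default_factory=dict)
    expected_depth: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


def _random_sense_codon(rng: np.random.Generator, aa: str | None = None) -> str:
    if aa is None:
        return ng86.SENSE_CODONS[rng.integers(len(ng86.SENSE_CODONS))]
    options = [c for c in ng86.SENSE_CODONS if ng86.translate_codon(c) == aa]
    return options[rng.integers(len(options))]


def _mutate_neutral(seq: str, n_mut: int, neutral_nt: np.ndarray,
                    rng: np.random.Generator) -> str:
    """Apply random substitutions at neutral nucleotide sites, never
    creating an in-frame stop (blocked draws are resampled)."""
    chars = list(seq)
    applied = 0
    guard = 0
    while applied < n_mut and guard < 50 * (n_mut + 1):
        guard += 1
        pos = int(neutral_nt[rng.integers(len(neutral_nt))])
        old = chars[pos]
        new = "ACGT"[rng.integers(4)]
        if new == old:
            continue
        codon_start = 3 * (pos // 3)
        codon = chars[codon_start:codon_start + 3]
        codon[pos - codon_start] = new
        if ng86.is_stop("".join(codon)):
            continue
        chars[pos] = new
        applied += 1
    return "".join(chars)


def _neutral_nt_positions(n_codons: int, selected: tuple[int, ...]) -> np.ndarray:
    sel = set(selected)
    return np.asarray(
        [3 * c + k for c in range(n_codons) if (c + 1) not in sel for k in range(3)]
    )


def _motif_set(rng: np.random.Generator, n_motifs: int, n_sites: int,
               alphabet_size: int) -> list[str]:
    """Distinct amino-acid motifs over a per-site constrained alphabet."""
    aas = [a for a in "ACDEFGHIKLMNPQRSTVWY"]
    per_site = [rng.choice(aas, size=alphabet_size, replace=False) for _ in range(n_sites)]
    motifs: set[str] = set()
    guard = 0
    while len(motifs) < n_motifs and guard < 1000:
        guard += 1
        motifs.add("".join(site[rng.integers(alphabet_size)] for site in per_site))
    if len(motifs) < n_motifs:
        raise RuntimeError("could not build enough distinct motifs")
    return sorted(motifs)


def _install_motif(seq: str, motif: str, selected: tuple[int, ...],
                   rng: np.random.Generator) -> str:
    chars = list(seq)
    for aa, codon_pos in zip(motif, selected):
        codon = _random_sense_codon(rng, aa)
        chars[3 * (codon_pos - 1): 3 * codon_pos] = list(codon)
    return "".join(chars)


def _enforce_distinct(seqs: list[str], neutral_nt: np.ndarray,
                      rng: np.random.Generator, min_diff: int = 2) -> list[str]:
    """Nudge within-species alleles apart until no pair differs by exactly
    1..min_diff-1 nucleotides. Identical alleles are left alone (they are
    real: the same allele shared across loci); 1-nt neighbours are not
    observable under the distinctness rule of the genotyping protocol, so
    the pool, like the study's variant catalogue, never contains them."""
    seqs = list(seqs)
    for _ in range(100):
        dirty = False
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                if 0 < d < min_diff:
                    seqs[j] = _mutate_neutral(seqs[j], min_diff - d, neutral_nt, rng)
                    dirty = True
        if not dirty:
            return seqs
    raise RuntimeError("could not separate alleles to the minimum distance")


def _gene_conversion(alleles: list[str], rate: float, mean_tract: float,
                     rng: np.random.Generator) -> list[str]:
    """Within-species nonreciprocal tract copying between random allele pairs."""
    n = len(alleles)
    if n < 2 or rate <= 0:
        return alleles
    seqs = list(alleles)
    n_events = rng.poisson(rate * n)
    length = len(seqs[0])
    for _ in range(n_events):
        donor, recip = rng.choice(n, size=2, replace=False)
        start = int(rng.integers(length))
        tract = int(rng.geometric(1.0 / mean_tract))
        end = min(length, start + tract)
        candidate = seqs[recip][:start] + seqs[donor][start:end] + seqs[recip][end:]
        try:
            ng86.encode_codons(candidate)
        except ValueError:
            continue  # conversion would create a stop across a codon boundary
        seqs[recip] = candidate
    return seqs


def simulate_allele_pools(config: AlleleSimConfig) -> tuple[AllelePool, SimTruth]:
    """Generate the species-labelled allele pool for one scenario."""
    rng = np.random.default_rng(config.seed)
    species = DEFAULT_SPECIES[: config.n_species]
    neutral_nt = _neutral_nt_positions(config.n_codons, config.selected_codons)
    n_neutral = len(neutral_nt)

    root = "".join(_random_sense_codon(rng) for _ in range(config.n_codons))
    motifs = _motif_set(rng, config.n_classes, len(config.selected_codons),
                        config.motif_alphabet_size)

    truth = SimTruth(config.scenario, config.selected_codons)
    alleles: list[Allele] = []

    if config.scenario == "tsp":
        # ancestral classes predate the splits: motif + neutral divergence
        class_haps = []
        for c in range(config.n_classes):
            hap = _install_motif(root, motifs[c], config.selected_codons, rng)
            hap = _mutate_neutral(
                hap, rng.poisson(config.class_divergence * n_neutral), neutral_nt, rng
            )
            class_haps.append(hap)
        for sp in species:
            sp_alleles: list[str] = []
            labels: list[int] = []
            for c, hap in enumerate(class_haps):
                sp_hap = _mutate_neutral(
                    hap, rng.poisson(config.species_divergence * n_neutral),
                    neutral_nt, rng,
                )
                for _ in range(config.alleles_per_class):
                    a = _mutate_neutral(
                        sp_hap, rng.poisson(config.post_split_drift * n_neutral),
                        neutral_nt, rng,
                    )
                    sp_alleles.append(a)
                    labels.append(c)
            sp_alleles = _gene_conversion(
                sp_alleles, config.gene_conversion_rate, config.gc_mean_tract, rng
            )
            sp_alleles = _enforce_distinct(sp_alleles, neutral_nt, rng)
            for i, (seq, lab) in enumerate(zip(sp_alleles, labels)):
                aid = f"{sp}_v{i + 1:03d}"
                alleles.append(Allele(aid, sp, seq, lab))
                truth.class_of_allele[aid] = lab
    else:
        for sp in species:
            backbone = _mutate_neutral(
                root, rng.poisson(config.species_divergence * n_neutral),
                neutral_nt, rng,
            )
            if config.scenario == "null":
                # species-level divergence at selected sites too
                sel_nt = np.asarray(sorted(set(range(3 * config.n_codons)) - set(neutral_nt)))
                backbone = _mutate_neutral(
                    backbone,
                    rng.poisson(config.species_divergence * len(sel_nt)),
                    sel_nt, rng,
                )
            sp_alleles, labels = [], []
            n_alleles = config.n_classes * config.alleles_per_class
            for i in range(n_alleles):
                a = _mutate_neutral(
                    backbone, rng.poisson(config.post_split_drift * n_neutral),
                    neutral_nt, rng,
                )
                if config.scenario == "convergence":
                    # balancing selection maintains every shared motif in
                    # every species; alleles cycle through the motif set
                    c = i % config.n_classes
                    a = _install_motif(a, motifs[c], config.selected_codons, rng)
                else:
                    c = -1
                sp_alleles.append(a)
                labels.append(c)
            sp_alleles = _gene_conversion(
                sp_alleles, config.gene_conversion_rate, config.gc_mean_tract, rng
            )
            sp_alleles = _enforce_distinct(sp_alleles, neutral_nt, rng)
            for i, (seq, lab) in enumerate(zip(sp_alleles, labels)):
                aid = f"{sp}_v{i + 1:03d}"
                alleles.append(Allele(aid, sp, seq, lab))
                truth.class_of_allele[aid] = lab

    pool = AllelePool(alleles, config.selected_codons, config.scenario)
    return pool, truth


# ---------------------------------------------------------------------------
# Individuals


@dataclass
class IndividualGenotype:
    sample_id: str
    species: str
    copies: dict[str, int]          # variant sequence -> copy number
    variant_ids: dict[str, str]     # variant sequence -> pool allele id

    @property
    def n_variants(self) -> int:
        return len(self.copies)


def simulate_individuals(
    pool: AllelePool,
    n_individuals: int = 18,
    loci_range: tuple[int, int] = (6, 10),
    seed: int | None = None,
) -> list[IndividualGenotype]:
    """Draw diploid multi-locus genotypes from each species' allele pool.

    Each individual carries L loci (uniform over ``loci_range``); each
    haplotype is an L-subset of the species pool drawn without
    replacement, so realised distinct-variant counts land in roughly
    7-20 at the defaults.
    """
    rng = np.random.default_rng(seed)
    out: list[IndividualGenotype] = []
    for sp, sp_alleles in sorted(pool.by_species().items()):
        seqs = [a.sequence for a in sp_alleles]
        ids = [a.allele_id for a in sp_alleles]
        for i in range(n_individuals):
            loci = int(rng.integers(loci_range[0], loci_range[1] + 1))
            if len(seqs) < loci:
                raise ValueError("allele pool too small for requested locus count")
            hap1 = rng.choice(len(seqs), size=loci, replace=False)
            hap2 = rng.choice(len(seqs), size=loci, replace=False)
            copies: dict[str, int] = {}
            vids: dict[str, str] = {}
            for idx in list(hap1) + list(hap2):
                seq = seqs[idx]
                copies[seq] = copies.get(seq, 0) + 1
                vids[seq] = ids[idx]
            out.append(IndividualGenotype(f"{sp}_ind{i + 1:02d}", sp, copies, vids))
    return out


# ---------------------------------------------------------------------------
# Reads


@dataclass
class AmpliconSimConfig:
    reads_per_replicate: int = 600
    replicates: int = 2
    per_base_error: float = 0.11 / 171.0
    chimera_rate: float = 0.06
    indel_rate: float = 0.02
    bias_sigma: float = math.log(10.0) / 3.29   # 5th-95th pct weight ratio ~ 10x
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.per_base_error, self.chimera_rate, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 PCR replicates for validation")


def make_tag_scheme(sample_ids: list[str], replicates: int = 2,
                    seed: int | None = None) -> TagScheme:
    """Random distinct 10-mer MIDs for every (sample, replicate)."""
    rng = np.random.default_rng(seed)
    used: set[tuple[str, str]] = set()
    entries = {}
    for sample in sample_ids:
        for rep in range(1, replicates + 1):
            while True:
                mid_f = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
                mid_r = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
                if (mid_f, mid_r) not in used:
                    used.add((mid_f, mid_r))
                    break
            entries[(sample, rep)] = TagEntry(mid_f, mid_r, _PRIMER_F, _PRIMER_R)
    return TagScheme(entries)


def _concretise(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b in "ACGT" else sorted(IUPAC_SETS[b])[rng.integers(len(IUPAC_SETS[b]))]
        for b in pattern
    )


def _reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(comp[b] for b in reversed(seq))


def simulate_amplicon_reads(
    genotype: IndividualGenotype,
    scheme: TagScheme,
    config: AmpliconSimConfig,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> dict[int, list[SequenceRead]]:
    """Simulate tagged reads for both PCR replicates of one individual.

    Per replicate, variant sampling weights are copy number times an
    independently redrawn log-normal bias factor. Each read may be a
    two-parent chimera (uniform breakpoint), may lose one base through
    the indel channel, and has every base flipped independently at the
    per-base error rate; it is then wrapped in the replicate's MID and
    primer (degenerate positions concretised) and emitted on a random
    strand. Expected error-free depths and full per-read provenance are
    recorded on ``truth`` when given.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variants = sorted(genotype.copies)
    copy_numbers = np.asarray([genotype.copies[v] for v in variants], dtype=float)
    L = len(variants[0])
    reads_by_rep: dict[int, list[SequenceRead]] = {}
    if truth is not None:
        truth.genotypes[genotype.sample_id] = dict(genotype.copies)
        truth.expected_depth[genotype.sample_id] = {
            v: [] for v in variants
        }

    for rep in range(1, config.replicates + 1):
        entry = scheme.entries[(genotype.sample_id, rep)]
        bias = rng.lognormal(mean=0.0, sigma=config.bias_sigma, size=len(variants))
        weights = copy_numbers * bias
        weights = weights / weights.sum()
        p_clean = (
            (1.0 - config.chimera_rate)
            * (1.0 - config.indel_rate)
            * (1.0 - config.per_base_error) ** L
        )
        if truth is not None:
            for v, w in zip(variants, weights):
                truth.expected_depth[genotype.sample_id][v].append(
                    float(config.reads_per_replicate * w * p_clean)
                )
        reads: list[SequenceRead] = []
        choices = rng.choice(len(variants), size=config.reads_per_replicate, p=weights)
        for ridx, vi in enumerate(choices):
            target = variants[vi]
            prov = {
                "read_id": f"{genotype.sample_id}_r{rep}_{ridx}",
                "sample": genotype.sample_id,
                "replicate": rep,
                "source": genotype.variant_ids[variants[vi]],
                "chimera": None,
                "indel": False,
                "n_errors": 0,
            }
            if rng.random() < config.chimera_rate:
                vj = int(rng.integers(len(variants)))
                bp = int(rng.integers(1, L))
                target = variants[vi][:bp] + variants[vj][bp:]
                prov["chimera"] = {
                    "parent2": genotype.variant_ids[variants[vj]],
                    "breakpoint": bp,
                }
            if rng.random() < config.indel_rate:
                pos = int(rng.integers(len(target)))
                target = target[:pos] + target[pos + 1:]
                prov["indel"] = True
            n_err = rng.binomial(len(target), config.per_base_error)
            if n_err:
                chars = list(target)
                for pos in rng.choice(len(chars), size=n_err, replace=False):
                    alternatives = [b for b in "ACGT" if b != chars[pos]]
                    chars[pos] = alternatives[rng.integers(3)]
                target = "".join(chars)
                prov["n_errors"] = int(n_err)
            full = (
                entry.mid_fwd + _concretise(entry.primer_fwd, rng) + target
                + _reverse_complement(_concretise(entry.primer_rev, rng))
                + _reverse_complement(entry.mid_rev)
            )
            if rng.random() < 0.5:
                full = _reverse_complement(full)
            reads.append(SequenceRead(prov["read_id"], full, [30] * len(full)))
            if truth is not None:
                truth.provenance.append(prov)
        reads_by_rep[rep] = reads
    return reads_by_rep
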