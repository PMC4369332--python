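"""Variant validation and genotyping of replicated amplicon bins.

The validation scheme addresses the two artifact classes that survive
read binning: polymerase substitution errors and PCR chimeras. A
candidate variant is accepted only when it is seen in at least ``r_min``
reads in *both* of two independent PCRs of the same individual, and when
it differs by at least ``min_nt_diff`` substitutions from every more
common accepted variant. Identical artifacts are vanishingly unlikely to
recur at depth in two independent amplifications, so the dual-replicate
rule removes chimeras without frequency cutoffs that would also remove
rare true alleles.

``min_reads_exact`` answers the design question "how many reads does an
amplicon need so that each of m co-amplified variants is seen at least r
times with a given confidence" by direct multinomial computation
(inclusion-exclusion over depleted categories), with a seeded Monte
Carlo cross-check and a linear-extrapolation mode for comparison.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass
class VariantCandidate:
    """A deduplicated sequence with read counts from two PCR replicates."""

    sequence: str
    count_rep1: int
    count_rep2: int

    def __post_init__(self) -> None:
        if self.count_rep1 < 0 or self.count_rep2 < 0:
            raise ValueError("replicate counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.count_rep1 + self.count_rep2


@dataclass
class GenotypeCall:
    sample_id: str
    variants: list[str]
    net_reads: int
    status: str  # "genotyped" | "insufficient_depth"


@dataclass
class DepthRequirement:
    m: int
    r: int
    confidence: float
    n_min: int
    method: str
    probability_at_n_min: float


def collapse_reads(
    bin_seqs: list[str],
    expected_len_range: tuple[int, int],
) -> tuple[list[tuple[str, int]], int]:
    """Deduplicate a demultiplexed bin; drop out-of-length sequences.

    The length gate is the proxy for indel removal: reads carrying
    homopolymer indels (or chimera-induced length changes) no longer fit
    the expected target length. Returns ``([(sequence, count), ...],
    dropped_count)`` with counts summing to the retained reads.
    """
    lo, hi = expected_len_range
    counts = Counter()
    dropped = 0
    for seq in bin_seqs:
        if lo <= len(seq) <= hi:
            counts[seq] += 1
        else:
            dropped += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked, dropped


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length (alignment assumed gap-free)")
    return sum(x != y for x, y in zip(a, b))


def validate_variants(
    candidates: list[VariantCandidate],
    r_min: int = 3,
    min_nt_diff: int = 2,
) -> tuple[list[str], int]:
    """Apply the dual-replicate and nucleotide-distinctness rules.

    Step 1 keeps candidates with ``count_rep1 >= r_min`` and
    ``count_rep2 >= r_min``; net reads is the summed total count of these
    survivors. Step 2 walks survivors in descending total count (ties
    broken lexicographically) and discards any candidate closer than
    ``min_nt_diff`` substitutions to an already accepted, more common
    variant.
    """
    survivors = [c for c in candidates if c.count_rep1 >= r_min and c.count_rep2 >= r_min]
    net_reads = sum(c.total for c in survivors)
    accepted: list[str] = []
    for cand in sorted(survivors, key=lambda c: (-c.total, c.sequence)):
        if all(hamming(cand.sequence, acc) >= min_nt_diff for acc in accepted):
            accepted.append(cand.sequence)
    return accepted, net_reads


def genotype_sample(
    sample_id: str,
    validated: list[str],
    net_reads: int,
    min_net_reads: int = 275,
) -> GenotypeCall:
    """Call the genotype if amplicon depth reaches ``min_net_reads``."""
    status = "genotyped" if net_reads >= min_net_reads else "insufficient_depth"
    return GenotypeCall(sample_id, list(validated), net_reads, status)


def threshold_frequency(r: int = 3, net_reads: int = 275) -> float:
    """Frequency represented by an r-copy variant at the depth threshold."""
    return r / net_reads


def loci_per_haplotype(max_variants: int) -> int:
    """Minimum locus count consistent with ``max_variants`` per diploid amplicon."""
    if max_variants < 1:
        raise ValueError("max_variants must be >= 1")
    return math.ceil(max_variants / 2)


def prob_all_sampled(n: int, m: int, r: int) -> float:
    """P(each of m equiprobable variants drawn >= r times in n multinomial draws).

    Inclusion-exclusion over the events "category i seen fewer than r
    times". For a fixed set of j depleted categories the joint
    probability is a finite sum over their total count t, with the
    composition weights read off the coefficients of
    ``(sum_{k<r} x^k / k!)^j``.
    """
    if n < m * r:
        return 0.0
    # coefficients g[t] of (sum_{k=0}^{r-1} x^k/k!)^j, built incrementally
    base = [1.0 / math.factorial(k) for k in range(r)]
    g = [1.0]  # j = 0
    terms = []
    log_m = math.log(m)
    for j in range(m + 1):
        if j > 0:
            new = [0.0] * (len(g) + r - 1)
            for t, gt in enumerate(g):
                for k, bk in enumerate(base):
                    new[t + k] += gt * bk
            g = new
        # A_j = sum_t g[t] * n!/(n-t)! * (1/m)^t * ((m-j)/m)^(n-t)
        a_j = 0.0
        for t, gt in enumerate(g):
            if t > n or gt == 0.0:
                continue
            if m - j == 0:
                if t != n:
                    continue
                log_tail = 0.0
            else:
                log_tail = (n - t) * (math.log(m - j) - log_m)
            log_term = (
                math.lgamma(n + 1) - math.lgamma(n - t + 1) - t * log_m + log_tail
            )
            a_j += gt * math.exp(log_term)
        terms.append(((-1) ** j) * math.comb(m, j) * a_j)
    p = math.fsum(terms)
    return min(1.0, max(0.0, p))


def prob_all_sampled_mc(
    n: int, m: int, r: int, reps: int = 100_000, seed: int | None = None
) -> float:
    """Monte Carlo estimate of :func:`prob_all_sampled` (seeded)."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, [1.0 / m] * m, size=reps)
    return float(np.mean((counts >= r).all(axis=1)))


def min_reads_exact(
    m: int,
    r: int,
    confidence: float,
    method: str = "exact",
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> DepthRequirement:
    """Smallest n with P(all m variants sampled >= r times) >= confidence.

    ``method='exact'`` uses the closed inclusion-exclusion sum;
    ``'monte_carlo'`` brackets the same probability by seeded simulation;
    ``'extrapolate_linear'`` fits n_min against m over m <= 8 at the same
    r and confidence and extrapolates (an approximation of historical
    practice, kept for comparison).
    """
    if m < 1 or r < 1 or not (0.0 < confidence < 1.0):
        raise ValueError("require m >= 1, r >= 1, 0 < confidence < 1")

    if method == "extrapolate_linear":
        ms = list(range(2, 9))
        ns = [min_reads_exact(mm, r, confidence, method="exact").n_min for mm in ms]
        slope, intercept = np.polyfit(ms, ns, 1)
        n_lin = int(math.ceil(slope * m + intercept))
        return DepthRequirement(m, r, confidence, n_lin, method, float("nan"))

    if method == "exact" and m * r > 2000:
        warnings.warn(
            "m*r too large for the exact computation; falling back to monte_carlo",
            RuntimeWarning,
        )
        method = "monte_carlo"

    if method == "exact":
        prob = lambda n: prob_all_sampled(n, m, r)  # noqa: E731
    elif method == "monte_carlo":
        prob = lambda n: prob_all_sampled_mc(n, m, r, mc_reps, seed)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")

    lo = m * r
    hi = lo
    while prob(hi) < confidence:
        hi = max(hi + 1, int(hi * 1.5))
    while lo < hi:
        mid = (lo + hi) // 2
        if prob(mid) >= confidence:
            hi = mid
        else:
            lo = mid + 1
    return DepthRequirement(m, r, confidence, lo, method, prob(lo))


@dataclass
class SampleTable:
    """Genotype calls plus per-variant counts, writable as a TSV."""

    calls: list[GenotypeCall] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tvariant_id\tsequence\tnet_reads\tstatus\n")
            for call in self.calls:
                if not call.variants:
                    fh.write(f"{call.sample_id}\t-\t-\t{call.net_reads}\t{call.status}\n")
                for i, seq in enumerate(call.variants, 1):
                    fh.write(
                        f"{call.sample_id}\t{call.sample_id}_v{i}\t{seq}\t"
                        f"{call.net_reads}\t{call.status}\n"
                    )
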