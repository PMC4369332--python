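"""Nei-Gojobori (1986) codon counting with Jukes-Cantor correction.

Implements the counting backbone used throughout the package: potential
synonymous/nonsynonymous site fractions per codon (the 1/3-fraction rule)
and observed synonymous/nonsynonymous differences between codon pairs,
averaged with equal weight over all minimal substitution pathways.
Pathways passing through stop codons are excluded; if every pathway is
blocked the average falls back to all pathways (stop steps counted as
nonsynonymous).

Precomputed 61x61 (sense-codon) lookup tables make pairwise distances over
long alignments a set of integer-indexed array sums, which is what the
bootstrap machinery in :mod:`corvmhc.phylo` relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

NUCLEOTIDES = "ACGT"

# Standard genetic code (table 1), TGA/TAA/TAG stops.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = tuple(sorted(_CODON_TABLE))
STOP_CODONS = tuple(c for c in ALL_CODONS if _CODON_TABLE[c] == "*")
SENSE_CODONS = tuple(c for c in ALL_CODONS if _CODON_TABLE[c] != "*")
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate_codon(codon: str) -> str:
    """Amino acid (one letter; '*' for stop) encoded by ``codon``."""
    return _CODON_TABLE[codon.upper()]


def is_stop(codon: str) -> bool:
    return _CODON_TABLE[codon.upper()] == "*"


def potential_sites(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) site counts for one codon.

    Each of the three positions contributes ``s_i = (# synonymous
    single-base changes at i) / 3``; mutations to stop codons are never
    synonymous. ``S + N == 3`` by construction.
    """
    codon = codon.upper()
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if _CODON_TABLE[mutant] == aa and aa != "*":
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences c1 -> c2.

    Averages over all orderings of the differing positions; a pathway is
    discarded when an intermediate codon is a stop. If all pathways are
    blocked, the unrestricted average is returned with stop-involving
    steps counted as nonsynonymous.
    """
    c1, c2 = c1.upper(), c2.upper()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_TABLE[nxt] == "*" and nxt != c2 and not allow_stops:
                return None
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt] and _CODON_TABLE[cur] != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    for allow_stops in (False, True):
        results = [r for r in (walk(o, allow_stops) for o in permutations(diff)) if r is not None]
        if results:
            arr = np.asarray(results)
            sd, nd = arr.mean(axis=0)
            return float(sd), float(nd)
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CountingTables:
    """Dense sense-codon lookup tables for vectorised NG86 counting."""

    sd: np.ndarray      # (61, 61) pathway-averaged synonymous differences
    nd: np.ndarray      # (61, 61) pathway-averaged nonsynonymous differences
    s_pot: np.ndarray   # (61,) potential synonymous sites
    n_pot: np.ndarray   # (61,) potential nonsynonymous sites


@lru_cache(maxsize=1)
def counting_tables() -> CountingTables:
    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i < j:
                s, d = pathway_differences(ci, cj)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = d
    pots = np.asarray([potential_sites(c) for c in SENSE_CODONS])
    return CountingTables(sd=sd, nd=nd, s_pot=pots[:, 0], n_pot=pots[:, 1])


def jukes_cantor(p: float | np.ndarray) -> float | np.ndarray:
    """JC69 distance ``-(3/4) ln(1 - 4p/3)``; NaN where p >= 3/4."""
    p = np.asarray(p, dtype=float)
    arg = 1.0 - (4.0 / 3.0) * p
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(arg > 0.0, -0.75 * np.log(np.where(arg > 0.0, arg, 1.0)), np.nan)
    if d.ndim == 0:
        return float(d)
    return d


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide sequence as sense-codon indices.

    Raises ``ValueError`` on in-frame stop codons, non-ACGT characters or
    length not divisible by 3.
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    idx = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"in-frame stop codon {codon} at nucleotide {k + 1}")
        try:
            idx[k // 3] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at nucleotide {k + 1}") from None
    return idx


def pair_counts(idx1: np.ndarray, idx2: np.ndarray) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for one codon-index pair, pair-averaged potentials."""
    t = counting_tables()
    s = 0.5 * (t.s_pot[idx1].sum() + t.s_pot[idx2].sum())
    n = 0.5 * (t.n_pot[idx1].sum() + t.n_pot[idx2].sum())
    sd = t.sd[idx1, idx2].sum()
    nd = t.nd[idx1, idx2].sum()
    return float(s), float(n), float(sd), float(nd)
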