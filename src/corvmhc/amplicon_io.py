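"""Sequence I/O and demultiplexing of double-tagged bidirectional amplicons.

Pyrosequencing amplicon libraries built with fusion primers carry a
multiplex identifier (MID) and a locus primer on *both* ends of every
read. A read is assigned to a (sample, PCR replicate) bin only when one
orientation of the read matches ``MID_fwd + primer_fwd`` exactly at the
5' end and the reverse complement of ``MID_rev + primer_rev`` at the 3'
end, with no ambiguous base anywhere in the enclosed target. The binned
output is the bare target sequence reported on the forward strand.
Degenerate IUPAC codes are honoured in primers (set membership), never
in MIDs.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring degenerate IUPAC codes."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def iupac_match(pattern: str, segment: str, max_mismatch: int = 0) -> bool:
    """True when ``segment`` is within ``max_mismatch`` of the IUPAC ``pattern``."""
    if len(pattern) != len(segment):
        return False
    mismatches = 0
    for p, b in zip(pattern, segment):
        if b not in IUPAC_SETS[p]:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


@dataclass
class SequenceRead:
    """A raw read: id, bases over {A,C,G,T,N}, optional Sanger qualities."""

    read_id: str
    bases: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(f"read {self.read_id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.bases)


class FormatError(ValueError):
    """Raised for unknown formats or unparseable records."""


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SequenceRead]:
    """Read a FASTA or FASTQ file into :class:`SequenceRead` records, order preserved."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    if fmt not in {"fasta", "fastq"}:
        raise FormatError(f"unknown format {fmt!r}; expected 'fasta' or 'fastq'")
    reads = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            qual = rec.letter_annotations.get("phred_quality")
            reads.append(SequenceRead(rec.id, str(rec.seq).upper(), list(qual) if qual else None))
    except ValueError as exc:
        raise FormatError(f"malformed {fmt} record in {path}: {exc}") from exc
    return reads


def write_sequences(reads: list[SequenceRead], path: str | Path, fmt: str = "fasta") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            if fmt == "fasta":
                fh.write(f">{r.read_id}\n{r.bases}\n")
            elif fmt == "fastq":
                qual = r.quality if r.quality is not None else [40] * len(r.bases)
                fh.write(f"@{r.read_id}\n{r.bases}\n+\n{''.join(chr(q + 33) for q in qual)}\n")
            else:
                raise FormatError(f"unknown format {fmt!r}")


def length_filter(reads: list[SequenceRead], min_len: int) -> tuple[list[SequenceRead], int]:
    """Keep reads of length >= ``min_len``; return (kept, dropped count)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in reads if len(r) >= min_len]
    return kept, len(reads) - len(kept)


@dataclass(frozen=True)
class TagEntry:
    mid_fwd: str
    mid_rev: str
    primer_fwd: str
    primer_rev: str


@dataclass
class TagScheme:
    """Per-(sample, replicate) MIDs and primers for demultiplexing."""

    entries: dict[tuple[str, int], TagEntry]

    def __post_init__(self) -> None:
        pairs = Counter((e.mid_fwd, e.mid_rev) for e in self.entries.values())
        dup = [p for p, c in pairs.items() if c > 1]
        if dup:
            raise ValueError(f"duplicate MID pairs in tag scheme: {dup}")
        for key, e in self.entries.items():
            for mid in (e.mid_fwd, e.mid_rev):
                if any(b not in "ACGT" for b in mid):
                    raise ValueError(f"degenerate code in MID for {key}: {mid}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagScheme":
        entries = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = (row["sample_id"], int(row["replicate"]))
                entries[key] = TagEntry(
                    row["mid_fwd"].upper(), row["mid_rev"].upper(),
                    row["primer_fwd"].upper(), row["primer_rev"].upper(),
                )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\treplicate\tmid_fwd\tmid_rev\tprimer_fwd\tprimer_rev\n")
            for (sample, rep), e in sorted(self.entries.items()):
                fh.write(f"{sample}\t{rep}\t{e.mid_fwd}\t{e.mid_rev}\t{e.primer_fwd}\t{e.primer_rev}\n")


class TagCollisionError(ValueError):
    """Two scheme entries matched the same read."""


@dataclass
class TaggedReadSet:
    """Demultiplexed target sequences per (sample, replicate) plus reject tallies."""

    bins: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    rejects: Counter = field(default_factory=Counter)

    @property
    def n_binned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def write_bins(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (sample, rep), seqs in sorted(self.bins.items()):
            with open(out_dir / f"{sample}_rep{rep}.fasta", "w") as fh:
                for i, s in enumerate(seqs, 1):
                    fh.write(f">{sample}_rep{rep}_{i}\n{s}\n")
        with open(out_dir / "demux_report.tsv", "w") as fh:
            fh.write("sample_id\treplicate\tn_reads\n")
            for (sample, rep), seqs in sorted(self.bins.items()):
                fh.write(f"{sample}\t{rep}\t{len(seqs)}\n")
            for reason, n in sorted(self.rejects.items()):
                fh.write(f"__rejected__\t{reason}\t{n}\n")


def _match_entry(bases: str, entry: TagEntry, max_mismatch: int) -> str | None:
    """Return the forward-strand target if ``bases`` matches ``entry``, else None."""
    head = entry.mid_fwd + entry.primer_fwd
    tail = reverse_complement(entry.mid_rev + entry.primer_rev)
    if len(bases) < len(head) + len(tail):
        return None
    if not iupac_match(head, bases[: len(head)], max_mismatch):
        return None
    if not iupac_match(tail, bases[len(bases) - len(tail):], max_mismatch):
        return None
    return bases[len(head): len(bases) - len(tail)]


def demultiplex(
    reads: list[SequenceRead],
    scheme: TagScheme,
    max_mismatch: int = 0,
) -> TaggedReadSet:
    """Bin reads by exact double-tag match in either orientation.

    Every read lands in exactly one bin or one rejection tally
    (``missing_tag`` or ``ambiguous_base``). A read matched by two scheme
    entries raises :class:`TagCollisionError`.
    """
    if not scheme.entries:
        raise ValueError("tag scheme is empty")
    result = TaggedReadSet(bins={key: [] for key in scheme.entries})
    for read in reads:
        oriented = (read.bases, reverse_complement(read.bases))
        hits: list[tuple[tuple[str, int], str]] = []
        for key, entry in scheme.entries.items():
            for bases in oriented:
                target = _match_entry(bases, entry, max_mismatch)
                if target is not None:
                    hits.append((key, target))
                    break
        if len(hits) > 1:
            raise TagCollisionError(
                f"read {read.read_id} matches entries {[k for k, _ in hits]}"
            )
        if not hits:
            result.rejects["missing_tag"] += 1
            continue
        key, target = hits[0]
        if "N" in target:
            result.rejects["ambiguous_base"] += 1
            continue
        result.bins[key].append(target)
    return result
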