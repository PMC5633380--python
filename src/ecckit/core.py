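"""Sequence, interval and read-pair primitives shared across the toolkit.

Coordinates are 0-based, half-open everywhere in memory.  Conversion to the
1-based SAM convention happens only inside pysam at the SAM boundary, and
BED output stays 0-based half-open.

The module also houses two small pieces of circular-DNA-specific machinery:

* :func:`excise_between_direct_repeats` — the Cre/loxP-style model of
  site-specific recombination between two direct repeats on a circular
  molecule, which splits the parent circle into two daughter circles each
  carrying exactly one repeat copy.  This is how reference control circles
  (e.g. a 412 bp mini-circle from a 3446 bp plasmid) are constructed.
* :func:`map_exact` — a naive exact mapper used only for self-contained
  testing; real data is expected to arrive pre-aligned (SAM/BAM from an
  external aligner).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LINEAR = "linear"
CIRCULAR = "circular"


class FormatError(ValueError):
    """Malformed input file (e.g. duplicate FASTA record names)."""


class PreconditionError(ValueError):
    """An operation's documented precondition was violated."""


class TopologyError(PreconditionError):
    """A molecule of the wrong topology was passed (linear vs circular)."""


class ConfigurationError(ValueError):
    """Inconsistent or unsatisfiable configuration."""


def _rc(seq: str) -> str:
    # unchecked fast path for internal hot loops
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string; N maps to N.

    Raises ``ValueError`` on characters outside ``{A,C,G,T,N}``.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return _rc(seq)


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Molecule:
    """A DNA molecule: bases, topology and optional genomic origin.

    Circular molecules store an explicit rotation (the stored string); two
    rotations of the same circle are *not* equal under ``==``.  Rotation-
    invariant comparison lives in test helpers only, keeping serialization
    deterministic.
    """

    bases: str
    topology: str = LINEAR
    origin: Interval | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("molecule must have length >= 1")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def circular_slice(self, start: int, length: int) -> str:
        """Substring of length ``length`` starting at ``start`` (mod L).

        May wrap past the origin more than once (a singly cut circle
        linearizes to length L + d, which re-reads its first bases).
        """
        if not self.is_circular:
            raise TopologyError("circular_slice requires a circular molecule")
        L = len(self.bases)
        start %= L
        repeats = (start + length - 1) // L + 1
        return (self.bases * repeats)[start : start + length]


@dataclass(frozen=True)
class AlignedPair:
    """One aligned, properly paired read pair (both mates on one chromosome).

    Coordinates are 0-based half-open per mate; strands are ``+``/``-``.
    """

    name: str
    chrom: str
    start1: int
    end1: int
    strand1: str
    start2: int
    end2: int
    strand2: str
    proper_pair: bool = True


@dataclass
class ReadPair:
    """Two inward-facing reads sequenced from one fragment."""

    name: str
    r1: str
    r2: str
    label: str | None = None


@dataclass
class ReferenceGenome:
    """Named chromosomes of DNA bases.

    ``circular`` marks chromosomes that are circular molecules in vivo
    (typically the mitochondrion); everything else is treated as linear
    nuclear sequence.
    """

    sequences: dict[str, str]
    circular: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-DNA characters {sorted(bad)}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceGenome):
            return NotImplemented
        return self.sequences == other.sequences and self.circular == other.circular

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"interval {chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        return seq[start:end]


# ---------------------------------------------------------------------------
# FASTA / FASTQ / SAM / BED I/O


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (uppercased).

    Duplicate record names raise :class:`FormatError`.  An empty file yields
    an empty genome.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq_pair(
    pairs: Iterable[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write paired reads as two FASTQ files with /1 and /2 name suffixes."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.r1}\n+\n{'I' * len(p.r1)}\n")
            f2.write(f"@{p.name}/2\n{p.r2}\n+\n{'I' * len(p.r2)}\n")


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path) -> list[ReadPair]:
    """Read two parallel FASTQ files back into :class:`ReadPair` objects."""

    def _name(rec_id: str) -> str:
        return rec_id[:-2] if rec_id.endswith(("/1", "/2")) else rec_id

    r1s = list(SeqIO.parse(str(path_r1), "fastq"))
    r2s = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1s) != len(r2s):
        raise FormatError(
            f"unpaired FASTQ files: {len(r1s)} vs {len(r2s)} records"
        )
    pairs = []
    for a, b in zip(r1s, r2s):
        if _name(a.id) != _name(b.id):
            raise FormatError(f"read name mismatch: {a.id} vs {b.id}")
        pairs.append(ReadPair(_name(a.id), str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def read_aligned_pairs(path: str | Path) -> list[AlignedPair]:
    """Load properly paired primary alignments from SAM/BAM via pysam.

    Mates are joined by query name; pairs with mates on different
    chromosomes, or with an unmapped mate, are skipped.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    out: list[AlignedPair] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            r1, r2 = (mate, aln) if mate.is_read1 else (aln, mate)
            if r1.reference_name != r2.reference_name:
                continue
            out.append(
                AlignedPair(
                    name=r1.query_name,
                    chrom=r1.reference_name,
                    start1=r1.reference_start,
                    end1=r1.reference_end,
                    strand1="-" if r1.is_reverse else "+",
                    start2=r2.reference_start,
                    end2=r2.reference_end,
                    strand2="-" if r2.is_reverse else "+",
                    proper_pair=r1.is_proper_pair,
                )
            )
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as 0-based half-open BED3."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Circle construction


def extract_circle_from_genome(
    genome: ReferenceGenome, interval: Interval
) -> Molecule:
    """Excise a genomic interval as a circular molecule.

    The stored rotation starts at the interval start; the genomic origin is
    recorded on the molecule.
    """
    bases = genome.fetch(interval.chrom, interval.start, interval.end)
    return Molecule(bases, CIRCULAR, origin=interval, label=f"circle:{interval.chrom}:{interval.start}-{interval.end}")


def excise_between_direct_repeats(
    parent: Molecule, repeat_len: int, pos_a: int, pos_b: int
) -> tuple[Molecule, Molecule]:
    """Recombine two direct repeats on a circular parent into two circles.

    Models Cre acting on two directly repeated loxP sites: the spacer between
    the repeats is excised as a circle carrying exactly one repeat copy, and
    the rest of the parent re-ligates into a second circle carrying the other
    copy.  ``pos_a``/``pos_b`` are the repeat start offsets in the stored
    rotation; the returned ``circle`` is the product containing the spacer
    downstream of ``pos_a`` (i.e. the arc from ``pos_a`` to ``pos_b``).

    Length is conserved: ``len(circle) + len(remainder) == len(parent)``.
    """
    if not parent.is_circular:
        raise TopologyError("excision requires a circular parent molecule")
    L = len(parent)
    rep_a = parent.circular_slice(pos_a, repeat_len)
    rep_b = parent.circular_slice(pos_b, repeat_len)
    if rep_a != rep_b:
        raise PreconditionError("direct-repeat copies are not identical")
    arc_ab = (pos_b - pos_a) % L
    arc_ba = (pos_a - pos_b) % L
    if arc_ab < repeat_len or arc_ba < repeat_len:
        raise PreconditionError("repeat copies overlap on the circle")
    circle = Molecule(
        parent.circular_slice(pos_a, arc_ab), CIRCULAR, label="excised-circle"
    )
    remainder = Molecule(
        parent.circular_slice(pos_b, arc_ba), CIRCULAR, label="excision-remainder"
    )
    return circle, remainder


# ---------------------------------------------------------------------------
# Positional deduplication and the naive exact mapper


def dedupe_pairs(
    pairs: Sequence[AlignedPair], strand_aware: bool = True
) -> list[AlignedPair]:
    """Collapse read pairs sharing a start/stop positional combination.

    One representative (the first occurrence) is kept per distinct
    ``(chrom, start1, end1, start2, end2[, strand1, strand2])`` tuple.  The
    strand-aware key is the default; ``strand_aware=False`` collapses over
    strands as well.
    """
    seen: set[tuple] = set()
    out: list[AlignedPair] = []
    for p in pairs:
        key: tuple = (p.chrom, p.start1, p.end1, p.start2, p.end2)
        if strand_aware:
            key += (p.strand1, p.strand2)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def map_exact(read: str, genome: ReferenceGenome) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``read`` or its reverse complement.

    Returns ``(chrom, pos, strand)`` tuples sorted by position.  For a
    reverse-complement-palindromic read both orientations match at the same
    position; a single ``+`` entry is reported.  This is a test-only
    substitute for an external aligner: no mismatches, no gaps.
    """
    if len(read) < 1:
        raise PreconditionError("read must have length >= 1")
    rc = reverse_complement(read)
    queries = [(read, "+")] if read == rc else [(read, "+"), (rc, "-")]
    hits: set[tuple[str, int, str]] = set()
    for chrom, seq in genome.sequences.items():
        for query, strand in queries:
            i = seq.find(query)
            while i != -1:
                hits.add((chrom, i, strand))
                i = seq.find(query, i + 1)
    return sorted(hits)
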