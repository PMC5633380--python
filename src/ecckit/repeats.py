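"""k-mer placement of reads over unique and repetitive genome space.

Short reads that align to repeated sequence cannot be assigned a single
genomic position, but the *set* of positions compatible with a read is
still informative.  This module indexes the genome by canonical k-mers,
recovers the full placement set of each read (equivalent to exact full-read
matching on both strands), and reduces it to one of four categories:

* ``UNIQUE`` — exactly one placement;
* ``FOCAL_REPEAT`` — multiple placements, all on one chromosome within a
  bounded span (300 kb by default), e.g. tandem exon arrays;
* ``INTRACHROMOSOMAL_REPEAT`` — multiple placements on one chromosome
  separated by more than the focal range;
* ``DISPERSED_REPEAT`` — placements on two or more chromosomes.

Unplaceable reads form a fifth, residual category.  Unique reads are
counted at their single position; focal-repeat reads at the midpoint of
their placement span; intrachromosomal and dispersed reads are tallied in
composition summaries only, since they have no single defensible location.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core import ConfigurationError, PreconditionError, ReferenceGenome, _rc
from .enrichment import BinnedCounts

DEFAULT_K = 31
DEFAULT_FOCAL_RANGE = 300_000


class Category(enum.Enum):
    UNIQUE = "unique"
    FOCAL_REPEAT = "focal_repeat"
    INTRACHROMOSOMAL_REPEAT = "intrachromosomal_repeat"
    DISPERSED_REPEAT = "dispersed_repeat"
    UNPLACEABLE = "unplaceable"


# rank used to classify a pair by its more-repetitive placeable mate
_REPETITIVENESS = {
    Category.UNPLACEABLE: 0,
    Category.UNIQUE: 1,
    Category.FOCAL_REPEAT: 2,
    Category.INTRACHROMOSOMAL_REPEAT: 3,
    Category.DISPERSED_REPEAT: 4,
}


@dataclass(frozen=True)
class PlacementSet:
    """All genomic positions compatible with a read."""

    read_id: str
    placements: tuple[tuple[str, int, str], ...]  # (chrom, pos, strand), sorted


@dataclass(frozen=True)
class ReadClassification:
    category: Category
    span: int | None = None  # outermost start distance, single-chromosome sets


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = _rc(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Canonical k-mer -> sorted (chrom, pos, strand) occurrence lists.

    ``strand`` records the orientation of the genomic k-mer relative to the
    stored canonical form ('+': equal, '-': reverse complement).  k-mers
    containing N are skipped.
    """

    def __init__(self, genome: ReferenceGenome, k: int, table: dict) -> None:
        self.genome = genome
        self.k = k
        self.table = table

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.table.values())

    def get(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.table.get(canonical(kmer), [])


def build_kmer_index(genome: ReferenceGenome, k: int = DEFAULT_K) -> KmerIndex:
    """Index every k-mer position of every chromosome (canonical form).

    Chromosomes shorter than ``k`` contribute nothing; if every chromosome
    is shorter than ``k`` a :class:`ConfigurationError` is raised.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if all(len(seq) < k for seq in genome.sequences.values()):
        raise ConfigurationError(f"k={k} exceeds every chromosome length")
    table: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for chrom, seq in genome.sequences.items():
        has_n = "N" in seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if has_n and "N" in kmer:
                continue
            rc = _rc(kmer)
            if kmer <= rc:
                table[kmer].append((chrom, i, "+"))
            else:
                table[rc].append((chrom, i, "-"))
    for occs in table.values():
        occs.sort()
    return KmerIndex(genome, k, dict(table))


def locate_read(read: str, index: KmerIndex) -> PlacementSet:
    """Full placement set of a read through the k-mer index.

    A placement at (chrom, p, strand) is reported iff every k-mer of the
    read matches the genome at its offset-consistent position — i.e. exact
    full-read matching on either strand, anchored on the read's first
    k-mer.  Reads shorter than k are a precondition error.
    """
    k, L = index.k, len(read)
    if L < k:
        raise PreconditionError(f"read shorter than k={k}")
    genome = index.genome
    first = read[:k]
    rc_first = _rc(first)
    rc_read = _rc(read)
    hits: set[tuple[str, int, str]] = set()
    for chrom, pos, strand in index.get(first):
        seq = genome.sequences[chrom]
        # orientation of the genomic k-mer at this occurrence
        gkmer = first if (strand == "+") == (canonical(first) == first) else rc_first
        if gkmer == first and seq.startswith(read, pos):
            hits.add((chrom, pos, "+"))
        if gkmer == rc_first:
            # read's first k-mer sits reverse-complemented at pos, so the
            # reverse-strand alignment starts L - k bases upstream
            start = pos - (L - k)
            if start >= 0 and seq.startswith(rc_read, start):
                hits.add((chrom, start, "-"))
    return PlacementSet(read_id="", placements=tuple(sorted(hits)))


def classify_placements(
    ps: PlacementSet, focal_range: int = DEFAULT_FOCAL_RANGE
) -> ReadClassification:
    """Reduce a placement set to one of the five categories.

    Span is measured between the outermost placement start positions on a
    single chromosome.
    """
    places = ps.placements
    if not places:
        return ReadClassification(Category.UNPLACEABLE)
    if len(places) == 1:
        return ReadClassification(Category.UNIQUE, span=0)
    chroms = {chrom for chrom, _, _ in places}
    if len(chroms) > 1:
        return ReadClassification(Category.DISPERSED_REPEAT)
    positions = [pos for _, pos, _ in places]
    span = max(positions) - min(positions)
    if span <= focal_range:
        return ReadClassification(Category.FOCAL_REPEAT, span=span)
    return ReadClassification(Category.INTRACHROMOSOMAL_REPEAT, span=span)


def classify_read(
    read: str, index: KmerIndex, focal_range: int = DEFAULT_FOCAL_RANGE
) -> tuple[ReadClassification, PlacementSet]:
    ps = locate_read(read, index)
    return classify_placements(ps, focal_range), ps


def pair_category(cat1: Category, cat2: Category) -> Category:
    """Category of a read pair: the more repetitive placeable mate wins.

    An unplaceable mate is ignored unless both mates are unplaceable.
    """
    return max(cat1, cat2, key=_REPETITIVENESS.get)


def class_composition(
    classifications: Iterable[ReadClassification],
) -> dict[Category, float]:
    """Fraction of reads per category; fractions sum to 1."""
    counts = {cat: 0 for cat in Category}
    n = 0
    for c in classifications:
        counts[c.category] += 1
        n += 1
    if n == 0:
        raise ValueError("composition of an empty read set is undefined")
    return {cat: counts[cat] / n for cat in Category}


def track_position(
    classification: ReadClassification, ps: PlacementSet
) -> tuple[str, int] | None:
    """Single representative genome position of a read, if it has one.

    Unique reads sit at their placement; focal-repeat reads at the midpoint
    of their span; other categories have no positional representative.
    """
    if classification.category is Category.UNIQUE:
        chrom, pos, _ = ps.placements[0]
        return chrom, pos
    if classification.category is Category.FOCAL_REPEAT:
        chrom = ps.placements[0][0]
        positions = [p for _, p, _ in ps.placements]
        return chrom, (min(positions) + max(positions)) // 2
    return None


def coverage_by_class(
    classified: Sequence[tuple[ReadClassification, PlacementSet]],
    genome: ReferenceGenome,
    bin_size: int,
) -> dict[Category, BinnedCounts]:
    """Per-category binned positional tracks (UNIQUE and FOCAL_REPEAT only).

    Track mass is conserved: the total of each track equals the number of
    reads of that category.
    """
    tracks = {
        cat: BinnedCounts.zeros(genome.lengths, bin_size)
        for cat in (Category.UNIQUE, Category.FOCAL_REPEAT)
    }
    for classification, ps in classified:
        pos = track_position(classification, ps)
        if pos is not None:
            tracks[classification.category].add(*pos)
    return tracks


def write_bedgraph(track: BinnedCounts, path: str | Path) -> None:
    """Write a binned track as BEDGRAPH (0-based half-open bins)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_bins():
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


def write_class_table(
    reads: Sequence[tuple[str, ReadClassification]], path: str | Path
) -> None:
    """Tab-separated per-read classification table."""
    with open(path, "w") as fh:
        fh.write("read\tcategory\tspan\n")
        for rid, c in reads:
            span = "" if c.span is None else str(c.span)
            fh.write(f"{rid}\t{c.category.value}\t{span}\n")
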