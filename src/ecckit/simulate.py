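"""Synthetic genomes, planted circles and a Tn5 tagmentation read model.

This module is the fixture factory for the whole toolkit: it builds
reference genomes with planted repeat families (focal, dispersed,
intrachromosomal), plants eccDNA circles with known coordinates and copy
numbers, and emits paired-end reads through a mechanistic model of Tn5
tagmentation.

The tagmentation model
----------------------
Tn5 cuts a double-stranded molecule and leaves a 9-nt staggered overhang;
fill-in during the first PCR cycle duplicates those 9 bases on both sides
of each insertion.  We model cut sites as a homogeneous Poisson process
along the molecule (rate ``cut_rate`` per bp).  A cut at position ``p`` of a
linear molecule produces a left fragment ending at ``p + d`` and a right
fragment starting at ``p``, so consecutive fragments share exactly ``d``
terminal bases.  A circular molecule cut exactly once linearizes into a
single molecule of length ``L + d`` whose first ``d`` bases equal its last
``d`` bases — the sequence signature of a singly tagmented circle.  The
"attenuated" regime (short tagmentase incubation in the lab) is modeled as
exactly one cut per circle.

Enrichment for circular DNA (exonuclease V digestion or density-gradient
banding) is modeled as Bernoulli removal of linear molecules with
probability ``linear_removal`` (epsilon); covalently closed circles always
survive.  ``epsilon = 0`` reproduces a total-genomic control library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import (
    CIRCULAR,
    LINEAR,
    ConfigurationError,
    Interval,
    Molecule,
    ReadPair,
    ReferenceGenome,
    TopologyError,
    _rc,
    write_fastq_pair,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Architecture and truth


@dataclass(frozen=True)
class FocalRepeatFamily:
    """A repeat family whose copies all sit within a bounded window.

    Reads drawn from such a family classify as FOCAL_REPEAT under the
    focal-range rule as long as ``region_span`` does not exceed the range.
    """

    name: str
    chrom: str
    unit_length: int
    copies: int
    region_span: int
    region_start: int | None = None  # random placement when None


@dataclass(frozen=True)
class DispersedRepeatFamily:
    """A repeat family with copies on every (non-circular) chromosome."""

    name: str
    unit_length: int
    copies_per_chromosome: int = 1


@dataclass(frozen=True)
class IntrachromosomalRepeatFamily:
    """Two copies on one chromosome separated by more than the focal range."""

    name: str
    chrom: str
    unit_length: int
    separation: int


@dataclass(frozen=True)
class GenomeArchitecture:
    """Blueprint for a simulated reference genome."""

    chromosome_lengths: dict[str, int]
    gc_fraction: float = 0.36
    focal_families: tuple[FocalRepeatFamily, ...] = ()
    dispersed_families: tuple[DispersedRepeatFamily, ...] = ()
    intrachromosomal_families: tuple[IntrachromosomalRepeatFamily, ...] = ()
    mito_name: str | None = None
    mito_length: int = 14000
    focal_range: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ConfigurationError("need at least one chromosome")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has length {length}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        for fam in self.focal_families:
            if fam.region_span > self.focal_range:
                raise ConfigurationError(
                    f"focal family {fam.name}: region_span {fam.region_span} "
                    f"exceeds the focal range {self.focal_range}"
                )
        for fam in self.intrachromosomal_families:
            if fam.separation <= self.focal_range:
                raise ConfigurationError(
                    f"intrachromosomal family {fam.name}: separation must "
                    f"exceed the focal range {self.focal_range}"
                )


@dataclass(frozen=True)
class RepeatPlacement:
    family: str
    interval: Interval


@dataclass(frozen=True)
class PlantedCircle:
    name: str
    interval: Interval
    copies: float = 1.0


@dataclass
class TruthSet:
    """Ground truth for a simulated dataset."""

    repeat_placements: list[RepeatPlacement] = field(default_factory=list)
    circles: list[PlantedCircle] = field(default_factory=list)
    read_provenance: dict[str, str] = field(default_factory=dict)

    def placements_for(self, family: str) -> list[RepeatPlacement]:
        return [p for p in self.repeat_placements if p.family == family]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


class _Occupancy:
    """Tracks planted intervals per chromosome to avoid overlaps."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def try_reserve(self, chrom: str, start: int, end: int) -> bool:
        spans = self._by_chrom.setdefault(chrom, [])
        for s, e in spans:
            if start < e and s < end:
                return False
        spans.append((start, end))
        return True


def _place_unit(
    rng: np.random.Generator,
    occ: _Occupancy,
    chrom: str,
    lo: int,
    hi: int,
    unit_len: int,
    what: str,
    tries: int = 1000,
) -> int:
    """Find a non-overlapping start for a unit in [lo, hi - unit_len]."""
    if hi - lo < unit_len:
        raise ConfigurationError(f"{what}: unit does not fit in the target region")
    for _ in range(tries):
        start = int(rng.integers(lo, hi - unit_len + 1))
        if occ.try_reserve(chrom, start, start + unit_len):
            return start
    raise ConfigurationError(f"{what}: could not place unit without overlap")


def simulate_reference(arch: GenomeArchitecture) -> tuple[ReferenceGenome, TruthSet]:
    """Build a genome from an architecture; deterministic given the seed.

    Planted repeat units are exact copies; every placement is recorded in the
    returned :class:`TruthSet`.  A declared mitochondrion is appended as a
    small chromosome marked circular.
    """
    rng = np.random.default_rng(arch.seed)
    sequences = {
        name: bytearray(_random_bases(rng, length, arch.gc_fraction), "ascii")
        for name, length in arch.chromosome_lengths.items()
    }
    truth = TruthSet()
    occ = _Occupancy()

    def plant(chrom: str, start: int, unit: str, family: str) -> None:
        sequences[chrom][start : start + len(unit)] = unit.encode("ascii")
        truth.repeat_placements.append(
            RepeatPlacement(family, Interval(chrom, start, start + len(unit)))
        )

    for fam in arch.focal_families:
        if fam.chrom not in sequences:
            raise ConfigurationError(f"unknown chromosome {fam.chrom!r}")
        clen = arch.chromosome_lengths[fam.chrom]
        if fam.region_span > clen:
            raise ConfigurationError(
                f"focal family {fam.name}: region larger than chromosome"
            )
        region_start = (
            fam.region_start
            if fam.region_start is not None
            else int(rng.integers(0, clen - fam.region_span + 1))
        )
        unit = _random_bases(rng, fam.unit_length, arch.gc_fraction)
        for _ in range(fam.copies):
            start = _place_unit(
                rng, occ, fam.chrom, region_start,
                region_start + fam.region_span, fam.unit_length, fam.name,
            )
            plant(fam.chrom, start, unit, fam.name)

    for fam in arch.dispersed_families:
        unit = _random_bases(rng, fam.unit_length, arch.gc_fraction)
        for chrom, clen in arch.chromosome_lengths.items():
            for _ in range(fam.copies_per_chromosome):
                start = _place_unit(rng, occ, chrom, 0, clen, fam.unit_length, fam.name)
                plant(chrom, start, unit, fam.name)

    for fam in arch.intrachromosomal_families:
        clen = arch.chromosome_lengths[fam.chrom]
        if fam.separation + 2 * fam.unit_length > clen:
            raise ConfigurationError(
                f"intrachromosomal family {fam.name}: separation does not fit"
            )
        unit = _random_bases(rng, fam.unit_length, arch.gc_fraction)
        for _ in range(1000):
            first = int(rng.integers(0, clen - fam.separation - 2 * fam.unit_length))
            gap = int(
                rng.integers(
                    fam.separation + 1,
                    clen - first - 2 * fam.unit_length + 1,
                )
            )
            second = first + fam.unit_length + gap
            if occ.try_reserve(fam.chrom, first, first + fam.unit_length):
                if occ.try_reserve(fam.chrom, second, second + fam.unit_length):
                    plant(fam.chrom, first, unit, fam.name)
                    plant(fam.chrom, second, unit, fam.name)
                    break
                # roll back unusable first reservation is not supported;
                # extremely unlikely at simulated densities
        else:
            raise ConfigurationError(f"could not place {fam.name}")

    circular: frozenset[str] = frozenset()
    if arch.mito_name is not None:
        sequences[arch.mito_name] = bytearray(
            _random_bases(rng, arch.mito_length, arch.gc_fraction), "ascii"
        )
        circular = frozenset({arch.mito_name})

    genome = ReferenceGenome(
        {name: seq.decode("ascii") for name, seq in sequences.items()},
        circular=circular,
    )
    return genome, truth


def plant_circles(
    truth: TruthSet, intervals: Sequence[Interval], copies: float, prefix: str = "ecc"
) -> None:
    """Register planted eccDNA circles (genomic intervals) in the truth set."""
    for i, iv in enumerate(intervals):
        truth.circles.append(PlantedCircle(f"{prefix}{i}", iv, copies))


# ---------------------------------------------------------------------------
# Tagmentation


@dataclass(frozen=True)
class TagmentationParams:
    """Parameters of the Tn5 cut-and-duplicate model.

    ``cut_rate`` is the expected number of cuts per bp (1/500 by default,
    i.e. a 500 bp mean fragment in the standard regime); ``dup_len`` is the
    target-site duplication length (9 bp for Tn5); ``attenuated`` forces
    exactly one cut on circular molecules, emulating the short-incubation
    protocol used to capture singly tagmented circles.
    """

    cut_rate: float = 1 / 500
    dup_len: int = 9
    attenuated: bool = True
    read_length: int = 100
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cut_rate <= 0:
            raise ConfigurationError("cut_rate must be > 0")
        if self.dup_len < 0:
            raise ConfigurationError("dup_len must be >= 0")
        if self.read_length <= self.dup_len:
            raise ConfigurationError("read_length must exceed dup_len")


def tagment_linear(
    mol: Molecule, params: TagmentationParams, rng: np.random.Generator
) -> list[Molecule]:
    """Fragment a linear molecule by Tn5, duplicating ``dup_len`` bases per cut.

    Cut positions follow a Poisson process restricted to sites where the
    duplicated segment fits (``1 <= p <= L - d``).  Consecutive fragments
    overlap in exactly ``d`` bases and total fragment length equals
    ``L + d * n_cuts``.
    """
    if mol.is_circular:
        raise TopologyError("tagment_linear requires a linear molecule")
    L, d = len(mol), params.dup_len
    n_sites = max(L - d, 0)
    n_cuts = int(rng.poisson(params.cut_rate * L)) if n_sites > 0 else 0
    n_cuts = min(n_cuts, n_sites)
    if n_cuts == 0:
        return [replace(mol)]
    cuts = np.sort(rng.choice(np.arange(1, L - d + 1), size=n_cuts, replace=False))
    frags: list[Molecule] = []
    prev = 0
    for i, p in enumerate(cuts):
        frags.append(_subfragment(mol, prev, int(p) + d, i))
        prev = int(p)
    frags.append(_subfragment(mol, prev, L, len(cuts)))
    return frags


def _subfragment(mol: Molecule, start: int, end: int, idx: int) -> Molecule:
    origin = None
    if mol.origin is not None:
        origin = Interval(mol.origin.chrom, mol.origin.start + start, mol.origin.start + end)
    label = f"{mol.label or 'mol'}|frag{idx}"
    return Molecule(mol.bases[start:end], LINEAR, origin=origin, label=label)


def tagment_circle(
    mol: Molecule, params: TagmentationParams, rng: np.random.Generator
) -> list[Molecule]:
    """Fragment a circular molecule by Tn5.

    The cut count is Poisson(rate * L) conditioned on >= 1 (a circle that is
    never cut is not sequenced); the attenuated regime forces exactly one
    cut.  A singly cut circle of length L yields one linear molecule of
    length ``L + d`` whose first ``d`` bases equal its last ``d`` bases.
    """
    if not mol.is_circular:
        raise TopologyError("tagment_circle requires a circular molecule")
    L, d = len(mol), params.dup_len
    if params.attenuated:
        n_cuts = 1
    else:
        n_cuts = 0
        while n_cuts == 0:
            n_cuts = int(rng.poisson(params.cut_rate * L))
        n_cuts = min(n_cuts, L)
    positions = np.sort(rng.choice(L, size=n_cuts, replace=False))
    frags: list[Molecule] = []
    for i, p in enumerate(positions):
        nxt = int(positions[(i + 1) % n_cuts])
        seg = (nxt - int(p)) % L or L
        frags.append(
            Molecule(
                mol.circular_slice(int(p), seg + d),
                LINEAR,
                label=f"{mol.label or 'circle'}|cut{i}@{int(p)}",
            )
        )
    return frags


def fragments_to_read_pairs(
    frags: Iterable[Molecule],
    params: TagmentationParams,
    rng: np.random.Generator | None = None,
    name_prefix: str = "frag",
) -> list[ReadPair]:
    """Sequence each fragment from both ends, inward-facing, error-free.

    R1 is the first ``read_length`` bases of the top strand; R2 is the first
    ``read_length`` bases of the bottom strand read inward from the right
    end (i.e. of the reverse complement).  Fragments shorter than the read
    length are skipped with a counted warning.  An optional uniform
    substitution rate introduces errors when an ``rng`` is supplied.
    """
    rl = params.read_length
    pairs: list[ReadPair] = []
    skipped = 0
    for i, frag in enumerate(frags):
        if len(frag) < rl:
            skipped += 1
            continue
        r1 = frag.bases[:rl]
        r2 = _rc(frag.bases)[:rl]
        if params.substitution_rate > 0 and rng is not None:
            r1 = _mutate(r1, params.substitution_rate, rng)
            r2 = _mutate(r2, params.substitution_rate, rng)
        pairs.append(ReadPair(f"{name_prefix}:{i}", r1, r2, label=frag.label))
    if skipped:
        logger.warning("skipped %d fragments shorter than the read length", skipped)
    return pairs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Library pools


@dataclass(frozen=True)
class SamplePool:
    """A sequencing library: genomic background plus circles, after enrichment.

    ``linear_removal`` (epsilon) is the probability that a linear genomic
    fragment is destroyed by the enrichment step; covalently closed circles
    are treated as fully resistant.  ``depth`` is the total number of read
    pairs drawn.  ``genome_copies`` and ``mito_copies`` set the relative
    molar abundance of the nuclear genome and of each circular chromosome;
    planted circles carry their own copy numbers in the truth set.
    """

    depth: int
    linear_removal: float = 0.0
    genome_copies: float = 1.0
    mito_copies: float = 2.0
    fragment_length: int = 400
    tagmentation: TagmentationParams = field(default_factory=TagmentationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.linear_removal <= 1.0:
            raise ConfigurationError("linear_removal must be in [0, 1]")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.fragment_length < self.tagmentation.read_length:
            raise ConfigurationError("fragment_length must cover a read")


def draw_pool_read_pairs(
    genome: ReferenceGenome, truth: TruthSet, pool: SamplePool, name: str = "sim"
) -> tuple[list[ReadPair], TruthSet]:
    """Draw read pairs from the enrichment mixture, in memory.

    Reads are allocated multinomially across sources in proportion to
    molecular mass (length x copy number), with linear sources down-weighted
    by ``1 - linear_removal``.  Linear background pairs sequence the two ends
    of a random genomic fragment (no shared duplication between mates);
    circle pairs sequence the two ends of a singly cut, linearized circle
    and therefore carry the ``dup_len`` duplication signature.

    Returns the pairs and a copy of the truth set with per-read provenance.
    """
    rng = np.random.default_rng(pool.seed)
    tp = pool.tagmentation
    d, rl = tp.dup_len, tp.read_length

    sources: list[tuple[str, float]] = []  # (kind:name, weight)
    linear_chroms = [c for c in genome.chromosomes if c not in genome.circular]
    for chrom in linear_chroms:
        w = genome.lengths[chrom] * pool.genome_copies * (1.0 - pool.linear_removal)
        sources.append((f"linear:{chrom}", w))
    for chrom in genome.circular:
        sources.append((f"chromcircle:{chrom}", genome.lengths[chrom] * pool.mito_copies))
    circle_seqs: dict[str, str] = {}
    for pc in truth.circles:
        circle_seqs[pc.name] = genome.fetch(
            pc.interval.chrom, pc.interval.start, pc.interval.end
        )
        sources.append((f"circle:{pc.name}", len(pc.interval) * pc.copies))

    weights = np.array([w for _, w in sources], dtype=float)
    if weights.sum() <= 0:
        raise ConfigurationError("pool has zero total molecular mass")
    counts = rng.multinomial(pool.depth, weights / weights.sum())

    pairs: list[ReadPair] = []
    provenance: dict[str, str] = {}
    serial = 0

    def emit(r1: str, r2: str, label: str) -> None:
        nonlocal serial
        rid = f"{name}:r{serial:08d}"
        serial += 1
        pairs.append(ReadPair(rid, r1, r2, label=label))
        provenance[rid] = label

    for (src, _), n in zip(sources, counts):
        kind, _, key = src.partition(":")
        if n == 0:
            continue
        if kind == "linear":
            seq = genome.sequences[key]
            hi = len(seq) - pool.fragment_length
            if hi < 0:
                raise ConfigurationError(f"chromosome {key} shorter than a fragment")
            starts = rng.integers(0, hi + 1, size=n)
            for s in starts:
                frag = seq[s : s + pool.fragment_length]
                emit(frag[:rl], _rc(frag)[:rl], f"linear:{key}:{int(s)}")
        else:  # a circular molecule, singly tagmented
            seq = genome.sequences[key] if kind == "chromcircle" else circle_seqs[key]
            L = len(seq)
            if L + d < rl:
                logger.warning("circle %s shorter than a read; skipped", key)
                continue
            cut_positions = rng.integers(0, L, size=n)
            doubled = seq + seq
            for p in cut_positions:
                lin = doubled[p : p + L] + doubled[p : p + d]
                emit(lin[:rl], _rc(lin)[:rl], f"{kind}:{key}:cut{int(p)}")

    out_truth = TruthSet(
        repeat_placements=list(truth.repeat_placements),
        circles=list(truth.circles),
        read_provenance=provenance,
    )
    return pairs, out_truth


def simulate_enrichment_pool(
    genome: ReferenceGenome,
    truth: TruthSet,
    pool: SamplePool,
    out_dir: str | Path,
    name: str = "sample",
) -> tuple[tuple[Path, Path], TruthSet]:
    """Draw a pool and write it as a FASTQ pair plus a provenance table.

    Outputs ``{name}_R1.fastq``, ``{name}_R2.fastq`` and
    ``{name}_provenance.tsv``; byte-identical under a fixed pool seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, out_truth = draw_pool_read_pairs(genome, truth, pool, name=name)
    p1 = out_dir / f"{name}_R1.fastq"
    p2 = out_dir / f"{name}_R2.fastq"
    write_fastq_pair(pairs, p1, p2)
    with open(out_dir / f"{name}_provenance.tsv", "w") as fh:
        fh.write("read\tsource\n")
        for rid, label in out_truth.read_provenance.items():
            fh.write(f"{rid}\t{label}\n")
    return (p1, p2), out_truth
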