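"""End-to-end orchestration: reads -> placements -> bins -> enrichment calls.

Thin glue used by the command-line interface and by reproduction scripts;
everything here is a composition of the public functions of the other
modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ReadPair, ReferenceGenome
from .enrichment import (
    BinnedCounts,
    CorrectionPolicy,
    EnrichmentResult,
    bin_reads,
    call_enriched,
)
from .repeats import (
    DEFAULT_FOCAL_RANGE,
    DEFAULT_K,
    Category,
    KmerIndex,
    PlacementSet,
    ReadClassification,
    build_kmer_index,
    classify_read,
    track_position,
)


@dataclass
class ClassifiedReads:
    """Per-read classifications plus the positions usable for binning."""

    classifications: list[tuple[str, ReadClassification]]
    positions: list[tuple[str, int]]


def classify_pairs(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    focal_range: int = DEFAULT_FOCAL_RANGE,
) -> ClassifiedReads:
    """Classify both mates of every pair; collect binnable positions.

    Each mate is located independently (R2 via its own placement set — the
    mapper is strand-symmetric, so no pre-orientation is needed).  Unique
    reads contribute their position, focal-repeat reads their span
    midpoint; other categories contribute to composition only.
    """
    classifications: list[tuple[str, ReadClassification]] = []
    positions: list[tuple[str, int]] = []
    for pair in pairs:
        for suffix, read in (("/1", pair.r1), ("/2", pair.r2)):
            cls, ps = classify_read(read, index, focal_range)
            classifications.append((pair.name + suffix, cls))
            pos = track_position(cls, ps)
            if pos is not None:
                positions.append(pos)
    return ClassifiedReads(classifications, positions)


def bin_pairs(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    bin_size: int,
    focal_range: int = DEFAULT_FOCAL_RANGE,
) -> BinnedCounts:
    """Bin the positional (unique + focal) reads of a pair collection."""
    cr = classify_pairs(pairs, index, focal_range)
    return bin_reads(cr.positions, index.genome.lengths, bin_size)


def enrich_pairs(
    sample_pairs: Sequence[ReadPair],
    control_pairs: Sequence[ReadPair],
    genome: ReferenceGenome,
    bin_size: int,
    k: int = DEFAULT_K,
    focal_range: int = DEFAULT_FOCAL_RANGE,
    min_fold: float = 4.0,
    policy: CorrectionPolicy | None = None,
    index: KmerIndex | None = None,
    full_report: bool = True,
) -> tuple[list[EnrichmentResult], BinnedCounts, BinnedCounts]:
    """Full enrichment pipeline from raw read pairs.

    Returns the per-bin results plus the sample and control binned counts
    (for downstream summaries such as the mitochondrial internal control).
    """
    if index is None:
        index = build_kmer_index(genome, k)
    sample_bins = bin_pairs(sample_pairs, index, bin_size, focal_range)
    control_bins = bin_pairs(control_pairs, index, bin_size, focal_range)
    results = call_enriched(
        sample_bins, control_bins, min_fold=min_fold, policy=policy,
        full_report=full_report,
    )
    return results, sample_bins, control_bins
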