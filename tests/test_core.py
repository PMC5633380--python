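"""Sequence primitives: reverse complement, FASTA I/O, excision, dedup, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecckit.core import (
    AlignedPair,
    FormatError,
    Interval,
    Molecule,
    PreconditionError,
    ReferenceGenome,
    TopologyError,
    dedupe_pairs,
    excise_between_direct_repeats,
    extract_circle_from_genome,
    map_exact,
    read_fasta,
    reverse_complement,
    write_fasta,
)
from ecckit.simulate import _random_bases

from conftest import rotations_equal

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGT", "ACGT"),  # reverse-complement palindrome
        ("AAACCC", "GGGTTT"),
        ("N", "N"),
        ("ANGT", "ACNT"),
    ],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_non_dna():
    with pytest.raises(ValueError, match="non-DNA"):
        reverse_complement("ACGU")


@settings(derandomize=True, max_examples=100)
@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    assert len(reverse_complement(seq)) == len(seq)


def test_interval_invariants():
    iv = Interval("chrI", 10, 20)
    assert len(iv) == 10
    with pytest.raises(ValueError):
        Interval("chrI", 20, 20)
    with pytest.raises(ValueError):
        Interval("chrI", -1, 5)


# ---------------------------------------------------------------------------
# FASTA


def test_fasta_round_trip(tmp_path, rng):
    genome = ReferenceGenome(
        {f"chr{i}": _random_bases(rng, 1000, 0.45) for i in range(3)}
    )
    path = tmp_path / "g.fasta"
    write_fasta(genome, path)
    back = read_fasta(path)
    assert back.sequences == genome.sequences


def test_fasta_two_records_and_empty(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(">a\nACGT\nACGT\n>b\nGGCC\n")
    g = read_fasta(path)
    assert g.lengths == {"a": 8, "b": 4}
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert read_fasta(empty).sequences == {}


def test_fasta_duplicate_names_rejected(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">a\nACGT\n>a\nGGCC\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_fasta(path)


# ---------------------------------------------------------------------------
# Direct-repeat excision (Cre/loxP-style recombination)


def _build_parent(backbone: str, repeat: str, spacer: str) -> Molecule:
    return Molecule(backbone + repeat + spacer + repeat, "circular")


def test_excision_mini_circle_arithmetic(rng):
    """A 378-bp spacer flanked by 34-bp direct repeats excises as a 412-bp
    circle, leaving a 3034-bp parent when the backbone is 3000 bp."""
    backbone = _random_bases(rng, 3000, 0.5)
    repeat = _random_bases(rng, 34, 0.5)
    spacer = _random_bases(rng, 378, 0.5)
    parent = _build_parent(backbone, repeat, spacer)
    assert len(parent) == 3446
    circle, remainder = excise_between_direct_repeats(parent, 34, 3000, 3412)
    assert len(circle) == 412
    assert len(remainder) == 3034
    assert circle.is_circular and remainder.is_circular


def test_excision_zero_length_spacer(rng):
    backbone = _random_bases(rng, 100, 0.5)
    repeat = _random_bases(rng, 10, 0.5)
    parent = Molecule(backbone + repeat + repeat, "circular")
    circle, remainder = excise_between_direct_repeats(parent, 10, 100, 110)
    assert len(circle) == 10
    assert len(remainder) == 110


def test_excision_random_constructs_match_string_surgery(rng):
    """Products equal an independent cut-and-religate string oracle."""
    for _ in range(25):
        nb = int(rng.integers(20, 200))
        nr = int(rng.integers(8, 30))
        ns = int(rng.integers(0, 100))
        backbone = _random_bases(rng, nb, 0.5)
        repeat = _random_bases(rng, nr, 0.5)
        spacer = _random_bases(rng, ns, 0.5)
        parent = _build_parent(backbone, repeat, spacer)
        circle, remainder = excise_between_direct_repeats(
            parent, nr, nb, nb + nr + ns
        )
        # oracle: cut after each repeat start, religate by hand
        expected_circle = Molecule(repeat + spacer, "circular")
        expected_remainder = Molecule(repeat + backbone, "circular")
        assert rotations_equal(circle, expected_circle)
        assert rotations_equal(remainder, expected_remainder)
        assert len(circle) + len(remainder) == len(parent)


def test_excision_preconditions(rng):
    repeat = _random_bases(rng, 10, 0.5)
    other = reverse_complement(repeat)
    parent = Molecule(_random_bases(rng, 50, 0.5) + repeat + "ACGT" * 5 + other, "circular")
    with pytest.raises(PreconditionError, match="not identical"):
        excise_between_direct_repeats(parent, 10, 50, 80)
    linear = Molecule("ACGT" * 30, "linear")
    with pytest.raises(TopologyError):
        excise_between_direct_repeats(linear, 4, 0, 20)
    # overlapping copies on a short homopolymer circle
    poly = Molecule("A" * 40, "circular")
    with pytest.raises(PreconditionError, match="overlap"):
        excise_between_direct_repeats(poly, 10, 0, 5)


# ---------------------------------------------------------------------------
# Circles from genomic intervals


def test_extract_circle(random_genome):
    iv = Interval("chrI", 100, 600)
    mol = extract_circle_from_genome(random_genome, iv)
    assert len(mol) == 500
    assert mol.is_circular and mol.origin == iv
    # circular adjacency: every junction-spanning k-mer is in the doubled string
    doubled = mol.bases + mol.bases
    for offset in range(490, 500):
        assert mol.circular_slice(offset, 20) in doubled
    # rotation-invariant equality of two rotations
    rot = Molecule(mol.bases[123:] + mol.bases[:123], "circular")
    assert rotations_equal(mol, rot)
    with pytest.raises(IndexError):
        extract_circle_from_genome(random_genome, Interval("chrI", 2900, 3100))


# ---------------------------------------------------------------------------
# Positional deduplication


def _pair(name, start1=100, start2=300, strand1="+", strand2="-"):
    return AlignedPair(name, "chrI", start1, start1 + 100, strand1,
                       start2, start2 + 100, strand2)


def test_dedupe_basic():
    pairs = [_pair("a"), _pair("b"), _pair("c"), _pair("d", start1=200)]
    kept = dedupe_pairs(pairs)
    assert [p.name for p in kept] == ["a", "d"]
    unique = [_pair("x", start1=i) for i in range(5)]
    assert dedupe_pairs(unique) == unique


def test_dedupe_strand_switch():
    pairs = [_pair("a"), _pair("b", strand1="-")]
    assert len(dedupe_pairs(pairs, strand_aware=True)) == 2
    assert len(dedupe_pairs(pairs, strand_aware=False)) == 1


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 5), st.sampled_from("+-")),
        min_size=1,
        max_size=50,
    )
)
def test_dedupe_matches_set_oracle(coords):
    pairs = [
        AlignedPair(f"r{i}", "chrI", s1, s1 + 10, strand, s2, s2 + 10, "-")
        for i, (s1, s2, strand) in enumerate(coords)
    ]
    expected = {
        (p.chrom, p.start1, p.end1, p.start2, p.end2, p.strand1, p.strand2)
        for p in pairs
    }
    assert len(dedupe_pairs(pairs)) == len(expected)


# ---------------------------------------------------------------------------
# Naive exact mapper


def _brute_force_hits(read, genome):
    rc = reverse_complement(read)
    hits = set()
    for chrom, seq in genome.sequences.items():
        for p in range(len(seq) - len(read) + 1):
            window = seq[p : p + len(read)]
            if window == read:
                hits.add((chrom, p, "+"))
            if window == rc and read != rc:
                hits.add((chrom, p, "-"))
    return sorted(hits)


def test_map_exact_planted_and_absent(random_genome):
    read = random_genome.sequences["chrI"][500:560]
    hits = map_exact(read, random_genome)
    assert hits == [("chrI", 500, "+")]
    assert map_exact("A" * 60, random_genome) == []


def test_map_exact_reverse_strand(random_genome):
    read = reverse_complement(random_genome.sequences["chrII"][100:160])
    assert map_exact(read, random_genome) == [("chrII", 100, "-")]


def test_map_exact_matches_sliding_window(rng):
    genome = ReferenceGenome({"chrA": _random_bases(rng, 50_000, 0.5)})
    seq = genome.sequences["chrA"]
    for _ in range(20):
        start = int(rng.integers(0, len(seq) - 40))
        read = seq[start : start + 40]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        assert map_exact(read, genome) == _brute_force_hits(read, genome)
    # a planted duplication must surface at both sites
    dup = seq[1000:1040]
    genome2 = ReferenceGenome({"chrA": seq[:20_000] + dup + seq[20_000:]})
    assert len(map_exact(dup, genome2)) == 2


# ---------------------------------------------------------------------------
# SAM input


def test_read_aligned_pairs_from_sam(tmp_path):
    pysam = pytest.importorskip("pysam")
    path = tmp_path / "pairs.sam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"LN": 5000, "SN": "chrI"}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for name, s1, s2 in [("p1", 100, 300), ("p2", 100, 300), ("p3", 800, 1000)]:
            for i, start in enumerate((s1, s2)):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "A" * 50
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.flag = (0x1 | 0x2 | (0x40 if i == 0 else 0x80)
                          | (0x20 if i == 0 else 0x10))
                a.mapping_quality = 60
                out.write(a)
    from ecckit.core import read_aligned_pairs

    pairs = read_aligned_pairs(path)
    assert [p.name for p in pairs] == ["p1", "p2", "p3"]
    assert pairs[0].chrom == "chrI"
    assert (pairs[0].start1, pairs[0].end1) == (100, 150)
    assert (pairs[0].strand1, pairs[0].strand2) == ("+", "-")
    assert pairs[0].proper_pair
    # positional deduplication collapses p1/p2
    assert [p.name for p in dedupe_pairs(pairs)] == ["p1", "p3"]
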