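"""Detection of the Tn5 9-bp duplication signature of singly cut circles.

A circular molecule cut exactly once by Tn5 linearizes with the 9-bp
target-site duplication at both ends.  Inward-facing paired-end sequencing
therefore reads the same duplicated 9-mer at the start of R1 and at the
start of R2 — on opposite strands.  A read pair is evidence for a singly
tagmented circle iff the first ``d`` bases of R1 equal the reverse
complement of the first ``d`` bases of R2.

Detection is sequence-only: no alignment is needed, so per-sample signature
fractions can be computed straight from FASTQ.  The chance positive rate
for random sequence is 4^-d (~3.8e-6 per pair at d = 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core import PreconditionError, ReadPair, _rc

DEFAULT_DUP_LEN = 9


class UndefinedStatisticError(ValueError):
    """A statistic was requested on an empty input."""


@dataclass(frozen=True)
class SignatureCall:
    """Outcome of signature detection for one read pair."""

    is_evidence: bool
    duplicated_kmer: str | None = None

    def __post_init__(self) -> None:
        if self.is_evidence != (self.duplicated_kmer is not None):
            raise ValueError("duplicated_kmer must be present iff is_evidence")


@dataclass(frozen=True)
class SignatureStats:
    """Per-sample signature counts and fraction (in percent)."""

    n_pairs: int
    n_evidence: int

    @property
    def fraction(self) -> float:
        return 100.0 * self.n_evidence / self.n_pairs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_duplication_signature(
    pair: ReadPair,
    d: int = DEFAULT_DUP_LEN,
    max_mismatch: int = 0,
    orientation: str = "inward",
) -> SignatureCall:
    """Test one read pair for the duplication signature.

    ``orientation="inward"`` (the standard paired-end chemistry) compares
    R1's first ``d`` bases against the reverse complement of R2's first
    ``d`` bases; ``"same"`` compares them directly, for nonstandard preps.
    The match is exact by default; ``max_mismatch`` tolerates substitutions
    at the cost of the analytic false-positive bound.
    """
    if len(pair.r1) < d or len(pair.r2) < d:
        raise PreconditionError(f"both reads must be at least {d} bases long")
    if orientation not in ("inward", "same"):
        raise ValueError(f"unknown orientation {orientation!r}")
    a = pair.r1[:d]
    b = _rc(pair.r2[:d]) if orientation == "inward" else pair.r2[:d]
    if (a == b) if max_mismatch == 0 else (_hamming(a, b) <= max_mismatch):
        return SignatureCall(True, a)
    return SignatureCall(False)


def signature_fraction(
    pairs: Iterable[ReadPair], d: int = DEFAULT_DUP_LEN, max_mismatch: int = 0
) -> SignatureStats:
    """Fraction of pairs carrying the duplication signature, in percent."""
    n_pairs = 0
    n_evidence = 0
    for pair in pairs:
        n_pairs += 1
        if detect_duplication_signature(pair, d, max_mismatch).is_evidence:
            n_evidence += 1
    if n_pairs == 0:
        raise UndefinedStatisticError("signature fraction of an empty sample")
    return SignatureStats(n_pairs, n_evidence)


def signature_fold_enrichment(
    sample: SignatureStats, control: SignatureStats, allow_infinite: bool = False
) -> float:
    """Fold enrichment of the signature fraction in a sample over its control.

    A zero control fraction is an error unless ``allow_infinite`` is set, in
    which case ``inf`` is returned as an explicit sentinel.
    """
    if control.fraction == 0:
        if allow_infinite:
            return float("inf")
        raise ZeroDivisionError("control signature fraction is zero")
    return sample.fraction / control.fraction


def write_signature_report(
    rows: Sequence[tuple[str, SignatureStats, float | None]], path: str | Path
) -> None:
    """Write a per-sample tab-separated signature report.

    Columns: sample, n_pairs, n_evidence, fraction_percent, fold_vs_control
    (empty when no control applies, as for the controls themselves).
    """
    with open(path, "w") as fh:
        fh.write("sample\tn_pairs\tn_evidence\tfraction_percent\tfold_vs_control\n")
        for name, stats, fold in rows:
            fold_s = "" if fold is None else f"{fold:.6g}"
            fh.write(
                f"{name}\t{stats.n_pairs}\t{stats.n_evidence}\t"
                f"{stats.fraction:.6g}\t{fold_s}\n"
            )
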