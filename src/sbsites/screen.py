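"""Junction-read screening: find the transposon end, trim it, keep the flank.

A read is kept iff its 5' prefix matches the library side's transposon
end sequence with at most ``max_end_mismatches`` substitutions (the
LM-PCR amplicon is primer-anchored, so matching is prefix-anchored, not
floating). Kept reads are trimmed at the exact end length; trimmed
fragments shorter than ``min_genomic_len`` are dropped as unmappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .constructs import TransposonConstruct

__all__ = ["TrimmedRead", "ScreenStats", "screen_and_trim", "iter_fastq"]


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    side: str
    fragment: str
    mismatches_in_end: int


@dataclass
class ScreenStats:
    """Per-library screening tally; the three outcomes partition the input."""

    total: int = 0
    matched: int = 0
    too_short: int = 0
    rejected: int = 0

    def balanced(self) -> bool:
        return self.matched + self.too_short + self.rejected == self.total


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def _prefix_mismatches(seq: str, end: str, limit: int) -> int:
    mm = 0
    for a, b in zip(seq, end):
        if a != b:
            mm += 1
            if mm > limit:
                return mm
    return mm


def screen_and_trim(
    reads: str | Path | Iterable[tuple[str, str]],
    construct: TransposonConstruct,
    side: str,
    max_end_mismatches: int = 1,
    min_genomic_len: int = 20,
) -> tuple[list[TrimmedRead], ScreenStats]:
    """Screen a FASTQ file (or (id, seq) stream) for one end's junction reads.

    Returns the kept trimmed reads and a :class:`ScreenStats` in which
    ``matched + too_short + rejected == total``.
    """
    if max_end_mismatches < 0:
        raise ValueError("max_end_mismatches must be >= 0")
    end = construct.end(side)  # raises on invalid side
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    kept: list[TrimmedRead] = []
    stats = ScreenStats()
    for read_id, seq in reads:
        stats.total += 1
        if len(seq) < len(end):
            stats.rejected += 1
            continue
        mm = _prefix_mismatches(seq[: len(end)], end, max_end_mismatches)
        if mm > max_end_mismatches:
            stats.rejected += 1
            continue
        fragment = seq[len(end) :]
        if len(fragment) < min_genomic_len:
            stats.too_short += 1
            continue
        stats.matched += 1
        kept.append(TrimmedRead(read_id, side, fragment, mm))
    return kept, stats
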