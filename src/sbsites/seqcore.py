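"""Sequence primitives and reference genome I/O.

All internal coordinates are 0-based, half-open. User-facing reports
(TSV site lists, run summaries) are 1-based inclusive and say so in
their headers. Reference sequences are restricted to the uppercase
alphabet ``{A, C, G, T, N}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "ReferenceGenome",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "fetch",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N).

    Raises ``ValueError`` on characters outside ``{A,C,G,T,N}``.
    """
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"invalid DNA characters: {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named chromosome with a strand.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class ReferenceGenome:
    """Ordered collection of named chromosome sequences."""

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if name in chroms:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if not _ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"chromosome {name!r} has invalid characters {bad!r}")
            chroms[name] = seq
        self.chromosomes = chroms

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceGenome):
            return NotImplemented
        return self.chromosomes == other.chromosomes

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; minus strand returns the reverse complement."""
        seq = self[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return revcomp(sub) if interval.strand == "-" else sub


def fetch(genome: ReferenceGenome, interval: GenomicInterval) -> str:
    return genome.fetch(interval)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Parse a (multi-line) FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; duplicate record names are rejected.
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        chroms[record.id] = str(record.seq).upper()
    if not chroms:
        # SeqIO silently yields nothing for junk input; distinguish it here.
        text = Path(path).read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise ValueError(f"{path}: sequence data before first FASTA header")
        raise ValueError(f"{path}: no FASTA records found")
    return ReferenceGenome(chroms)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    """Write the genome as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
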