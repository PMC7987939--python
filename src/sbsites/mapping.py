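"""Fragment placement on the reference.

A deterministic seed-and-extend aligner for desk-scale genomes plus SAM
import so an external aligner can substitute.

The internal aligner is exhaustive-equivalent under its mismatch budget:
it seeds ``max_mismatches + 1`` disjoint k-mers spread across the
fragment, so by pigeonhole every alignment with at most
``max_mismatches`` substitutions leaves at least one seed exact and is
therefore found; fragments too short to host that many disjoint seeds
fall back to a vectorized full scan. Candidates are extended by Hamming
comparison over the full fragment on both strands; ``unique`` means a
single best-scoring locus, ``ambiguous`` at least two tied best loci.
No indel alignment is attempted internally; SAM import accepts indel
CIGARs, with the junction taken from the reference placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .seqcore import ReferenceGenome, revcomp

__all__ = [
    "Alignment",
    "KmerIndex",
    "build_index",
    "map_fragment",
    "import_sam",
    "filter_alignments",
    "FilterStats",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class Alignment:
    """Placement of one trimmed fragment (plus-strand leftmost ``start``)."""

    read_id: str
    side: str
    status: str  # unique | ambiguous | unmapped
    chrom: str | None = None
    start: int | None = None
    strand: str | None = None
    mismatches: int | None = None
    length: int | None = None


class KmerIndex:
    """Exact k-mer -> plus-strand position index over a genome.

    Minus-strand occurrences are reached by querying the reverse
    complement of a k-mer, so both strands are represented via
    plus-strand positions. Windows containing N are not indexed.
    """

    def __init__(self, genome: ReferenceGenome, k: int = 12):
        if not 4 <= k <= 31:
            raise ValueError(f"k must be in 4..31, got {k}")
        shortest = min(len(s) for s in genome.chromosomes.values())
        if k > shortest:
            raise ValueError(
                f"k={k} larger than shortest contig (length {shortest})"
            )
        self.genome = genome
        self.k = k
        self.chrom_bytes: dict[str, np.ndarray] = {}
        self._sorted_vals: dict[str, np.ndarray] = {}
        self._sorted_pos: dict[str, np.ndarray] = {}
        for name, seq in genome.chromosomes.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            self.chrom_bytes[name] = arr
            codes = _CODE[arr]
            n = len(seq) - k + 1
            vals = np.zeros(n, dtype=np.int64)
            for j in range(k):
                vals = vals * 4 + codes[j : j + n]
            # exclude windows containing N
            invalid = (codes >= 4).astype(np.int32)
            cs = np.concatenate(([0], np.cumsum(invalid)))
            good = (cs[k:] - cs[:-k]) == 0
            pos = np.nonzero(good)[0]
            order = np.argsort(vals[pos], kind="stable")
            self._sorted_vals[name] = vals[pos][order]
            self._sorted_pos[name] = pos[order]

    def _encode(self, kmer: str) -> int | None:
        codes = _CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if (codes >= 4).any():
            return None
        v = 0
        for c in codes:
            v = v * 4 + int(c)
        return v

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Plus-strand positions of an exact k-mer, across all chromosomes."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        val = self._encode(kmer.upper())
        if val is None:
            return []
        hits: list[tuple[str, int]] = []
        for chrom, vals in self._sorted_vals.items():
            lo = int(np.searchsorted(vals, val, side="left"))
            hi = int(np.searchsorted(vals, val, side="right"))
            hits.extend((chrom, int(p)) for p in self._sorted_pos[chrom][lo:hi])
        return hits


def build_index(genome: ReferenceGenome, k: int = 12) -> KmerIndex:
    return KmerIndex(genome, k)


def _full_scan_hits(
    index: KmerIndex, text_bytes: np.ndarray, strand: str, max_mismatches: int
) -> list[tuple[int, str, int, str]]:
    L = text_bytes.size
    hits = []
    for chrom, arr in index.chrom_bytes.items():
        n = arr.size - L + 1
        if n <= 0:
            continue
        mm = np.zeros(n, dtype=np.int32)
        for j in range(L):
            mm += arr[j : j + n] != text_bytes[j]
        for p in np.nonzero(mm <= max_mismatches)[0]:
            hits.append((int(mm[p]), chrom, int(p), strand))
    return hits


def map_fragment(
    index: KmerIndex,
    genome: ReferenceGenome,
    fragment: str,
    max_mismatches: int = 2,
    read_id: str = "",
    side: str = "left",
) -> Alignment:
    """Best Hamming placement of a fragment on either strand.

    Equivalent to an exhaustive scan of all positions and strands for
    status, locus, strand, and mismatch count (see module docstring).
    """
    fragment = fragment.upper()
    L = len(fragment)
    k = index.k
    if L < k:
        raise ValueError(f"fragment length {L} < k={k}")
    rc = revcomp(fragment)
    frag_bytes = np.frombuffer(fragment.encode(), dtype=np.uint8)
    rc_bytes = np.frombuffer(rc.encode(), dtype=np.uint8)
    nseeds = max_mismatches + 1
    hits: list[tuple[int, str, int, str]]
    if L >= nseeds * k:
        block = L // nseeds
        offsets = [i * block for i in range(nseeds)]
        cands: set[tuple[str, int, str]] = set()
        for text, strand in ((fragment, "+"), (rc, "-")):
            for o in offsets:
                for chrom, pos in index.lookup(text[o : o + k]):
                    cands.add((chrom, pos - o, strand))
        hits = []
        for chrom, start, strand in sorted(cands):
            arr = index.chrom_bytes[chrom]
            if start < 0 or start + L > arr.size:
                continue
            text_bytes = frag_bytes if strand == "+" else rc_bytes
            mm = int((arr[start : start + L] != text_bytes).sum())
            if mm <= max_mismatches:
                hits.append((mm, chrom, start, strand))
    else:
        hits = _full_scan_hits(index, frag_bytes, "+", max_mismatches)
        hits += _full_scan_hits(index, rc_bytes, "-", max_mismatches)
    if not hits:
        return Alignment(read_id, side, "unmapped", length=L)
    best = min(h[0] for h in hits)
    bests = [h for h in hits if h[0] == best]
    if len(bests) > 1:
        return Alignment(read_id, side, "ambiguous", length=L)
    mm, chrom, start, strand = bests[0]
    return Alignment(read_id, side, "unique", chrom, start, strand, mm, L)


def map_fragments(
    index: KmerIndex,
    genome: ReferenceGenome,
    trimmed: Iterable,
    max_mismatches: int = 2,
) -> list[Alignment]:
    """Map a stream of :class:`~sbsites.screen.TrimmedRead`."""
    return [
        map_fragment(
            index, genome, t.fragment, max_mismatches, read_id=t.read_id,
            side=t.side,
        )
        for t in trimmed
    ]


def import_sam(
    path: str | Path,
    side: str,
    genome: ReferenceGenome | None = None,
    mapq_min: int = 20,
) -> list[Alignment]:
    """Read primary records from a SAM file produced by an external aligner.

    Unmapped flag -> ``unmapped``; MAPQ below ``mapq_min`` ->
    ``ambiguous``; coordinates converted from SAM 1-based to internal
    0-based. Records aligned to a contig absent from ``genome`` (when
    given) are an error, as is a missing @SQ header.
    """
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        sq = sam.header.to_dict().get("SQ", [])
        if not sq:
            raise ValueError(f"{path}: SAM header has no @SQ lines")
        if genome is not None:
            missing = {d["SN"] for d in sq} - set(genome.names)
            if missing:
                raise ValueError(
                    f"{path}: SAM contigs absent from reference: {sorted(missing)}"
                )
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            qlen = rec.query_length or 0
            if rec.is_unmapped:
                alignments.append(
                    Alignment(rec.query_name, side, "unmapped", length=qlen)
                )
                continue
            if rec.mapping_quality < mapq_min:
                alignments.append(
                    Alignment(rec.query_name, side, "ambiguous", length=qlen)
                )
                continue
            ref_len = (
                rec.reference_end - rec.reference_start
                if rec.reference_end is not None
                else qlen
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alignments.append(
                Alignment(
                    rec.query_name,
                    side,
                    "unique",
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    int(nm),
                    ref_len,
                )
            )
    return alignments


@dataclass
class FilterStats:
    input: int = 0
    kept: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    too_short: int = 0

    def balanced(self) -> bool:
        return (
            self.kept + self.ambiguous + self.unmapped + self.too_short
            == self.input
        )


def filter_alignments(
    alignments: Sequence[Alignment],
    min_fragment_len: int = 20,
    require_unique: bool = True,
) -> tuple[list[Alignment], FilterStats]:
    """Keep unique alignments of sufficiently long fragments."""
    kept: list[Alignment] = []
    stats = FilterStats()
    for aln in alignments:
        stats.input += 1
        if aln.status == "unmapped":
            stats.unmapped += 1
        elif aln.status == "ambiguous" and require_unique:
            stats.ambiguous += 1
        elif aln.length is not None and aln.length < min_fragment_len:
            stats.too_short += 1
        else:
            stats.kept += 1
            kept.append(aln)
    return kept, stats
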