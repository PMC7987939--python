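"""Integration-site calling, deduplication, and dinucleotide tables.

The target dinucleotide of a junction read is the first two bases of the
mapped genomic fragment in read orientation: for a plus-strand alignment
``genome[start : start+2]``, for a minus-strand alignment the reverse
complement of the last two reference bases of the placement. It is taken
from the mapped *reference* (robust to sequencing error) and reported in
the sequenced orientation with no palindromic collapsing — CA and TG are
counted separately, matching how integration screens tabulate targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mapping import Alignment
from .seqcore import ReferenceGenome, revcomp

__all__ = [
    "IntegrationSite",
    "DinucleotideTable",
    "DINUC_ORDER",
    "call_site",
    "call_sites",
    "dedupe_sites",
    "dinucleotide_table",
    "nonTA_proportion",
    "write_sites_tsv",
    "write_sites_bed",
]

log = logging.getLogger(__name__)

#: Row order used by the standard count-table layout.
DINUC_ORDER = [
    "TA", "CA", "TG", "TT", "AA", "GA", "TC", "AG",
    "CT", "GG", "CC", "AT", "GT", "AC", "GC", "CG",
]


@dataclass(frozen=True)
class IntegrationSite:
    chrom: str
    dinuc_start: int  # 0-based plus-strand position of the pair's first base
    strand: str
    side: str  # left | right
    dinucleotide: str  # as read in the sequenced orientation

    @property
    def is_TA(self) -> bool:
        return self.dinucleotide == "TA"


def call_site(
    alignment: Alignment, genome: ReferenceGenome, side: str | None = None
) -> IntegrationSite | None:
    """Site for one unique alignment; ``None`` if the pair window leaves
    the contig (logged by the caller via :func:`call_sites`)."""
    if alignment.status != "unique":
        raise ValueError("call_site requires a unique alignment")
    side = side or alignment.side
    seq = genome[alignment.chrom]
    if alignment.strand == "+":
        start = alignment.start
    else:
        start = alignment.start + alignment.length - 2
    if start < 0 or start + 2 > len(seq):
        return None
    pair = seq[start : start + 2]
    dinuc = pair if alignment.strand == "+" else revcomp(pair)
    return IntegrationSite(alignment.chrom, start, alignment.strand, side, dinuc)


def call_sites(
    alignments: Iterable[Alignment],
    genome: ReferenceGenome,
    side: str | None = None,
) -> tuple[list[IntegrationSite], int]:
    """Call all sites; returns (sites, number discarded out-of-bounds)."""
    sites: list[IntegrationSite] = []
    discarded = 0
    for aln in alignments:
        site = call_site(aln, genome, side)
        if site is None:
            discarded += 1
        else:
            sites.append(site)
    if discarded:
        log.info("discarded %d sites with out-of-bounds dinucleotide", discarded)
    return sites, discarded


def dedupe_sites(
    sites: Sequence[IntegrationSite],
) -> tuple[list[IntegrationSite], int]:
    """One site per (chrom, dinuc_start, strand, side); idempotent.

    Returns the unique sites in first-seen order and the duplicate count.
    """
    seen: set[tuple[str, int, str, str]] = set()
    unique: list[IntegrationSite] = []
    duplicates = 0
    for s in sites:
        key = (s.chrom, s.dinuc_start, s.strand, s.side)
        if key in seen:
            duplicates += 1
        else:
            seen.add(key)
            unique.append(s)
    return unique, duplicates


@dataclass
class DinucleotideTable:
    """16-way histogram of target dinucleotides for one library."""

    label: str
    counts: dict[str, int] = field(
        default_factory=lambda: {d: 0 for d in DINUC_ORDER}
    )

    def __post_init__(self) -> None:
        full = {d: 0 for d in DINUC_ORDER}
        for d, c in self.counts.items():
            if d not in full:
                raise ValueError(f"invalid dinucleotide {d!r}")
            if c < 0:
                raise ValueError(f"negative count for {d!r}")
            full[d] = int(c)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def nonTA_total(self) -> int:
        return self.total - self.counts["TA"]

    @property
    def nonTA_fraction(self) -> float:
        if self.total == 0:
            return math.nan
        return self.nonTA_total / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dinucleotide": DINUC_ORDER,
             "count": [self.counts[d] for d in DINUC_ORDER]}
        )


def dinucleotide_table(
    sites: Iterable[IntegrationSite | str], label: str
) -> DinucleotideTable:
    """Tally sites (or raw dinucleotide strings) into a table.

    Zero-count dinucleotides are reported explicitly.
    """
    table = DinucleotideTable(label)
    for s in sites:
        dinuc = s if isinstance(s, str) else s.dinucleotide
        if dinuc not in table.counts:
            raise ValueError(f"invalid dinucleotide {dinuc!r}")
        table.counts[dinuc] += 1
    return table


def nonTA_proportion(table: DinucleotideTable) -> float:
    """Non-TA percentage, 100 * (total - TA) / total; NaN on empty input.

    Reports render it to 3 decimals.
    """
    if table.total == 0:
        return math.nan
    return 100.0 * table.nonTA_total / table.total


def format_table(table: DinucleotideTable) -> str:
    """Standard text layout: 16 rows in canonical order, then totals."""
    lines = [f"# library: {table.label}", "dinucleotide\tcount"]
    lines += [f"{d}\t{table.counts[d]}" for d in DINUC_ORDER]
    lines.append(f"total\t{table.total}")
    lines.append(f"non_TA_total\t{table.nonTA_total}")
    pct = nonTA_proportion(table)
    lines.append(
        "non_TA_proportion\t" + ("NA" if math.isnan(pct) else f"{pct:.3f}%")
    )
    return "\n".join(lines) + "\n"


def write_sites_tsv(sites: Sequence[IntegrationSite], path: str | Path) -> None:
    """Site list as TSV; positions are 1-based inclusive (stated in header)."""
    with open(path, "w") as fh:
        fh.write("# positions are 1-based inclusive\n")
        fh.write("chrom\tpos_1based\tstrand\tside\tdinucleotide\tis_TA\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.dinuc_start + 1}\t{s.strand}\t{s.side}\t"
                f"{s.dinucleotide}\t{int(s.is_TA)}\n"
            )


def write_sites_bed(sites: Sequence[IntegrationSite], path: str | Path) -> None:
    """BED6 (0-based half-open) spanning each target dinucleotide."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.dinuc_start}\t{s.dinuc_start + 2}\t"
                f"{s.side}:{s.dinucleotide}\t0\t{s.strand}\n"
            )
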