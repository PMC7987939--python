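"""Synthetic data generator: genomes, integration events, junction reads.

The generator emulates an LM-PCR junction-sequencing experiment on a
transposon integration screen:

* a reference genome of i.i.d. bases at a configurable GC content;
* integration events, most of them *canonical* (both junctions at a TA
  dinucleotide, one genomic position), a minority *aberrant* — exactly
  one junction at a non-TA dinucleotide whose distal flank (the genomic
  bases just past the target dinucleotide, read in the sequenced
  orientation) resembles the transposon end motif, while the opposite
  junction resolves at an ordinary TA;
* two junction read libraries (left and right transposon end), each read
  being the end sequence followed by the genomic fragment starting at
  the target dinucleotide, with PCR duplicates and i.i.d. substitution
  errors.

Read geometry. An event has an orientation (``strand``). For a
plus-orientation event the left-end read continues into the genome
toward higher coordinates (it aligns to the plus strand) and the
right-end read reads the minus strand leftward from the junction; a
minus-orientation event swaps the two. In all cases the first two bases
of the genomic fragment are the target dinucleotide as sequenced.

Event positions are drawn without replacement (all junction positions
distinct across events), so on error-free reads the deduplicated site
set called by the pipeline equals the truth table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constructs import TransposonConstruct
from .seqcore import ReferenceGenome, revcomp

__all__ = [
    "SimulationParams",
    "TrueEvent",
    "ReadSimStats",
    "generate_genome",
    "simulate_integrations",
    "events_to_reads",
    "simulate_dataset",
    "align_strand",
    "truth_site_set",
    "truth_dinucleotides",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Sub-stream labels so genome, events and reads draw from independent,
# reproducible generators derived from the one user seed.
_STAGE_GENOME, _STAGE_EVENTS, _STAGE_READS = 0, 1, 2


@dataclass(kw_only=True)
class SimulationParams:
    """Study conditions for one simulated junction-sequencing run.

    Defaults follow the experimental scale the analysis targets: a
    1 Mb uniform-composition genome, 20,000 events with a ~1.4%
    aberrant (non-TA) fraction, 60 bp reads at Q30 (error rate 1e-3),
    and a mean of 2 PCR copies per junction.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    gc: float = 0.5
    n_events: int = 20_000
    p_nonTA: float = 0.014
    motif_match_prob: float = 0.8
    read_length: int = 60
    error_rate: float = 0.001
    duplicates_mean: float = 2.0
    duplicates_fixed: int | None = None
    quality_char: str = "?"  # Phred+33 Q30
    exclude_cg: bool = False
    both_sides_nonTA: bool = False

    def __post_init__(self) -> None:
        for name, p in (
            ("gc", self.gc),
            ("p_nonTA", self.p_nonTA),
            ("motif_match_prob", self.motif_match_prob),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.duplicates_mean < 1.0:
            raise ValueError("duplicates_mean must be >= 1")
        if self.duplicates_fixed is not None and self.duplicates_fixed < 1:
            raise ValueError("duplicates_fixed must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth integration event.

    ``pos`` is the 0-based position of the target dinucleotide's first
    base — for aberrant events, of the non-TA junction. ``left_pos`` /
    ``right_pos`` give the junction position seen by each library
    (identical for canonical events; the aberrant event's TA-side
    junction is at an independent TA locus). Dinucleotides are reported
    in each side's sequenced orientation.
    """

    chrom: str
    pos: int
    strand: str
    klass: str  # canonical | aberrant
    left_dinuc: str
    right_dinuc: str
    aberrant_side: str  # left | right | both | none
    left_pos: int
    right_pos: int


@dataclass
class ReadSimStats:
    n_reads_left: int = 0
    n_reads_right: int = 0
    skipped_events: int = 0


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def align_strand(event_strand: str, side: str) -> str:
    """Reference strand a junction read of ``side`` aligns to."""
    return "+" if (event_strand == "+") == (side == "left") else "-"


def generate_genome(
    params: SimulationParams, seed: int | None = None
) -> ReferenceGenome:
    """I.i.d. random genome at ``params.gc``; deterministic given the seed.

    Each chromosome is checked to contain at least one TA per 200 bp on
    average and redrawn (bounded) if not — at any reasonable GC this
    never triggers, but it guards degenerate compositions.
    """
    base_seed = params.seed if seed is None else seed
    gc = params.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    for idx, (name, length) in enumerate(params.chrom_lengths.items()):
        if length == 0:
            raise ValueError(f"chromosome {name!r} has zero length")
        if length < 1000:
            raise ValueError(f"chromosome {name!r} shorter than 1 kb ({length})")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(base_seed), _STAGE_GENOME, idx])
        )
        for _ in range(5):
            codes = rng.choice(4, size=length, p=probs)
            seq = _BASES[codes].tobytes().decode()
            if seq.count("TA") >= length / 200:
                break
        else:
            raise RuntimeError(
                f"chromosome {name!r}: TA density below 1/200 bp after 5 redraws"
            )
        chroms[name] = seq
    return ReferenceGenome(chroms)


def _draw_nonTA_dinuc(rng: np.random.Generator, exclude_cg: bool) -> str:
    choices = [d for d in _DINUCS if d != "TA" and not (exclude_cg and d == "CG")]
    return choices[int(rng.integers(len(choices)))]


def _oriented_constraints(
    dinuc: str, motif: str, mask: np.ndarray, strand: str
) -> list[tuple[int, str]]:
    """Base constraints, as (offset from junction position, plus-strand base).

    In the sequenced orientation the fragment reads D1 D2, then distal
    bases +1..+L. On a plus alignment that is genome[p], genome[p+1],
    genome[p+1+j]; on a minus alignment the same window maps to
    genome[p+1-? ] reverse-complemented: D1=comp(genome[p+1]),
    D2=comp(genome[p]), distal +j = comp(genome[p-j]).
    """
    cons: list[tuple[int, str]] = []
    if strand == "+":
        cons.append((0, dinuc[0]))
        cons.append((1, dinuc[1]))
        for j in range(len(motif)):
            if mask[j]:
                cons.append((2 + j, motif[j]))
    else:
        cons.append((0, _COMP[dinuc[1]]))
        cons.append((1, _COMP[dinuc[0]]))
        for j in range(len(motif)):
            if mask[j]:
                cons.append((-1 - j, _COMP[motif[j]]))
    return cons


def _find_locus(
    chrom_bytes: dict[str, np.ndarray],
    constraints: Sequence[tuple[int, str]],
    margin: int,
    used: set[tuple[str, int]],
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Uniform draw over all genome positions satisfying the constraints."""
    candidates: list[tuple[str, int]] = []
    for chrom, arr in chrom_bytes.items():
        lo, hi = margin, len(arr) - margin - 2  # positions p, exclusive hi
        if hi <= lo:
            continue
        n = hi - lo
        ok = np.ones(n, dtype=bool)
        for off, base in constraints:
            ok &= arr[lo + off : lo + off + n] == ord(base)
        candidates.extend(
            (chrom, int(p) + lo)
            for p in np.nonzero(ok)[0]
            if (chrom, int(p) + lo) not in used
        )
    if not candidates:
        raise RuntimeError(
            "no genome locus satisfies the aberrant-junction constraint "
            f"{constraints!r} (margin {margin})"
        )
    return candidates[int(rng.integers(len(candidates)))]


def simulate_integrations(
    genome: ReferenceGenome,
    construct: TransposonConstruct,
    params: SimulationParams,
) -> list[TrueEvent]:
    """Draw ground-truth integration events.

    With probability ``1 - p_nonTA`` an event is canonical and placed at
    a uniformly chosen unused TA dinucleotide. Otherwise it is aberrant:
    one side (uniform) gets a non-TA dinucleotide drawn uniformly from
    the 15 non-TA dinucleotides (CG optionally excluded) at a locus
    whose distal bases +1..+L match the end motif independently with
    probability ``motif_match_prob`` per position; the other side stays
    TA at an independent TA locus.
    """
    rng = _rng(params.seed, _STAGE_EVENTS)
    margin = params.read_length
    chrom_bytes = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8)
        for name, seq in genome.chromosomes.items()
    }

    ta_pool: list[tuple[str, int]] = []
    for name, seq in genome.chromosomes.items():
        top = len(seq) - margin - 2
        start = seq.find("TA", margin)
        while 0 <= start < top:
            ta_pool.append((name, start))
            start = seq.find("TA", start + 1)
    if not ta_pool:
        raise RuntimeError("genome has no eligible TA sites away from contig edges")
    order = rng.permutation(len(ta_pool))
    ta_iter = iter(order)

    used: set[tuple[str, int]] = set()

    def next_ta() -> tuple[str, int]:
        for i in ta_iter:
            loc = ta_pool[int(i)]
            if loc not in used:
                return loc
        raise RuntimeError("TA site pool exhausted; genome too small for n_events")

    events: list[TrueEvent] = []
    for _ in range(params.n_events):
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() >= params.p_nonTA:
            chrom, p = next_ta()
            used.add((chrom, p))
            events.append(
                TrueEvent(chrom, p, strand, "canonical", "TA", "TA", "none", p, p)
            )
            continue
        ab_side = "left" if rng.random() < 0.5 else "right"
        sides = ("left", "right") if params.both_sides_nonTA else (ab_side,)
        side_pos: dict[str, int] = {}
        side_chrom: dict[str, str] = {}
        side_dinuc: dict[str, str] = {}
        for side in ("left", "right"):
            if side in sides:
                dinuc = _draw_nonTA_dinuc(rng, params.exclude_cg)
                motif = construct.motif(side)
                mask = rng.random(len(motif)) < params.motif_match_prob
                cons = _oriented_constraints(
                    dinuc, motif, mask, align_strand(strand, side)
                )
                chrom, p = _find_locus(chrom_bytes, cons, margin, used, rng)
                used.add((chrom, p))
                side_chrom[side], side_pos[side], side_dinuc[side] = chrom, p, dinuc
            else:
                chrom, p = next_ta()
                used.add((chrom, p))
                side_chrom[side], side_pos[side], side_dinuc[side] = chrom, p, "TA"
        primary = sides[0]
        events.append(
            TrueEvent(
                side_chrom[primary],
                side_pos[primary],
                strand,
                "aberrant",
                side_dinuc["left"],
                side_dinuc["right"],
                "both" if params.both_sides_nonTA else ab_side,
                side_pos["left"],
                side_pos["right"],
            )
        )
    return events


def _side_chrom(event: TrueEvent, side: str) -> str:
    # Events keep one chrom except two-locus aberrant events, which by
    # construction draw both junctions from the same genome; the truth
    # table stores a single chrom per event.
    return event.chrom


def _fragment(
    genome: ReferenceGenome, chrom: str, pos: int, strand: str, length: int
) -> str | None:
    seq = genome[chrom]
    if strand == "+":
        if pos + length > len(seq):
            return None
        return seq[pos : pos + length]
    if pos + 2 - length < 0:
        return None
    return revcomp(seq[pos + 2 - length : pos + 2])


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        codes = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode()


def events_to_reads(
    events: Sequence[TrueEvent],
    genome: ReferenceGenome,
    construct: TransposonConstruct,
    params: SimulationParams,
    left_path: str | Path,
    right_path: str | Path,
    truth_path: str | Path | None = None,
) -> ReadSimStats:
    """Emit the two junction FASTQ libraries (and optionally the truth TSV).

    Every event yields >=1 read per side: transposon end sequence, then
    the genomic fragment starting at the junction dinucleotide, read off
    the strand implied by the event orientation. Byte-identical output
    for identical params + seed.
    """
    for side in ("left", "right"):
        if params.read_length <= len(construct.end(side)) + 20:
            raise ValueError(
                "read_length must exceed the end length by more than 20 bases"
            )
    rng = _rng(params.seed, _STAGE_READS)
    stats = ReadSimStats()
    with open(left_path, "w") as fl, open(right_path, "w") as fr:
        handles = {"left": fl, "right": fr}
        for i, ev in enumerate(events):
            frags: dict[str, str] = {}
            for side, pos in (("left", ev.left_pos), ("right", ev.right_pos)):
                end = construct.end(side)
                frag = _fragment(
                    genome,
                    _side_chrom(ev, side),
                    pos,
                    align_strand(ev.strand, side),
                    params.read_length - len(end),
                )
                if frag is None:
                    break
                frags[side] = end + frag
            if len(frags) < 2:
                stats.skipped_events += 1
                continue
            for side in ("left", "right"):
                if params.duplicates_fixed is not None:
                    ndup = params.duplicates_fixed
                else:
                    ndup = 1 + int(rng.poisson(params.duplicates_mean - 1.0))
                for d in range(ndup):
                    seq = _apply_errors(frags[side], params.error_rate, rng)
                    rid = f"ev{i:07d}:{side}:{d}"
                    handles[side].write(
                        f"@{rid}\n{seq}\n+\n{params.quality_char * len(seq)}\n"
                    )
                if side == "left":
                    stats.n_reads_left += ndup
                else:
                    stats.n_reads_right += ndup
    if truth_path is not None:
        write_truth(events, truth_path)
    return stats


_TRUTH_HEADER = (
    "chrom\tpos_1based\tstrand\tclass\tleft_dinuc\tright_dinuc\t"
    "aberrant_side\tleft_pos_1based\tright_pos_1based"
)


def write_truth(events: Iterable[TrueEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.pos + 1}\t{ev.strand}\t{ev.klass}\t"
                f"{ev.left_dinuc}\t{ev.right_dinuc}\t{ev.aberrant_side}\t"
                f"{ev.left_pos + 1}\t{ev.right_pos + 1}\n"
            )


def read_truth(path: str | Path) -> list[TrueEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise ValueError(f"unexpected truth header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            events.append(
                TrueEvent(
                    f[0], int(f[1]) - 1, f[2], f[3], f[4], f[5], f[6],
                    int(f[7]) - 1, int(f[8]) - 1,
                )
            )
    return events


def truth_site_set(
    events: Iterable[TrueEvent], side: str
) -> set[tuple[str, int, str]]:
    """Expected unique (chrom, dinuc_start, strand) per library."""
    out = set()
    for ev in events:
        pos = ev.left_pos if side == "left" else ev.right_pos
        out.add((_side_chrom(ev, side), pos, align_strand(ev.strand, side)))
    return out


def truth_dinucleotides(events: Iterable[TrueEvent], side: str) -> list[str]:
    return [
        ev.left_dinuc if side == "left" else ev.right_dinuc for ev in events
    ]


@dataclass
class SimulatedDataset:
    genome_path: Path
    left_fastq: Path
    right_fastq: Path
    truth_path: Path
    genome: ReferenceGenome
    events: list[TrueEvent]
    read_stats: ReadSimStats


def simulate_dataset(
    params: SimulationParams,
    construct: TransposonConstruct,
    outdir: str | Path,
) -> SimulatedDataset:
    """Generate genome + events + reads + truth into ``outdir``."""
    from .seqcore import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(params)
    events = simulate_integrations(genome, construct, params)
    genome_path = outdir / "genome.fa"
    left = outdir / "reads_left.fastq"
    right = outdir / "reads_right.fastq"
    truth = outdir / "truth.tsv"
    write_fasta(genome, genome_path)
    stats = events_to_reads(events, genome, construct, params, left, right, truth)
    return SimulatedDataset(genome_path, left, right, truth, genome, events, stats)
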