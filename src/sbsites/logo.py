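"""Flank extraction, position frequency matrices, and consensus logos.

Windows span positions ``-W..-1, D1, D2, +1..+W`` in the *sequenced*
orientation of each site: D1 D2 is the target dinucleotide, the negative
side is junction-proximal (toward the sequencing primer / transposon
end) and the positive side distal. For a plus-strand site the window is
``genome[dinuc_start - W : dinuc_start + 2 + W]``; a minus-strand site
takes the reverse complement of the same interval, so D1 D2 always
equals the reported dinucleotide.

Information content per column is the Kullback-Leibler divergence from
the background in bits, ``IC_j = sum_b f_bj * log2(f_bj / q_b)`` with
``0*log(0) = 0`` — between 0 and 2 bits under the uniform background.
Consensus is the per-column argmax base, ``N`` on ties. No small-sample
correction is applied by default; a Schneider-style correction can be
switched on for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import ReferenceGenome, revcomp
from .sites import IntegrationSite

__all__ = [
    "FlankWindow",
    "PositionFrequencyMatrix",
    "extract_flanks",
    "build_pfm",
    "information_content",
    "combine_sides",
    "end_match_score",
    "side_bias",
    "render_pfm_tsv",
    "render_text_logo",
    "render_svg_logo",
]

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class FlankWindow:
    """A site plus its length-(2W+2) window in sequenced orientation."""

    site: IntegrationSite | None
    seq: str


def extract_flanks(
    genome: ReferenceGenome,
    sites: Iterable[IntegrationSite],
    W: int = 10,
) -> list[FlankWindow]:
    """Strand-normalized flank windows; out-of-bounds or N-containing
    windows are excluded (counts logged)."""
    if W < 1:
        raise ValueError("W must be >= 1")
    windows: list[FlankWindow] = []
    n_oob = n_with_n = 0
    for site in sites:
        seq = genome[site.chrom]
        lo = site.dinuc_start - W
        hi = site.dinuc_start + 2 + W
        if lo < 0 or hi > len(seq):
            n_oob += 1
            continue
        window = seq[lo:hi]
        if "N" in window:
            n_with_n += 1
            continue
        if site.strand == "-":
            window = revcomp(window)
        windows.append(FlankWindow(site, window))
    if n_oob or n_with_n:
        log.info(
            "extract_flanks: excluded %d out-of-bounds and %d N-containing windows",
            n_oob, n_with_n,
        )
    return windows


class PositionFrequencyMatrix:
    """Per-position base counts/frequencies over aligned windows."""

    def __init__(
        self, counts: np.ndarray, n_sequences: int, pseudocount: float = 0.0
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L array (rows A,C,G,T)")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.counts = counts
        self.n_sequences = int(n_sequences)
        self.pseudocount = float(pseudocount)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def half_width(self) -> int:
        """W for a 2W+2 window layout."""
        if self.length < 4 or self.length % 2:
            raise ValueError(
                f"length {self.length} is not a 2W+2 flank-window layout"
            )
        return (self.length - 2) // 2

    def frequencies(self) -> np.ndarray:
        denom = self.n_sequences + 4.0 * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    def information_content(
        self, background: Sequence[float] | None = None
    ) -> np.ndarray:
        return information_content(self, background)

    def consensus(self) -> str:
        """Argmax base per position; ``N`` marks a tie."""
        out = []
        for j in range(self.length):
            col = self.counts[:, j]
            m = col.max()
            winners = np.nonzero(col == m)[0]
            out.append(_BASES[winners[0]] if winners.size == 1 else "N")
        return "".join(out)

    def position_labels(self) -> list[str]:
        W = self.half_width
        return (
            [str(-w) for w in range(W, 0, -1)]
            + ["D1", "D2"]
            + [f"+{w}" for w in range(1, W + 1)]
        )


def build_pfm(
    windows: Sequence[FlankWindow | str], pseudocount: float = 0.1
) -> PositionFrequencyMatrix:
    """Tally aligned equal-length windows into a PFM."""
    seqs = [w.seq if isinstance(w, FlankWindow) else w for w in windows]
    if not seqs:
        raise ValueError("no windows to build a PFM from")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("windows have unequal lengths")
    counts = np.zeros((4, L))
    for s in seqs:
        for j, base in enumerate(s.upper()):
            try:
                counts[_BASE_INDEX[base], j] += 1
            except KeyError:
                raise ValueError(f"invalid base {base!r} in window") from None
    return PositionFrequencyMatrix(counts, len(seqs), pseudocount)


def information_content(
    pfm: PositionFrequencyMatrix, background: Sequence[float] | None = None
) -> np.ndarray:
    """Per-position IC in bits against the background (default uniform)."""
    if background is None:
        q = np.full(4, 0.25)
    else:
        q = np.asarray(background, dtype=float)
        if q.shape != (4,) or (q <= 0).any():
            raise ValueError("background must be 4 positive frequencies")
        if abs(q.sum() - 1.0) > 1e-6:
            raise ValueError(f"background sums to {q.sum()}, not 1")
    f = pfm.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / q[:, None]), 0.0)
    return terms.sum(axis=0)


def combine_sides(
    left_windows: Sequence[FlankWindow | str],
    right_windows: Sequence[FlankWindow | str],
    pseudocount: float = 0.1,
) -> PositionFrequencyMatrix:
    """Pool the two libraries into one PFM, aligned by the transposon ends.

    Right-library windows are reverse complemented — mapping their
    proximal side onto the distal positions of the shared frame — and
    pooled with the left windows; ``n = n_left + n_right``.
    """
    left = [w.seq if isinstance(w, FlankWindow) else w for w in left_windows]
    right = [w.seq if isinstance(w, FlankWindow) else w for w in right_windows]
    flipped = [revcomp(s) for s in right]
    pooled = list(left) + flipped
    if not pooled:
        raise ValueError("no windows to combine")
    L = len(pooled[0])
    if any(len(s) != L for s in pooled):
        raise ValueError("left and right windows have unequal lengths")
    return build_pfm(pooled, pseudocount)


def end_match_score(
    pfm: PositionFrequencyMatrix, end_motif: str, offset: int = 1
) -> float:
    """Fraction of motif positions whose consensus base equals the motif.

    The motif is compared at distal positions ``offset .. offset+L-1``
    (offset >= 1); consensus ties (``N``) count as mismatches.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1 (distal positions)")
    W = pfm.half_width
    start = W + 1 + offset
    stop = start + len(end_motif)
    if stop > pfm.length:
        raise ValueError(
            f"motif at offset +{offset} overruns the window (W={W})"
        )
    consensus = pfm.consensus()[start:stop]
    matches = sum(c == m for c, m in zip(consensus, end_motif.upper()))
    return matches / len(end_motif)


def side_bias(
    pfm: PositionFrequencyMatrix,
    W: int | None = None,
    L: int = 4,
    background: Sequence[float] | None = None,
) -> float:
    """Mean IC over distal positions +1..+L minus proximal -L..-1.

    Positive values indicate the consensus sits on the distal flank —
    opposite the sequenced junction.
    """
    if W is None:
        W = pfm.half_width
    if L > W:
        raise ValueError(f"L={L} exceeds window half-width W={W}")
    ic = information_content(pfm, background)
    distal = ic[W + 2 : W + 2 + L]
    proximal = ic[W - L : W]
    return float(distal.mean() - proximal.mean())


def render_pfm_tsv(pfm: PositionFrequencyMatrix) -> str:
    """Positions as rows (-W..+W with D1/D2 labeled), counts, freqs, IC."""
    f = pfm.frequencies()
    ic = information_content(pfm)
    cons = pfm.consensus()
    lines = [
        f"# n_sequences={pfm.n_sequences} pseudocount={pfm.pseudocount}",
        "position\tA\tC\tG\tT\tfA\tfC\tfG\tfT\tIC_bits\tconsensus",
    ]
    try:
        labels = pfm.position_labels()
    except ValueError:
        labels = [str(j) for j in range(pfm.length)]
    for j, lab in enumerate(labels):
        c = pfm.counts[:, j]
        lines.append(
            f"{lab}\t" + "\t".join(f"{int(x)}" for x in c) + "\t"
            + "\t".join(f"{x:.4f}" for x in f[:, j])
            + f"\t{ic[j]:.4f}\t{cons[j]}"
        )
    return "\n".join(lines) + "\n"


def render_text_logo(pfm: PositionFrequencyMatrix, height: int = 20) -> str:
    """Plain-text stack: per position, bases tall in proportion to IC share."""
    f = pfm.frequencies()
    ic = information_content(pfm)
    cols = []
    for j in range(pfm.length):
        stack = []
        order = np.argsort(-f[:, j], kind="stable")
        for b in order:
            h = int(round(f[b, j] * ic[j] / 2.0 * height))
            stack.extend([_BASES[b]] * h)
        stack += ["."] * (height - len(stack))
        cols.append(stack[:height])
    try:
        labels = pfm.position_labels()
    except ValueError:
        labels = [str(j) for j in range(pfm.length)]
    rows = []
    for r in range(height - 1, -1, -1):
        rows.append("".join(col[r] for col in cols))
    rows.append("-" * pfm.length)
    marks = "".join(
        "D" if lab in ("D1", "D2") else ("+" if lab.startswith("+") else "-")
        for lab in labels
    )
    rows.append(marks)
    return "\n".join(rows) + "\n"


_SVG_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def render_svg_logo(pfm: PositionFrequencyMatrix, col_width: int = 20,
                    height: int = 100) -> str:
    """Minimal SVG letter-stack logo (letter height proportional to
    frequency x column IC, full height = 2 bits)."""
    f = pfm.frequencies()
    ic = information_content(pfm)
    width = col_width * pfm.length
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height + 14}" font-family="monospace">'
    ]
    for j in range(pfm.length):
        y = float(height)
        order = np.argsort(f[:, j], kind="stable")
        for b in order:
            h = f[b, j] * ic[j] / 2.0 * height
            if h < 0.5:
                continue
            y -= h
            cx = j * col_width + col_width / 2
            scale = h / 12.0
            parts.append(
                f'<text x="{cx:.1f}" y="{y + h:.1f}" text-anchor="middle" '
                f'font-size="12" fill="{_SVG_COLORS[_BASES[b]]}" '
                f'transform="translate({cx:.1f},{y + h:.1f}) '
                f'scale(1,{scale:.3f}) translate({-cx:.1f},{-(y + h):.1f})">'
                f"{_BASES[b]}</text>"
            )
    try:
        labels = pfm.position_labels()
    except ValueError:
        labels = [str(j) for j in range(pfm.length)]
    for j, lab in enumerate(labels):
        if lab in ("D1", "D2") or lab in ("-1", "+1"):
            parts.append(
                f'<text x="{j * col_width + col_width / 2:.1f}" '
                f'y="{height + 12}" text-anchor="middle" font-size="8">'
                f"{lab}</text>"
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
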