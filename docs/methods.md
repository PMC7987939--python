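# Methods

This note documents the model, conventions, parameter choices, and
known limitations of `sbsites`. Coordinates are 0-based half-open
internally; every user-facing table is 1-based inclusive and says so in
its header.

## Read geometry and the junction dinucleotide

A junction read is the transposon end sequence followed by the genomic
fragment, which begins at the target dinucleotide and runs away from
the insertion point. After end trimming and alignment, the target
dinucleotide is defined as the first two bases of the fragment *in read
orientation*: `genome[start : start+2]` for a plus-strand placement,
and the reverse complement of the last two reference bases of the
placement for a minus-strand one. The dinucleotide is taken from the
mapped reference rather than the read (the reference is error-free by
definition; a diagnostic read-derived mode is easy to add but the
reference mode is the default and the only one used in the pipeline).
Dinucleotides are reported in sequenced orientation with no
palindromic collapsing — CA and TG are distinct rows, matching the
standard 16-row accounting of integration screens.

Sites are deduplicated on `(chrom, dinuc_start, strand, side)`. Two
genuine integrations at the same coordinates on the same strand and
side are indistinguishable from PCR duplicates and count once; this is
the usual unique-site convention and a known limitation. Read-level
counting (no deduplication) is available by simply tabulating the
called sites before `dedupe_sites`.

## Flank windows and logos

Windows span `−W…−1, D1, D2, +1…+W` in the sequenced orientation of
each site: for a plus-strand site `genome[p−W : p+2+W]`, for a
minus-strand site the reverse complement of the same interval. The
negative (proximal) side is toward the sequencing primer, i.e. the side
occupied by the transposon after insertion; the positive (distal) side
is the genomic continuation present in the read. Windows containing N
or overhanging a contig edge are excluded and counted.

PFM frequencies use a symmetric pseudocount, default 0.1 — enough to
stabilize logos built from tens of non-TA sites without visibly
flattening columns at n in the hundreds. Information content is the KL
divergence from a uniform background in bits (a genome-composition
background can be supplied); no small-sample correction is applied by
default because the corrected and uncorrected profiles order the same
comparisons here, and the summary statistics are differences or argmax
reads of the same profile. Consensus is the per-column argmax with `N`
on ties, and ties score as mismatches in the end-match statistic —
deterministic and conservative.

`side_bias` = mean IC over `+1..+L` minus mean IC over `−L..−1`
(default L = 4, the end-motif length; W defaults to 10, wide enough for
the motif plus context). `end_match_score` compares the consensus at
`+1..+L` against the configured end motif.

### Combining the two libraries

The combined frame pools left-library windows as-is with
reverse-complemented right-library windows, aligning both junctions on
a common frame anchored at the transposon end. Because each library
carries its own motif signal distally, the flip also mirrors the right
library's signal to the proximal side as the motif's reverse
complement: a combined PFM therefore shows the motif consensus at
`+1..+L` (dominated by the left windows, with the right windows
contributing background there) and its mirror at `−L..−1`. The distal
consensus read `+1..+L` is the quantity the pipeline reports and tests.

## Transposon constructs

End sequences are configuration, not constants. The shipped presets use
synthetic 20 bp ends whose last four bases (the junction-adjacent
motif, in read orientation) are the documented motifs: `ACTG` native,
`ATCG` for the C,T→T,C transition mutants. Because the two SB ends are
inverted repeats, both ends read the same motif in their respective
sequenced orientations, so one motif string serves both sides. The
`pYT53` preset encodes an A>T transversion at the second nucleotide of
the left end *in transposon orientation* (`CAGT…` → `CTGT…`), which in
read orientation gives the motif `ACAG`; users who adopt a different
orientation convention override the end sequences via the registry
file. `mutate_end` warns (but does not refuse) when the first motif
base is touched, since the terminal nucleotides are critical for
transposition and real mutant designs keep them.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes:

* **Genome** — i.i.d. bases at a configurable GC (default 0.5, one
  1 Mb chromosome). A sanity check requires ≥ 1 TA per 200 bp on
  average, redrawing (bounded) if violated.
* **Events** — `n_events` (default 20,000) integrations, each with a
  uniform orientation. With probability `1 − p_nonTA` (default
  `p_nonTA = 0.014`, the non-TA frequency typical of SB screens) the
  event is canonical: one TA position, both junctions TA. Otherwise it
  is aberrant: one side (uniform) gets a non-TA dinucleotide drawn
  uniformly from the 15 non-TA dinucleotides (CG optionally excluded to
  mimic CpG-depleted genomes) at a locus whose distal bases `+1..+L`
  match the end motif independently with probability
  `motif_match_prob = 0.8` per position; the opposite junction resolves
  at an independent TA locus. `motif_match_prob` is a free parameter of
  the generative model — no estimate of it exists, 0.8 produces
  logos with the strong-but-imperfect consensus the analysis is built
  to expose. A flag allows both-sides-non-TA events for robustness
  testing. Aberrant loci are found by exact vectorized pattern matching
  over the genome (uniform over all satisfying positions), so the
  generator fails only when no locus satisfies the constraint at all.
* **Position sampling is without replacement.** All junction positions
  are distinct across events. A uniform-with-replacement draw of 20,000
  events over the ~62,000 TA sites of a 1 Mb genome would collide at
  the dedup key for ~8% of events, silently deflating totals and
  biasing the recovered non-TA rate upward; distinct positions keep the
  estimator unbiased and make truth recovery exact. Events are also
  kept `read_length` away from contig edges so no read is truncated.
* **Reads** — per event and side: end sequence + genomic fragment of
  `read_length − end_length` bases (default 60 − 20 = 40). PCR
  duplicates are 1 + Poisson(mean − 1) copies (default mean 2), or a
  fixed count for arithmetic tests. Sequencing errors are i.i.d.
  substitutions at `error_rate` (default 1e-3, matching the constant
  Q30 quality string); indels are not modeled — the analysis is
  junction-anchored and indel realism would add noise without
  exercising new logic. Output is byte-identical for identical
  parameters and seed; the one user seed feeds separate derived streams
  for genome, events, and reads.

What the generator does **not** model: chromatin accessibility and
hot-TA-site preference, local hopping, amplification bias, chimeric
reads, real genome composition (repeats, CpG islands). Passing tests
therefore demonstrate the pipeline's correctness and the internal
consistency of the aberrant-integration signature, not that real
genomes are this easy to map uniquely or that real non-TA sites match
the motif this cleanly.

## Internal aligner

A k-mer index (default k = 12, 2-bit codes, sorted-array lookups; N
windows unindexed) seeds `max_mismatches + 1` disjoint k-mers evenly
spread across the fragment, on both strands. By pigeonhole, any
placement with at most `max_mismatches` substitutions leaves at least
one seed window exact, so the candidate set provably contains every
qualifying locus; candidates are extended by full-length Hamming
comparison and the best score wins. Fragments too short to host the
required disjoint seeds (< `(max_mismatches+1)·k`) fall back to a
vectorized exhaustive scan, preserving the guarantee. `unique` means a
single best-scoring locus; a tie at the best score (including the same
position on both strands of a palindrome) is `ambiguous` and carries no
coordinates — the simplest rule that an exhaustive-scan oracle can
check exactly. Defaults: `max_mismatches = 2` over fragments of ≥ 20 bp
(`min_fragment_len = 20`, below which unique mapping is not credible),
unique-only filtering. All thresholds are config-exposed. SAM import
(primary records only) maps the unmapped flag to `unmapped`,
MAPQ < 20 to `ambiguous`, and converts to 0-based coordinates; indel
CIGARs are accepted with the junction taken from the reference
placement.

Screening defaults: `max_end_mismatches = 1` over the 20 bp end anchor
(tolerates Q30-level error without admitting spurious matches) and
`min_genomic_len = 20`.

## Rates, intervals, and rounding

Non-TA proportions are reported to 3 decimals. The event-level non-TA
rate (simulation mode, both libraries present) is
`100 · (nonTA_L + nonTA_R) / ((total_L + total_R)/2)`: each event
contributes one site per library and an aberrant event is non-TA in
exactly one, so this estimates the per-event aberrant probability. Its
95% CI is Clopper–Pearson on the pooled site-level proportion, scaled
by two. Degenerate inputs: an empty library tabulates as all-zero
counts with proportion NA; an empty non-TA set skips the logo step with
a note and exits successfully.

## Problem sizes used in validation

Unit and property tests run on 1–300 kb genomes with 25–3,000 events.
The end-to-end recovery check uses the full default conditions (1 Mb,
20,000 events, planted 1.4% non-TA, error-free reads) and asserts that
the recovered rate's 95% CI covers the planted value and that the
called site set equals the simulator's truth exactly, per side. The
consensus-asymmetry checks use 400 all-aberrant events at
`motif_match_prob = 0.9` on 100 kb, for both the native and the
mutant-end construct. Aligner correctness is checked against an
independent exhaustive Hamming-scan oracle on 1,000 random fragments
(exact, reverse-complemented, mutated, and unrelated) against a 50 kb
genome.
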