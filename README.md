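# sbsites

Analysis of **Sleeping Beauty (SB) transposon integration sites** from
junction (LM-PCR-style) sequencing reads.

SB, a Tc1/mariner-family DNA transposon, canonically integrates into TA
dinucleotides, which are duplicated on both sides of the inserted
element. Deep sequencing of transposon–genome junctions shows a small
minority of integrations (~1.4% in typical screens, much higher in some
datasets) at non-TA dinucleotides. These non-TA events have two striking
properties: the non-TA dinucleotide appears at **one junction only**
(the other junction still resolves at TA), and the flanking genomic
sequence carries a consensus that **matches the transposon end
sequence** and always sits on the flank **opposite the sequenced
junction** — the signature of an aberrant integration pathway guided by
transposon-end / target-DNA interaction rather than by the transposase
alone.

`sbsites` turns that analysis into a tested, reusable pipeline:

* **screen** junction reads for the SB left/right end sequence and trim
  it (`sbsites.screen`);
* **map** the genomic fragments with a deterministic, exhaustive-
  equivalent seed-and-extend aligner, or import SAM from an external
  aligner such as Bowtie2 (`sbsites.mapping`);
* **call** integration sites, classify the target dinucleotide (TA vs
  the 15 non-TA dinucleotides, no palindromic collapsing), deduplicate
  PCR copies, and tabulate 16-way dinucleotide count tables with non-TA
  proportions (`sbsites.sites`);
* **build consensus logos** from strand-normalized flanking windows:
  position frequency matrices, per-position information content,
  left/right/combined frames, and the two summary statistics
  *side bias* (distal-minus-proximal mean IC) and *end-match score*
  (fraction of motif positions reproduced by the consensus)
  (`sbsites.logo`);
* **simulate** genomes, ground-truth integration events (canonical and
  aberrant), and junction FASTQ libraries with PCR duplicates and
  sequencing error, so the whole chain is testable with no external
  data (`sbsites.simulate`).

## The statistics at the core

For aligned flank windows spanning positions `−W…−1, D1, D2, +1…+W`
(D1 D2 = target dinucleotide, negative side junction-proximal), the
position frequency matrix with pseudocount `c` is
`f_bj = (n_bj + c) / (N + 4c)`, and per-position information content is
the Kullback–Leibler divergence from background `q` in bits:

```
IC_j = Σ_b f_bj · log2(f_bj / q_b),   0 ≤ IC_j ≤ 2 for uniform q
```

The junction-side asymmetry statistic is
`side_bias = mean(IC_{+1..+L}) − mean(IC_{−L..−1})`; positive values
put the consensus on the distal flank, opposite the sequencing primer.
The correspondence between consensus and transposon end is
`end_match_score`, the fraction of the `L` distal positions whose
consensus base equals the end motif (`ACTG` for native SB ends in read
orientation; `ATCG` for the transition-mutant ends; ties score as
mismatches).

The non-TA proportion of a library is `100 × (total − TA) / total` over
unique sites. In simulations, where every event contributes one site to
each library and an aberrant event is non-TA in exactly one of them,
the event-level non-TA rate is the pooled site-level proportion scaled
by two, with an exact (Clopper–Pearson) binomial confidence interval.

## Worked example

Simulate a screen of 2,000 events on a 200 kb genome with 5% aberrant
integrations and run the full pipeline:

```
sbsites run --seed 11 --out demo_run --n-events 2000 \
    --genome-length 200000 --p-non-ta 0.05 --error-rate 0.001
```

This prints (abridged):

```
sbsites run — construct pYT11, mode simulate, seed 11

== left library ==
reads: 4014 total, 4012 end-matched, 0 too short, 2 rejected
alignments: 4012 kept, 0 ambiguous, 0 unmapped, 0 too short
unique sites: 1999 (2013 duplicates removed)
dinucleotide	count
TA	1941
CA	3
...
total	1999
non-TA proportion	2.901%
nonTA logo: n=58, side_bias=1.132 bits, end_match=1.00 (logo_left_nonTA.logo.txt)
TA logo: n=1941, side_bias=0.000 bits, end_match=0.25 (logo_left_TA.logo.txt)
```

Reading the numbers: each library's non-TA proportion is about half the
planted 5% event rate (an aberrant event is non-TA in only one
library). The non-TA logo of each library has strongly positive side
bias and end-match 1.00 — its consensus reproduces the transposon end
motif `ACTG` on the distal flank — while the TA logo is flat outside
D1 D2 (side bias 0.000). The combined-frame PFM
(`demo_run/logo_combined_nonTA.pfm.tsv`) shows the distal consensus
`ACTG` at `+1..+4` with IC rising to ~0.5 bits per position, against a
~0.01-bit background. Switching `--construct` to the mutant preset
`pYT23` switches the recovered consensus to `ATCG` with no other
change.

Every run also writes site lists (TSV, 1-based, and BED6), per-library
count tables, PFM/text/SVG logos, and a `summary.json` whose stage
counts balance exactly (reads in = kept + too-short + rejected, and so
on down the chain).

Real data enter either as FASTQ libraries plus a reference FASTA
(`mode: reads` in a `RunConfig` YAML) or as SAM alignments from an
external aligner (`mode: sam`); for a public junction-sequencing run
such as SRA SRR1634458, align the end-trimmed reads to hg38 with your
aligner of choice and hand the SAM files to the same pipeline.

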