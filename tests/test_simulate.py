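import math

import pytest
from scipy.stats import binomtest

from sbsites.simulate import (
    SimulationParams,
    align_strand,
    events_to_reads,
    generate_genome,
    read_truth,
    simulate_dataset,
    simulate_integrations,
    truth_site_set,
)
from sbsites.seqcore import revcomp


def params(**kw):
    base = dict(
        seed=7,
        chrom_lengths={"chr1": 50_000},
        n_events=200,
        p_nonTA=0.1,
        motif_match_prob=0.8,
        error_rate=0.0,
        duplicates_fixed=1,
    )
    base.update(kw)
    return SimulationParams(**base)


def oriented_window(genome, chrom, pos, strand, up, down):
    """Sequenced-orientation context around a junction dinucleotide:
    ``up`` proximal bases, the dinucleotide, ``down`` distal bases."""
    seq = genome[chrom]
    if strand == "+":
        return seq[pos - up : pos + 2 + down]
    return revcomp(seq[pos - down : pos + 2 + up])


class TestGenerateGenome:
    def test_deterministic(self):
        p = params()
        assert generate_genome(p) == generate_genome(p)

    def test_gc_zero_is_at_only(self):
        g = generate_genome(params(gc=0.0))
        assert set(g["chr1"]) <= {"A", "T"}

    def test_ta_frequency_matches_closed_form(self):
        # i.i.d. uniform bases: P(TA at a position) = 1/16
        p = params(chrom_lengths={"chr1": 100_000})
        seq = generate_genome(p)["chr1"]
        count = sum(
            seq[i : i + 2] == "TA" for i in range(len(seq) - 1)
        )
        n = len(seq) - 1
        assert binomtest(count, n, 1 / 16).pvalue > 1e-4

    def test_sub_kilobase_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(params(chrom_lengths={"chr1": 500}))


class TestSimulateIntegrations:
    def test_all_canonical_when_p_zero(self, native_construct):
        p = params(p_nonTA=0.0)
        evs = simulate_integrations(generate_genome(p), native_construct, p)
        assert all(e.klass == "canonical" for e in evs)
        assert all(e.left_dinuc == e.right_dinuc == "TA" for e in evs)

    def test_canonical_events_sit_on_ta(self, native_construct):
        p = params(p_nonTA=0.0, n_events=50)
        g = generate_genome(p)
        for e in simulate_integrations(g, native_construct, p):
            assert g[e.chrom][e.pos : e.pos + 2] == "TA"

    def test_forced_motif_match(self, native_construct):
        # p_nonTA=1, motif_match_prob=1: every distal flank equals the motif
        p = params(p_nonTA=1.0, motif_match_prob=1.0, n_events=30)
        g = generate_genome(p)
        for e in simulate_integrations(g, native_construct, p):
            side = e.aberrant_side
            pos = e.left_pos if side == "left" else e.right_pos
            win = oriented_window(g, e.chrom, pos, align_strand(e.strand, side), 0, 4)
            dinuc, distal = win[:2], win[2:]
            assert dinuc != "TA"
            assert distal == native_construct.motif(side)

    def test_aberrant_events_keep_ta_on_other_side(self, native_construct):
        p = params(p_nonTA=1.0, n_events=40)
        g = generate_genome(p)
        for e in simulate_integrations(g, native_construct, p):
            other = "right" if e.aberrant_side == "left" else "left"
            dinuc = e.left_dinuc if other == "left" else e.right_dinuc
            assert dinuc == "TA"
            pos = e.left_pos if other == "left" else e.right_pos
            assert g[e.chrom][pos : pos + 2] == "TA"

    def test_class_balance_binomial(self, native_construct):
        p = params(n_events=3000, p_nonTA=0.1, chrom_lengths={"chr1": 300_000})
        evs = simulate_integrations(generate_genome(p), native_construct, p)
        k = sum(e.klass == "aberrant" for e in evs)
        assert binomtest(k, 3000, 0.1).pvalue > 0.01

    def test_positions_unique_across_events(self, native_construct):
        p = params(n_events=300)
        evs = simulate_integrations(generate_genome(p), native_construct, p)
        positions = [(e.chrom, e.left_pos) for e in evs]
        positions += [(e.chrom, e.right_pos) for e in evs if e.right_pos != e.left_pos]
        assert len(positions) == len(set(positions))


class TestEventsToReads:
    def test_deterministic_bytes(self, native_construct, tmp_path):
        p = params(error_rate=0.001, duplicates_fixed=None)
        files = []
        for run in ("a", "b"):
            d = tmp_path / run
            ds = simulate_dataset(p, native_construct, d)
            files.append(
                tuple(f.read_bytes() for f in (ds.left_fastq, ds.right_fastq, ds.truth_path))
            )
        assert files[0] == files[1]

    def test_error_free_left_read_structure(self, native_construct, tmp_path):
        p = params(p_nonTA=0.0, n_events=10)
        ds = simulate_dataset(p, native_construct, tmp_path)
        end = native_construct.left_end
        lines = ds.left_fastq.read_text().splitlines()
        ids, seqs = lines[0::4], lines[1::4]
        for rid, seq in zip(ids, seqs):
            ev = ds.events[int(rid[3:10])]
            assert seq.startswith(end)
            frag = seq[len(end):]
            assert frag[:2] == "TA"
            expected = oriented_window(
                ds.genome, ev.chrom, ev.left_pos,
                align_strand(ev.strand, "left"), 0, len(frag) - 2,
            )
            assert frag == expected

    def test_fixed_duplicates_read_count(self, native_construct, tmp_path):
        p = params(n_events=25, duplicates_fixed=3)
        ds = simulate_dataset(p, native_construct, tmp_path)
        assert ds.read_stats.n_reads_left == 3 * 25
        assert ds.read_stats.n_reads_right == 3 * 25
        assert ds.read_stats.skipped_events == 0

    def test_truth_tsv_round_trip(self, native_construct, tmp_path):
        ds = simulate_dataset(params(n_events=30), native_construct, tmp_path)
        assert read_truth(ds.truth_path) == ds.events

    def test_read_length_must_exceed_end(self, native_construct, tmp_path):
        p = params(read_length=30)
        g = generate_genome(p)
        evs = simulate_integrations(g, native_construct, p)
        with pytest.raises(ValueError, match="read_length"):
            events_to_reads(
                evs, g, native_construct, p,
                tmp_path / "l.fq", tmp_path / "r.fq",
            )


def test_truth_site_set_strand_convention(native_construct):
    p = params(n_events=20, p_nonTA=0.0)
    g = generate_genome(p)
    evs = simulate_integrations(g, native_construct, p)
    left = truth_site_set(evs, "left")
    right = truth_site_set(evs, "right")
    # canonical events: same position, opposite strands between libraries
    assert {(c, p_) for c, p_, _ in left} == {(c, p_) for c, p_, _ in right}
    for chrom, pos, strand in left:
        assert (chrom, pos, "+" if strand == "-" else "-") in right
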