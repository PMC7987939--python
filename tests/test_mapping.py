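import numpy as np
import pytest

from sbsites.mapping import (
    Alignment,
    build_index,
    filter_alignments,
    import_sam,
    map_fragment,
)
from sbsites.seqcore import ReferenceGenome, revcomp


def brute_force_map(genome, fragment, max_mismatches):
    """Independent oracle: exhaustive Hamming scan of every position/strand."""
    hits = []
    for strand, text in (("+", fragment), ("-", revcomp(fragment))):
        for chrom, seq in genome.chromosomes.items():
            for start in range(len(seq) - len(text) + 1):
                mm = sum(a != b for a, b in zip(seq[start : start + len(text)], text))
                if mm <= max_mismatches:
                    hits.append((mm, chrom, start, strand))
    if not hits:
        return ("unmapped", None, None, None, None)
    best = min(h[0] for h in hits)
    bests = [h for h in hits if h[0] == best]
    if len(bests) > 1:
        return ("ambiguous", None, None, None, None)
    mm, chrom, start, strand = bests[0]
    return ("unique", chrom, start, strand, mm)


class TestKmerIndex:
    def test_example_positions(self):
        g = ReferenceGenome({"c": "ACGTACGT" + "T" * 1})
        idx = build_index(g, k=4)
        assert [(c, p) for c, p in idx.lookup("ACGT")] == [("c", 0), ("c", 4)]

    def test_determinism(self):
        g = ReferenceGenome({"c": "ACGTACGTTTACGGA"})
        a, b = build_index(g, 5), build_index(g, 5)
        for kmer in ("ACGTA", "TTTTT", "TTACG"):
            assert a.lookup(kmer) == b.lookup(kmer)

    def test_k_exceeding_shortest_contig_rejected(self):
        g = ReferenceGenome({"c1": "ACGTACGTACGT", "c2": "ACGT"})
        with pytest.raises(ValueError, match="shortest contig"):
            build_index(g, 8)

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        g = ReferenceGenome({"c": seq})
        idx = build_index(g, 8)
        for _ in range(50):
            start = int(rng.integers(0, len(seq) - 8))
            kmer = seq[start : start + 8]
            naive = [
                ("c", i)
                for i in range(len(seq) - 7)
                if seq[i : i + 8] == kmer
            ]
            assert sorted(idx.lookup(kmer)) == naive

    def test_n_windows_not_indexed(self):
        g = ReferenceGenome({"c": "ACGTNACGTACGTT"})
        idx = build_index(g, 4)
        assert sorted(idx.lookup("ACGT")) == [("c", 0), ("c", 5), ("c", 9)]
        assert idx.lookup("CGTN") == []


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(42)
    return ReferenceGenome({"c": "".join(rng.choice(list("ACGT"), size=8000))})


@pytest.fixture(scope="module")
def index(genome):
    return build_index(genome, 12)


class TestMapFragment:
    def test_unique_substring(self, genome, index):
        frag = genome["c"][1000:1040]
        aln = map_fragment(index, genome, frag, 2)
        assert (aln.status, aln.chrom, aln.start, aln.strand, aln.mismatches) == (
            "unique", "c", 1000, "+", 0,
        )

    def test_revcomp_maps_minus(self, genome, index):
        frag = revcomp(genome["c"][2000:2040])
        aln = map_fragment(index, genome, frag, 2)
        assert (aln.status, aln.start, aln.strand) == ("unique", 2000, "-")

    def test_two_exact_loci_are_ambiguous(self):
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), size=40))
        filler = "".join(rng.choice(list("ACGT"), size=200))
        g = ReferenceGenome({"c": filler + core + filler[::-1] + core + filler})
        aln = map_fragment(build_index(g, 12), g, core, 2)
        assert aln.status == "ambiguous"
        assert aln.chrom is None and aln.start is None

    def test_no_match_is_unmapped(self, genome, index):
        aln = map_fragment(index, genome, "A" * 40, 2)
        if aln.status != "unmapped":  # astronomically unlikely on random genome
            assert "A" * 38 in genome["c"]

    def test_strand_consistency(self, genome, index):
        frag = genome["c"][3000:3040]
        fwd = map_fragment(index, genome, frag, 2)
        rev = map_fragment(index, genome, revcomp(frag), 2)
        assert (fwd.chrom, fwd.start) == (rev.chrom, rev.start)
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_short_fragment_uses_full_scan(self, genome, index):
        # below (max_mm+1)*k the mapper falls back to exhaustive scanning
        frag = genome["c"][4000:4020]
        aln = map_fragment(index, genome, frag, 2)
        expected = brute_force_map(genome, frag, 2)
        assert (aln.status, aln.chrom, aln.start, aln.strand, aln.mismatches) == expected

    def test_mismatched_fragment_found_wherever_errors_fall(self, genome, index):
        # two substitutions placed inside the first and last seed windows
        frag = list(genome["c"][5000:5040])
        for pos in (2, 38):
            frag[pos] = "A" if frag[pos] != "A" else "C"
        frag = "".join(frag)
        aln = map_fragment(index, genome, frag, 2)
        expected = brute_force_map(genome, frag, 2)
        assert (aln.status, aln.chrom, aln.start, aln.strand, aln.mismatches) == expected


class TestImportSam:
    SAM = (
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:chr1\tLN:6000\n"
        "r_plus\t0\tchr1\t100\t60\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
        "r_unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 40 + "\t*\n"
        "r_minus\t16\tchr1\t200\t60\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
        "r_lowmapq\t0\tchr1\t300\t5\t40M\t*\t0\t0\t" + "A" * 40 + "\t*\n"
    )

    def test_import(self, tmp_path):
        path = tmp_path / "aln.sam"
        path.write_text(self.SAM)
        alns = {a.read_id: a for a in import_sam(path, "left")}
        assert alns["r_plus"].status == "unique"
        assert alns["r_plus"].start == 99  # SAM POS 100 -> 0-based
        assert alns["r_plus"].strand == "+"
        assert alns["r_minus"].strand == "-"
        assert alns["r_unmapped"].status == "unmapped"
        assert alns["r_lowmapq"].status == "ambiguous"

    def test_missing_sq_header_rejected(self, tmp_path):
        path = tmp_path / "nohdr.sam"
        path.write_text("@HD\tVN:1.6\n")
        with pytest.raises(ValueError, match="@SQ"):
            import_sam(path, "left")

    def test_unknown_contig_rejected(self, tmp_path):
        path = tmp_path / "aln.sam"
        path.write_text(self.SAM)
        genome = ReferenceGenome({"chrX": "ACGT" * 2000})
        with pytest.raises(ValueError, match="chr1"):
            import_sam(path, "left", genome=genome)


class TestFilterAlignments:
    def test_mixed_fixture(self):
        alns = [
            Alignment("a", "left", "unique", "c", 10, "+", 0, 40),
            Alignment("b", "left", "ambiguous", length=40),
            Alignment("c", "left", "unmapped", length=40),
            Alignment("d", "left", "unique", "c", 50, "-", 1, 10),  # too short
            Alignment("e", "left", "unique", "c", 90, "+", 2, 25),
        ]
        kept, stats = filter_alignments(alns, min_fragment_len=20)
        assert [a.read_id for a in kept] == ["a", "e"]
        assert (stats.input, stats.kept, stats.ambiguous, stats.unmapped,
                stats.too_short) == (5, 2, 1, 1, 1)
        assert stats.balanced()

    def test_all_unique_kept(self):
        alns = [
            Alignment(str(i), "left", "unique", "c", i, "+", 0, 30)
            for i in range(5)
        ]
        kept, stats = filter_alignments(alns)
        assert len(kept) == 5 and stats.kept == 5
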