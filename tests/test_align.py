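"""Read preparation, the seed-and-extend aligner, and SAM interchange."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import exhaustive_best_score, suffix_adapter_scan

from cracpipe.align import (
    AlignedRead,
    Aligner,
    collapse_duplicates,
    lift_all,
    prepare_reads,
    read_sam,
    trim_adapter,
    write_sam,
)
from cracpipe.genome import Genome, revcomp
from cracpipe.junctions import build_junction_library
from cracpipe.simulate import ForgeSpec, SimConfig, forge_genome, simulate_reads


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(12)
    g = Genome()
    g.add("chrR", "".join(rng.choice(list("ACGT"), size=2000)))
    return g


class TestCollapse:
    def test_merges_identical_sequences(self):
        reads = [("a", "ACGT"), ("b", "ACGT"), ("c", "ACGG")]
        assert collapse_duplicates(reads) == [("a", "ACGT", 2), ("c", "ACGG", 1)]

    def test_empty_stream(self):
        assert collapse_duplicates([]) == []

    def test_thousand_copies(self):
        reads = [(f"r{i}", "ACGTACGT") for i in range(1000)]
        assert collapse_duplicates(reads) == [("r0", "ACGTACGT", 1000)]


class TestTrimAdapter:
    def test_no_match_left_untouched(self):
        assert trim_adapter("ACGTACGT", "AGATC") == "ACGTACGT"

    def test_exact_prefix_match_trims(self):
        assert trim_adapter("ACGTAGATC", "AGATCGG") == "ACGT"

    def test_short_insert_discarded_by_prepare(self):
        out = prepare_reads([("r", "ACGTAGATC")], "AGATCGG", min_length=15)
        assert out == []

    def test_full_adapter_after_insert(self, random_genome):
        insert = random_genome["chrR"][100:130]
        adapter = "TGGCGTCGTCTGCCGTGGCGT"
        assert trim_adapter(insert + adapter, adapter) == insert

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_suffix_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 60))))
        adapter = "TGGCGTCGTCTGCCGTGGCGT"
        if rng.random() < 0.5:
            seq = seq + adapter[: int(rng.integers(1, len(adapter)))]
        assert trim_adapter(seq, adapter) == suffix_adapter_scan(seq, adapter)


class TestAligner:
    def test_exact_read(self, random_genome):
        read = random_genome["chrR"][100:130]
        aln = Aligner(random_genome).align("r", read)
        assert (aln.ref, aln.strand, aln.start) == ("chrR", "+", 100)
        assert aln.cigar_string() == "30M"
        assert aln.soft3 == ""

    def test_deletion_read(self, random_genome):
        # seed shorter than the 10 nt before the gap so the 5' k-mer is
        # contiguous; locus 101 has a unique optimal gap placement
        from cracpipe.align import AlignParams

        chrom = random_genome["chrR"]
        read = chrom[101:111] + chrom[113:131]
        aln = Aligner(random_genome, params=AlignParams(seed_length=10)).align("r", read)
        assert aln.start == 101
        assert aln.cigar_string() == "10M2D18M"
        # brute-force check: this is the best single-gap placement
        best = exhaustive_best_score(read, [chrom, revcomp(chrom)])
        assert aln.score == best

    def test_soft_clipped_tail(self, random_genome):
        chrom = random_genome["chrR"]
        prefix = chrom[100:120]
        read = prefix + "AAAA"
        # ensure the tail cannot be templated at this locus
        assert not chrom[120:126].startswith("A")
        aln = Aligner(random_genome).align("r", read)
        assert aln.cigar_string() == "20M4S"
        assert aln.soft3 == "AAAA"

    def test_minus_strand_read(self, random_genome):
        chrom = random_genome["chrR"]
        read = revcomp(chrom[300:340])
        aln = Aligner(random_genome).align("r", read)
        assert (aln.strand, aln.start) == ("-", 300)
        assert aln.cigar_string() == "40M"

    def test_no_seed_hit_unmapped(self, random_genome):
        assert Aligner(random_genome).align("r", "N" * 30) is None

    def test_soft_clip_conservation(self, random_genome):
        """Read sequence = genome-reconstructed aligned part + soft3."""
        chrom = random_genome["chrR"]
        rng = np.random.default_rng(3)
        al = Aligner(random_genome)
        for _ in range(50):
            s = int(rng.integers(0, len(chrom) - 45))
            read = chrom[s : s + 40]
            if rng.random() < 0.5:
                read += "A" * int(rng.integers(2, 6))
            aln = al.align("r", read)
            assert aln is not None
            assert aln.strand == "+"
            recon = chrom[aln.start : aln.start + aln.ref_span]
            # drop deleted reference bases from the reconstruction
            pos = 0
            kept = []
            for n, op in aln.cigar:
                if op == "M":
                    kept.append(recon[pos : pos + n])
                    pos += n
                elif op in "DN":
                    pos += n
            recon_read = "".join(kept) + aln.soft3
            assert len(recon_read) == len(read)
            mismatches = sum(a != b for a, b in zip(recon_read, read))
            assert mismatches <= aln.nm  # identical up to recorded mismatches

    def test_mapped_fraction_monotone_in_error_rate(self):
        spec = ForgeSpec(mrna_spliced=0, mrna_intronless=3, trna=1, trna_spliced=0,
                         snorna=1, snrna=0, rrna_35s=0, rrna_5s=0, cut=0, sut=0, scr1=0)
        genome, feats, _ = forge_genome(spec, seed=5)
        al = Aligner(genome)
        fractions = []
        for err in (0.0, 0.05, 0.15):
            cfg = SimConfig(n_reads=800, crosslink_sites={}, seq_error=err, seed=4)
            reads, _ = simulate_reads(genome, feats, cfg)
            alns, unmapped = al.align_all(prepare_reads(reads, cfg.adapter))
            total = len(alns) + unmapped
            fractions.append(len(alns) / total)
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[0] > fractions[2]

    def test_multi_mapper_flagged_and_dropped(self):
        g = Genome()
        seg = "ACGTTGCAGGCTAGCTTACGCGT"
        g.add("c", seg + "TTTTTTTTTT" + seg)
        al = Aligner(g)
        aln = al.align("r", seg)
        assert aln.multi
        alns, dropped = al.align_all([("r", seg, 1)])
        assert alns == [] and dropped == 1

    def test_junction_read_lifts_to_m_n_m(self, tiny_genome, spliced_feature):
        lib = build_junction_library([spliced_feature], tiny_genome, flank=8)
        al = Aligner(tiny_genome, lib)
        mature = spliced_feature.mature_sequence(tiny_genome)
        read = mature[2:18]  # spans the junction at mature position 10
        aln = al.align("r", read, 1)
        assert aln is not None and aln.is_junction
        (lifted,) = lift_all([aln], lib)
        assert lifted.ref == "chrT"
        assert lifted.cigar_string() == "8M10N8M"
        assert lifted.start == 2


class TestOracleEquivalence:
    def test_scores_match_exhaustive_dp(self):
        spec = ForgeSpec(mrna_spliced=0, mrna_intronless=2, trna=1, trna_spliced=0,
                         snorna=1, snrna=0, rrna_35s=0, rrna_5s=0, cut=0, sut=0,
                         scr1=0, spacer=60)
        genome, feats, _ = forge_genome(spec, seed=8)
        assert len(genome["chrS"]) <= 5000
        cfg = SimConfig(n_reads=60, crosslink_sites={}, seq_error=0.0, seed=6)
        reads, _ = simulate_reads(genome, feats, cfg)
        al = Aligner(genome)
        refs = [genome["chrS"], revcomp(genome["chrS"])]
        agree = 0
        for rid, seq in reads:
            seq = trim_adapter(seq, cfg.adapter)
            aln = al.align(rid, seq)
            if aln is not None and aln.score == exhaustive_best_score(seq, refs):
                agree += 1
        assert agree >= 0.99 * len(reads)


class TestSam:
    def _simulated_alignments(self, n=100):
        genome, feats, sites = forge_genome(ForgeSpec(), seed=9)
        cfg = SimConfig(n_reads=n * 3, crosslink_sites={}, seed=3)
        reads, _ = simulate_reads(genome, feats, cfg)
        lib = build_junction_library(feats, genome, flank=60)
        al = Aligner(genome, lib)
        alns, _ = al.align_all(prepare_reads(reads, cfg.adapter))
        return genome, lift_all(alns, lib)[:n]

    def test_round_trip_identity(self, tmp_path):
        genome, alns = self._simulated_alignments()
        p = tmp_path / "a.sam"
        write_sam(p, alns, genome)
        back = read_sam(p)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert (a.read_id, a.ref, a.strand, a.start) == (b.read_id, b.ref, b.strand, b.start)
            assert a.cigar == b.cigar
            assert a.seq == b.seq
            assert a.soft3 == b.soft3
            assert a.count == b.count

    def test_pos_is_one_based_in_sam(self, tmp_path, random_genome):
        aln = AlignedRead("r", "chrR", "+", 100, [(5, "M"), (1, "D"), (5, "M")],
                          seq="A" * 10)
        p = tmp_path / "b.sam"
        write_sam(p, [aln], random_genome)
        line = [l for l in p.read_text().splitlines() if not l.startswith("@")][0]
        assert line.split("\t")[3] == "101"
        assert read_sam(p)[0].start == 100

    def test_hard_clip_rejected(self, tmp_path):
        p = tmp_path / "h.sam"
        p.write_text(
            "@SQ\tSN:chrR\tLN:2000\n"
            "r1\t0\tchrR\t1\t60\t5H10M\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        with pytest.raises(ValueError, match="unsupported CIGAR"):
            read_sam(p)

    def test_equals_and_x_normalized_to_m(self, tmp_path):
        p = tmp_path / "x.sam"
        p.write_text(
            "@SQ\tSN:chrR\tLN:2000\n"
            "r1\t0\tchrR\t1\t60\t4=2X4=\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        (aln,) = read_sam(p)
        assert aln.cigar == [(10, "M")]
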