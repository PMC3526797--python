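"""Pileup tracks, metagene matrices, tRNA profiles and bedGraph IO."""

import numpy as np
import pytest

from cracpipe.align import AlignedRead, Aligner, lift_all, prepare_reads
from cracpipe.annotation import Feature
from cracpipe.classify import FeatureIndex
from cracpipe.coverage import (
    metagene_3ss,
    pileup,
    read_bedgraph,
    trna_profile,
    write_bedgraph,
)
from cracpipe.genome import Genome
from cracpipe.junctions import build_junction_library
from cracpipe.simulate import (
    ForgeSpec,
    PositionalProfile,
    SimConfig,
    forge_genome,
    simulate_reads,
    sites_with_delta,
)
from cracpipe.tails import call_tails, filter_a_tailed


def _read(start, cigar, rid="r", strand="+", count=1):
    qlen = sum(n for n, op in cigar if op in "MIS")
    return AlignedRead(rid, "c", strand, start, cigar, seq="N" * qlen, count=count)


@pytest.fixture
def flat_genome():
    g = Genome()
    g.add("c", "A" * 100)
    return g


class TestPileup:
    def test_single_read_hits(self):
        track = pileup([_read(0, [(10, "M")])], "c", 0, 20)
        assert np.all(track.values[:10] == 1e6)
        assert np.all(track.values[10:] == 0)

    def test_deletion_track(self):
        aln = _read(0, [(4, "M"), (2, "D"), (4, "M")])
        dels = pileup([aln], "c", 0, 10, kind="dels")
        hits = pileup([aln], "c", 0, 10, kind="hits")
        assert list(np.nonzero(dels.values)[0]) == [4, 5]
        assert dels.values[4] == dels.values[5] == 1e6
        assert hits.values[4] == hits.values[5] == 0

    def test_n_gap_not_covered(self):
        aln = _read(0, [(4, "M"), (10, "N"), (4, "M")])
        track = pileup([aln], "c", 0, 20)
        assert np.all(track.values[4:14] == 0)
        assert np.all(track.values[14:18] == 1e6)

    def test_region_outside_genome_is_error(self, flat_genome):
        with pytest.raises(ValueError, match="outside"):
            pileup([], "c", 0, 500, genome=flat_genome)

    def test_mass_conservation(self):
        """Total hits mass equals sum of M lengths times per-read weight."""
        rng = np.random.default_rng(1)
        alns = [
            _read(int(rng.integers(0, 50)), [(int(rng.integers(5, 20)), "M")],
                  count=int(rng.integers(1, 4)))
            for _ in range(30)
        ]
        total = sum(a.count for a in alns)
        track = pileup(alns, "c", 0, 100, total_mapped=total)
        expected = sum(a.count * a.ref_span for a in alns) * 1e6 / total
        assert track.values.sum() == pytest.approx(expected)

    def test_atailed_track_bounded_by_total(self, forged):
        genome, feats, sites = forged
        cfg = SimConfig(n_reads=3000, crosslink_sites=sites_with_delta(sites, 0.3), seed=14)
        reads, _ = simulate_reads(genome, feats, cfg)
        lib = build_junction_library(feats, genome, flank=60)
        al = Aligner(genome, lib)
        alns, _ = al.align_all(prepare_reads(reads, cfg.adapter))
        alns = lift_all(alns, lib)
        calls = call_tails(alns, genome)
        tailed = filter_a_tailed(alns, calls)
        total_units = sum(a.count for a in alns)
        L = len(genome["chrS"])
        t_all = pileup(alns, "chrS", 0, L, total_mapped=total_units)
        t_tail = pileup(tailed, "chrS", 0, L, total_mapped=total_units)
        assert np.all(t_tail.values <= t_all.values + 1e-9)

    def test_dels_to_hits_mass_ratio_tracks_delta(self, forged):
        genome, feats, sites = forged
        delta = 0.3
        cfg = SimConfig(
            n_reads=20000,
            crosslink_sites=sites_with_delta(sites, delta),
            profile=PositionalProfile(peak_weight=1.0, width=6.0),
            seed=15,
        )
        reads, manifest = simulate_reads(genome, feats, cfg)
        lib = build_junction_library(feats, genome, flank=60)
        al = Aligner(genome, lib)
        alns, _ = al.align_all(prepare_reads(reads, cfg.adapter))
        alns = lift_all(alns, lib)
        total_units = sum(a.count for a in alns)
        L = len(genome["chrS"])
        dels = pileup(alns, "chrS", 0, L, kind="dels", total_mapped=total_units).values.sum()
        hits = pileup(alns, "chrS", 0, L, kind="hits", total_mapped=total_units).values.sum()
        # expected from the simulation truth itself
        true_del = sum(len(r.deletions) for r in manifest.records)
        true_cov = sum(r.genomic_end - r.genomic_start - len(r.deletions)
                       for r in manifest.records)
        assert dels / hits == pytest.approx(true_del / true_cov, rel=0.2)


class TestMetagene:
    def _spliced_setup(self):
        g = Genome()
        rng = np.random.default_rng(2)
        g.add("c", "".join(rng.choice(list("ACGT"), size=1200)))
        long_gene = Feature("LONG", "c", "+", [(100, 200), (600, 700)], "mRNA")
        short_gene = Feature("SHORT", "c", "+", [(800, 850), (950, 1000)], "mRNA")
        return g, [long_gene, short_gene]

    def test_rows_ordered_by_intron_length(self):
        g, feats = self._spliced_setup()
        mg = metagene_3ss([], feats, g, window=(50, 20))
        assert list(mg.matrix.index) == ["LONG", "SHORT"]
        assert mg.row_meta["intron_length"].tolist() == [400, 100]

    def test_exon2_reads_land_right_of_anchor(self):
        g, feats = self._spliced_setup()
        alns = [_read(610, [(30, "M")], rid=f"r{i}") for i in range(5)]
        mg = metagene_3ss(alns, feats, g, window=(50, 30), total_mapped=5)
        row = mg.matrix.loc["LONG"].to_numpy()
        assert np.nansum(row[: mg.anchor_col]) == 0
        assert np.nansum(row[mg.anchor_col :]) > 0

    def test_no_spliced_genes_is_error(self, flat_genome):
        f = Feature("I", "c", "+", [(0, 50)], "mRNA")
        with pytest.raises(ValueError):
            metagene_3ss([], [f], flat_genome)

    def test_weighted_genes_get_proportional_mass(self):
        spec = ForgeSpec(mrna_spliced=4, mrna_intronless=0, trna=0, trna_spliced=0,
                         snorna=0, snrna=0, rrna_35s=0, rrna_5s=0, cut=0, sut=0, scr1=0)
        genome, feats, _ = forge_genome(spec, seed=17)
        spliced = [f for f in feats if f.spliced]
        long_ids = [f.id for f in spliced
                    if f.introns[0][1] - f.introns[0][0] > 200]
        cfg = SimConfig(
            n_reads=20000, class_weights={"mRNA": 1.0}, crosslink_sites={}, pi_a={},
            feature_weights={fid: 3.0 for fid in long_ids}, seed=18,
        )
        reads, _ = simulate_reads(genome, feats, cfg)
        lib = build_junction_library(feats, genome, flank=60)
        al = Aligner(genome, lib)
        alns, _ = al.align_all(prepare_reads(reads, cfg.adapter))
        alns = lift_all(alns, lib)
        mg = metagene_3ss(alns, feats, genome, window=(100, 50),
                          total_mapped=sum(a.count for a in alns))
        sums = np.nansum(mg.matrix.to_numpy(), axis=1)
        by_gene = dict(zip(mg.matrix.index, sums))
        long_mean = np.mean([by_gene[i] for i in long_ids])
        short_mean = np.mean([v for k, v in by_gene.items() if k not in long_ids])
        assert long_mean / short_mean == pytest.approx(3.0, rel=0.35)


class TestTrnaProfile:
    def _trnas(self):
        g = Genome()
        rng = np.random.default_rng(4)
        g.add("c", "".join(rng.choice(list("ACGT"), size=600)))
        t1 = Feature("T1", "c", "+", [(100, 180)], "tRNA")  # 80 nt
        t2 = Feature("T2", "c", "+", [(300, 330), (350, 390)], "tRNA")  # 90 nt precursor
        return g, [t1, t2]

    def test_ranked_by_precursor_length_with_intron(self):
        g, feats = self._trnas()
        mg = trna_profile([], feats, g, flank=20)
        assert list(mg.matrix.index) == ["T2", "T1"]
        assert mg.row_meta.loc[0, "has_intron"]

    def test_mature_reads_leave_flanks_empty(self):
        g, feats = self._trnas()
        alns = [_read(110, [(40, "M")], rid=f"r{i}") for i in range(3)]
        mg = trna_profile(alns, feats, g, flank=20, total_mapped=3)
        row = mg.matrix.loc["T1"].to_numpy(dtype=float)
        assert np.nansum(row[: mg.anchor_col]) == 0  # 5' flank clean
        body = row[mg.anchor_col : mg.anchor_col + 80]
        assert np.nansum(body) > 0

    def test_trailer_reads_visible_beyond_mature_end(self):
        g, feats = self._trnas()
        alns = [_read(160, [(35, "M")])]  # runs 15 nt past T1's 3' end
        mg = trna_profile(alns, feats, g, flank=20, total_mapped=1)
        row = mg.matrix.loc["T1"].to_numpy(dtype=float)
        three_prime_flank = row[mg.anchor_col + 80 :]
        assert np.nansum(three_prime_flank) > 0


class TestBedgraph:
    def test_constant_track_single_line(self, tmp_path):
        track = pileup([_read(0, [(10, "M")])], "c", 0, 10)
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["c\t0\t10\t1e+06"]

    def test_empty_track_header_only(self, tmp_path):
        track = pileup([], "c", 0, 10, total_mapped=1)
        p = tmp_path / "e.bedgraph"
        write_bedgraph(track, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_round_trip(self, tmp_path):
        alns = [_read(2, [(5, "M")]), _read(4, [(6, "M")], rid="r2")]
        track = pileup(alns, "c", 0, 20, total_mapped=2)
        p = tmp_path / "r.bedgraph"
        write_bedgraph(track, p)
        recovered = np.zeros(20)
        for chrom, s, e, v in read_bedgraph(p):
            recovered[s:e] = v
        assert np.allclose(recovered, track.values)
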