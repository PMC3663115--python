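"""Simulation harness: reference generation, spiking, read simulation,
downsampling and truth-based scoring."""

import random

import pytest

from retrocall.formats import CallTableRow, Genome, LibraryStats, revcomp
from retrocall.simulate import (ReadMapper, SpikeSpec, TruthRecord,
                                build_insert, downsample, downsample_bam,
                                evaluate_calls, make_reference,
                                sample_spikes, simulate_reads,
                                spike_retrocopy, spliced_transcript,
                                to_sorted_bam, write_pairs_sam)

SIZES = {"chr1": 60_000, "chr2": 60_000}


class TestMakeReference:
    def test_reproducible_from_seed(self):
        g1, genes1 = make_reference(3, SIZES, 6)
        g2, genes2 = make_reference(3, SIZES, 6)
        assert g1.sequence("chr1") == g2.sequence("chr1")
        assert genes1 == genes2

    def test_seed_sensitivity(self):
        g1, _ = make_reference(3, SIZES, 6)
        g2, _ = make_reference(4, SIZES, 6)
        assert g1.sequence("chr1") != g2.sequence("chr1")

    def test_zero_genes(self):
        genome, genes = make_reference(3, {"chr1": 10_000}, 0)
        assert genes == [] and genome.chrom_sizes == {"chr1": 10_000}

    def test_single_exon_gene_planted(self):
        _, genes = make_reference(3, SIZES, 6)
        assert any(g.n_exons == 1 for g in genes)
        assert sum(g.n_exons >= 2 for g in genes) == 5

    def test_genes_within_bounds_and_disjoint(self):
        genome, genes = make_reference(5, SIZES, 8)
        by_chrom = {}
        for g in genes:
            assert 0 <= g.start < g.end <= genome.chrom_sizes[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError):
            make_reference(3, {"chr1": 5_000}, 40)


class TestSplicedTranscript:
    def test_single_exon_verbatim(self):
        genome, genes = make_reference(3, SIZES, 6)
        single = [g for g in genes if g.n_exons == 1][0]
        s, e = single.exons[0]
        tx = spliced_transcript(single, genome)
        raw = genome.fetch(single.chrom, s, e)
        assert tx == (raw if single.strand == "+" else revcomp(raw))

    def test_concatenation_length(self):
        genome, genes = make_reference(3, SIZES, 6)
        g = [g for g in genes if g.n_exons >= 3][0]
        tx = spliced_transcript(g, genome)
        assert len(tx) == sum(e - s for s, e in g.exons)

    def test_minus_strand_is_reverse_complement(self):
        genome, genes = make_reference(3, SIZES, 6)
        minus = [g for g in genes if g.strand == "-"]
        assert minus  # seed chosen arbitrarily; generator flips coins
        g = minus[0]
        fwd = "".join(genome.fetch(g.chrom, s, e) for s, e in g.exons)
        assert spliced_transcript(g, genome) == revcomp(fwd)


class TestSpike:
    @pytest.fixture
    def world(self):
        genome, genes = make_reference(9, SIZES, 6)
        gene = [g for g in genes if g.n_exons >= 3][0]
        return genome, gene

    def test_tsd_duplicated_on_both_flanks(self, world):
        genome, gene = world
        pos = 40_000 if gene.chrom == "chr2" else 40_000
        spec = SpikeSpec(gene_id=gene.gene_id, chrom="chr2", position=pos,
                         strand="+", tsd_len=15, polyA_len=20)
        if gene.chrom == "chr2":
            spec = SpikeSpec(gene_id=gene.gene_id, chrom="chr1",
                             position=pos, strand="+", tsd_len=15,
                             polyA_len=20)
        allele, truth = spike_retrocopy(genome, gene, spec)
        ref = genome.sequence(spec.chrom)
        tract = ref[pos:pos + 15]
        ins = build_insert(spec, spliced_transcript(gene, genome))
        # left flank ends with the tract, then the insert, then the
        # tract again at the start of the right flank
        left = allele[pos:pos + 15]
        right = allele[pos + 15 + len(ins):pos + 30 + len(ins)]
        assert left == tract and right == tract
        assert allele[pos + 15:pos + 15 + len(ins)] == ins
        assert len(allele) == len(ref) + 15 + len(ins)
        assert truth.insert_length == len(ins)

    def test_blunt_insertion(self, world):
        genome, gene = world
        chrom = "chr1" if gene.chrom == "chr2" else "chr2"
        spec = SpikeSpec(gene_id=gene.gene_id, chrom=chrom, position=30_000,
                         strand="+", tsd_len=0, polyA_len=10)
        allele, _ = spike_retrocopy(genome, gene, spec)
        ins = build_insert(spec, spliced_transcript(gene, genome))
        assert allele[30_000:30_000 + len(ins)] == ins

    def test_full_truncation_rejected(self, world):
        genome, gene = world
        tx = spliced_transcript(gene, genome)
        spec = SpikeSpec(gene_id=gene.gene_id, chrom="chr1",
                         position=30_000, strand="+",
                         five_prime_truncation=len(tx))
        with pytest.raises(ValueError, match="truncation"):
            build_insert(spec, tx)

    def test_position_inside_source_gene_rejected(self, world):
        genome, gene = world
        spec = SpikeSpec(gene_id=gene.gene_id, chrom=gene.chrom,
                         position=gene.start + 5, strand="+")
        with pytest.raises(ValueError, match="source gene"):
            spike_retrocopy(genome, gene, spec)

    def test_expected_junctions_respect_truncation(self, world):
        genome, gene = world
        chrom = "chr1" if gene.chrom == "chr2" else "chr2"
        lens = [e - s for s, e in gene.exons]
        if gene.strand == "-":
            lens = lens[::-1]
        # truncate past the first exon: junction (1,2) must disappear
        spec = SpikeSpec(gene_id=gene.gene_id, chrom=chrom, position=30_000,
                         strand="+", five_prime_truncation=lens[0])
        _, truth = spike_retrocopy(genome, gene, spec)
        assert (1, 2) not in truth.expected_junctions
        assert (2, 3) in truth.expected_junctions

    def test_sampled_sites_respect_constraints(self):
        genome, genes = make_reference(9, SIZES, 8)
        specs = sample_spikes(2, genes, genome, n_multi=6, n_single=1)
        gene_by = {g.gene_id: g for g in genes}
        for s in specs:
            g = gene_by[s.gene_id]
            if g.chrom == s.chrom:
                assert (s.position < g.start - 10_000
                        or s.position > g.end + 10_000)
        single = [s for s in specs if gene_by[s.gene_id].n_exons == 1]
        assert len(single) == 1


@pytest.fixture(scope="module")
def small_world():
    genome, _genes = make_reference(13, {"chr1": 30_000}, 2)
    stats = LibraryStats(100, 500, 30)
    alleles = {"chr1": genome.sequence("chr1")}
    return genome, alleles, stats


class TestReadSimulation:

    def test_pair_count_tracks_coverage(self, small_world):
        genome, alleles, stats = small_world
        pairs = simulate_reads(alleles, genome, 20, stats, seed=3)
        expected = 20 * 30_000 / 200
        assert abs(len(pairs) - expected) < 0.05 * expected

    def test_deterministic_per_seed(self, small_world):
        genome, alleles, stats = small_world
        a = simulate_reads(alleles, genome, 5, stats, seed=9)
        b = simulate_reads(alleles, genome, 5, stats, seed=9)
        assert a == b
        c = simulate_reads(alleles, genome, 5, stats, seed=10)
        assert a != c

    def test_tiny_coverage_no_crash(self, small_world):
        genome, _, stats = small_world
        pairs = simulate_reads({"chr1": genome.sequence("chr1")[:1000]},
                               genome, 0.001, stats, seed=3)
        assert pairs == []

    def test_clean_reads_map_back_exactly(self, small_world):
        genome, alleles, stats = small_world
        pairs = simulate_reads(alleles, genome, 2, stats, error_rate=0.0,
                               seed=4)
        ref = genome.sequence("chr1")
        for rec in pairs[:200]:
            for e in rec.mapped_ends:
                assert not e.soft_clipped
                assert ref[e.start:e.end] == e.seq

    def test_mapper_clips_at_novel_junction(self, small_world):
        genome, _, stats = small_world
        ref = genome.sequence("chr1")
        mapper = ReadMapper(genome)
        # novel tail engineered to mismatch the reference at every
        # position past the junction
        novel = "".join("C" if ref[10_060 + i] != "C" else "G"
                        for i in range(40))
        read = ref[10_000:10_060] + novel
        a = mapper.map(read)
        assert a is not None
        assert (a.start, a.end) == (10_000, 10_060)
        assert a.clip_right == 40 and a.clip_left == 0


class TestDownsample:
    def _pairs(self, n=2000):
        genome, _ = make_reference(13, {"chr1": 20_000}, 0)
        stats = LibraryStats(100, 500, 30)
        return simulate_reads({"chr1": genome.sequence("chr1")}, genome,
                              n * 200 / 20_000, stats, seed=6)

    def test_fraction_one_identity(self):
        pairs = self._pairs(500)
        assert downsample(pairs, 1.0, seed=1) == pairs

    def test_binomial_fraction(self):
        pairs = self._pairs(2000)
        kept = downsample(pairs, 0.5, seed=2)
        n, p = len(pairs), 0.5
        sd = (n * p * (1 - p)) ** 0.5
        assert abs(len(kept) - n * p) < 5 * sd

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            downsample([], 0.0)
        with pytest.raises(ValueError):
            downsample([], 1.5)

    def test_bam_downsampling_never_orphans_mates(self, tmp_path):
        genome, _ = make_reference(13, {"chr1": 20_000}, 0)
        stats = LibraryStats(100, 500, 30)
        pairs = simulate_reads({"chr1": genome.sequence("chr1")}, genome,
                               10, stats, seed=6)
        sam = str(tmp_path / "a.sam")
        write_pairs_sam(pairs, genome, sam)
        out = str(tmp_path / "b.sam")
        downsample_bam(sam, out, 0.5, seed=3)
        import pysam
        counts = {}
        with pysam.AlignmentFile(out, "r", check_sq=False) as fh:
            for aln in fh:
                counts[aln.query_name] = counts.get(aln.query_name, 0) + 1
        assert counts and all(v == 2 for v in counts.values())


class TestEvaluate:
    def _truth(self, gene, chrom, pos):
        spec = SpikeSpec(gene_id=gene, chrom=chrom, position=pos,
                         strand="+", tsd_len=10, polyA_len=10)
        return TruthRecord(spec=spec, insert_length=500,
                           allele_position=pos, expected_junctions=())

    def _call(self, gene, chrom, pos):
        return CallTableRow(chrom=chrom, start=pos, end=pos + 10,
                            gene_id=gene, n_left=5, n_right=5,
                            exons_hit=(1, 2), samples=("s",))

    def test_counts_and_rates(self):
        truths = [self._truth(f"G{i}", "chr1", 1000 * i)
                  for i in range(1, 11)]
        calls = [self._call(f"G{i}", "chr1", 1000 * i)
                 for i in range(1, 9)]
        rep = evaluate_calls(calls, truths)
        assert (rep.tp, rep.fp, rep.fn) == (8, 0, 2)
        assert rep.precision == 1.0 and rep.recall == 0.8
        row = rep.per_gene.set_index("gene_id").loc["G9"]
        assert row["recall"] == 0.0

    def test_no_calls(self):
        truths = [self._truth("G1", "chr1", 1000)]
        rep = evaluate_calls([], truths)
        assert rep.precision is None and rep.recall == 0.0

    def test_slop_boundary(self):
        truths = [self._truth("G1", "chr1", 1000)]
        near = evaluate_calls([self._call("G1", "chr1", 1090)], truths,
                              match_slop=100)
        assert (near.tp, near.fp, near.fn) == (1, 0, 0)
        far = evaluate_calls([self._call("G1", "chr1", 1150)], truths,
                             match_slop=100)
        assert (far.tp, far.fp, far.fn) == (0, 1, 1)

    def test_one_call_matches_at_most_one_truth(self):
        truths = [self._truth("G1", "chr1", 1000),
                  self._truth("G1", "chr1", 1050)]
        rep = evaluate_calls([self._call("G1", "chr1", 1000)], truths)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 1)

    def test_gene_identity_required(self):
        truths = [self._truth("G1", "chr1", 1000)]
        rep = evaluate_calls([self._call("G2", "chr1", 1000)], truths)
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)
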