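"""Shared fixtures: a session-scoped spike-in benchmark plus small
hand-built read/gene factories."""

from __future__ import annotations

import pytest

from retrocall.detect import DiscordantPair, discover_from_pairs
from retrocall.formats import GeneModel, Genome, LibraryStats, ReadEnd, ReadPairRecord
from retrocall.simulate import build_benchmark

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench():
    """The standard 60x spike-in benchmark (built once per session)."""
    return build_benchmark(BENCH_SEED)


@pytest.fixture(scope="session")
def bench_calls(bench):
    """Fully annotated discovery output on the benchmark reads."""
    return discover_from_pairs({"sim": bench.pairs}, bench.genes,
                               bench.genome, bench.stats)


@pytest.fixture(scope="session")
def bench_matched(bench, bench_calls):
    """(call, truth) pairs matched by source gene and proximity."""
    out = []
    for c in bench_calls:
        cand = [t for t in bench.truths
                if t.spec.gene_id == c.row.gene_id
                and t.spec.chrom == c.row.chrom
                and abs(t.spec.position - c.row.start) < 200]
        if cand:
            out.append((c, cand[0]))
    return out


@pytest.fixture
def stats():
    return LibraryStats(read_length=100, median_insert=500, insert_sd=30)


def make_end(chrom="chrA", start=0, length=100, strand="+", mapq=60,
             seq=None, clip_left=0, clip_right=0):
    aligned = length - clip_left - clip_right
    cigar = ""
    if clip_left:
        cigar += f"{clip_left}S"
    cigar += f"{aligned}M"
    if clip_right:
        cigar += f"{clip_right}S"
    return ReadEnd(chrom=chrom, start=start, end=start + aligned,
                   strand=strand, mapq=mapq, cigar=cigar,
                   seq=seq if seq is not None else "G" * length,
                   clip_left=clip_left, clip_right=clip_right)


def make_pair(name, end1, end2, sample="s1"):
    return ReadPairRecord(query_name=name, sample_id=sample,
                          end1=end1, end2=end2)


def make_discordant(gene_id, exon_index, distal_start, distal_strand,
                    chrom="chrB", sample="s1", name=None, mapq=60):
    exonic = make_end(chrom="chrA", start=1500, strand="+", mapq=mapq)
    distal = make_end(chrom=chrom, start=distal_start,
                      strand=distal_strand, mapq=mapq)
    return DiscordantPair(sample_id=sample, gene_id=gene_id,
                          exon_index=exon_index, exonic=exonic,
                          distal=distal,
                          query_name=name or f"q{distal_start}{distal_strand}")


@pytest.fixture
def toy_gene():
    return GeneModel(gene_id="G1", chrom="chrA", strand="+",
                     exons=((1000, 1200), (1500, 1700), (2000, 2200)))


@pytest.fixture
def toy_genome_factory():
    """Deterministic random genome builder for hand fixtures."""
    import random

    def build(sizes: dict[str, int], seed: int = 11) -> Genome:
        rng = random.Random(seed)
        return Genome({c: "".join(rng.choice("ACGT") for _ in range(n))
                       for c, n in sizes.items()})

    return build
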