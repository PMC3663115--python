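"""Spike-in simulation harness: synthetic genomes, retrocopy insertions,
FR paired reads, downsampling, and truth-based scoring.

The generator emulates the data the caller is designed for: a small
multi-chromosome genome carrying multi- and single-exon genes; spiked
insertions of spliced, polyadenylated transcripts with target site
duplications and optional 5' truncation; and 100 bp forward-reverse read
pairs around a 300 bp unsequenced insert (500 bp outer fragment) at a
configurable depth.  Spiking operates at the sequence level — the
modified allele is built as ``ref[:pos+tsd] + insert + ref[pos:]`` so the
duplicated tract flanks the insert on both sides — and reads are then
mapped back to the *unmodified* reference with an internal seed-and-
extend mapper, which produces the discordant pairs and base-precise
soft clips the caller consumes.

So that truth values are exact (and parameter-recovery checks are
meaningful), the generator avoids junction micro-homology: insertion
sites are resampled until the first and last inserted bases differ from
the adjoining reference bases, and generated transcripts end in two
non-A bases.  Real data does not offer this guarantee; see the methods
note for what that means for interpreting passing tests.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np
import pysam

import pandas as pd

from .formats import (GeneModel, Genome, LibraryStats, ReadEnd,
                      ReadPairRecord, revcomp)

log = logging.getLogger("retrocall")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_STATS = LibraryStats(read_length=100, median_insert=500, insert_sd=30)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def make_reference(seed: int, chrom_sizes: dict[str, int], n_genes: int,
                   exon_count_range: tuple[int, int] = (2, 6),
                   exon_len_range: tuple[int, int] = (80, 250),
                   intron_len_range: tuple[int, int] = (200, 800),
                   gene_gap_range: tuple[int, int] = (1500, 4000),
                   ) -> tuple[Genome, list[GeneModel]]:
    """Build a reproducible random genome plus non-overlapping gene models.

    Genes are laid out round-robin across chromosomes with random
    spacing.  When ``n_genes`` >= 5 the last gene is forced to a single
    exon so the caller's known blind spot is always represented.
    Generated transcripts end in two non-A bases (see module docstring).
    Raises if the requested genes cannot be placed.
    """
    rng = np.random.default_rng(seed)
    arrays = {c: _BASES[rng.integers(0, 4, size)].copy()
              for c, size in chrom_sizes.items()}
    chroms = list(chrom_sizes)
    cursors = {c: 1000 for c in chroms}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        chrom = chroms[gi % len(chroms)]
        if n_genes >= 5 and gi == n_genes - 1:
            n_ex = 1
        else:
            n_ex = int(rng.integers(exon_count_range[0],
                                    exon_count_range[1] + 1))
        start = cursors[chrom] + int(rng.integers(*gene_gap_range))
        exons = []
        pos = start
        for e in range(n_ex):
            elen = int(rng.integers(*exon_len_range))
            exons.append((pos, pos + elen))
            pos += elen
            if e < n_ex - 1:
                pos += int(rng.integers(*intron_len_range))
        if pos > chrom_sizes[chrom] - 1000:
            raise ValueError(
                f"cannot place gene {gi} on {chrom}: genome too small")
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene = GeneModel(gene_id=f"GENE{gi:03d}", chrom=chrom, strand=strand,
                         exons=tuple(exons))
        _patch_transcript_tail(arrays[chrom], gene)
        genes.append(gene)
        cursors[chrom] = pos
    genome = Genome({c: a.tobytes().decode() for c, a in arrays.items()})
    return genome, genes


def _patch_transcript_tail(arr: np.ndarray, gene: GeneModel) -> None:
    # force the transcript's last two bases non-A so a simulated poly-A
    # tail never blends into transcript sequence
    if gene.strand == "+":
        e = gene.exons[-1][1]
        for p in (e - 2, e - 1):
            if arr[p] == b"A":
                arr[p] = b"C"
    else:
        s = gene.exons[0][0]
        for p in (s, s + 1):
            if arr[p] == b"T":  # complements to A in the transcript
                arr[p] = b"G"


def spliced_transcript(gene: GeneModel, genome: Genome) -> str:
    """Exon sequences joined in transcription order (introns removed)."""
    seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeSpec:
    """One simulated retrocopy insertion."""

    gene_id: str
    chrom: str
    position: int                 # reference coordinate of the target site
    strand: str                   # orientation of the inserted copy
    tsd_len: int = 0
    polyA_len: int = 20
    five_prime_truncation: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tsd_len < 0 or self.polyA_len < 0:
            raise ValueError("tsd_len and polyA_len must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """A spike plus its realized coordinates and expected junctions."""

    spec: SpikeSpec
    insert_length: int
    allele_position: int          # insert start in the modified allele
    expected_junctions: tuple[tuple[int, int], ...]


def build_insert(spec: SpikeSpec, transcript: str) -> str:
    core = transcript[spec.five_prime_truncation:]
    if not core:
        raise ValueError("truncation removes the entire transcript")
    ins = core + "A" * spec.polyA_len
    return revcomp(ins) if spec.strand == "-" else ins


def _expected_junctions(gene: GeneModel, genome: Genome, trunc: int,
                        min_flank: int = 20) -> tuple[tuple[int, int], ...]:
    lens = [e - s for s, e in gene.exons]
    if gene.strand == "-":
        lens = lens[::-1]
    out = []
    cum = 0
    for i, ln in enumerate(lens[:-1]):
        cum += ln
        if cum - trunc >= min_flank:
            out.append((i + 1, i + 2))
    return tuple(out)


def spike_retrocopy(genome: Genome, gene: GeneModel,
                    spec: SpikeSpec) -> tuple[str, TruthRecord]:
    """Insert one retrocopy into its chromosome's sequence.

    The returned allele is ``ref[:pos+tsd] + insert + ref[pos:]``: the
    ``tsd_len`` reference bases at the site end up flanking the insert
    on both sides (an exact target site duplication).
    """
    ref = genome.sequence(spec.chrom)
    pos, t = spec.position, spec.tsd_len
    if not 0 <= pos <= len(ref) - t:
        raise ValueError(f"spike position {pos} out of bounds")
    if gene.chrom == spec.chrom and gene.start <= pos < gene.end:
        raise ValueError("spike position inside the source gene span")
    ins = build_insert(spec, spliced_transcript(gene, genome))
    allele = ref[:pos + t] + ins + ref[pos:]
    truth = TruthRecord(
        spec=spec, insert_length=len(ins), allele_position=pos + t,
        expected_junctions=_expected_junctions(
            gene, genome, spec.five_prime_truncation))
    return allele, truth


def apply_spikes(genome: Genome, genes: list[GeneModel],
                 specs: list[SpikeSpec]
                 ) -> tuple[dict[str, str], list[TruthRecord]]:
    """Apply many spikes; returns modified alleles for every chromosome.

    Spikes on one chromosome are applied right-to-left so reference
    coordinates stay valid throughout.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    alleles = {c: genome.sequence(c) for c in genome.chroms()}
    truths: list[TruthRecord] = []
    by_chrom: dict[str, list[SpikeSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_specs in by_chrom.items():
        seq = alleles[chrom]
        for spec in sorted(chrom_specs, key=lambda s: -s.position):
            gene = gene_by_id[spec.gene_id]
            ins = build_insert(spec, spliced_transcript(gene, genome))
            pos, t = spec.position, spec.tsd_len
            seq = seq[:pos + t] + ins + seq[pos:]
            truths.append(TruthRecord(
                spec=spec, insert_length=len(ins), allele_position=pos + t,
                expected_junctions=_expected_junctions(
                    gene, genome, spec.five_prime_truncation)))
        alleles[chrom] = seq
    truths.sort(key=lambda t: (t.spec.chrom, t.spec.position))
    return alleles, truths


def sample_spikes(seed: int, genes: list[GeneModel], genome: Genome,
                  n_multi: int, n_single: int = 0, n_tsd_zero: int = 0,
                  tsd_range: tuple[int, int] = (5, 25),
                  polyA_range: tuple[int, int] = (10, 30),
                  truncation_prob: float = 0.4,
                  min_insert_len: int = 250,
                  min_site_gap: int = 2500,
                  source_gene_clearance: int = 10_500,
                  edge_clearance: int = 1000) -> list[SpikeSpec]:
    """Draw a reproducible set of spike specifications.

    Sites are uniform over the genome subject to: clearance from the
    source gene span (so the distal-mate rule can fire), mutual spacing
    (so clusters never merge), distance from chromosome ends, and no
    junction micro-homology with the insert (see module docstring).
    """
    rng = random.Random(seed)
    sizes = genome.chrom_sizes
    multi = [g for g in genes if g.n_exons >= 2
             and len(spliced_transcript(g, genome)) >= min_insert_len + 50]
    single = [g for g in genes if g.n_exons == 1]
    if n_multi > 0 and not multi:
        raise ValueError("no multi-exon genes long enough to spike")
    if n_single > 0 and not single:
        raise ValueError("no single-exon genes available to spike")
    taken: list[tuple[str, int]] = []
    specs: list[SpikeSpec] = []

    def place(gene: GeneModel, tsd: int, polya: int, trunc: int) -> SpikeSpec:
        tx = spliced_transcript(gene, genome)
        for _ in range(2000):
            chrom = rng.choice(list(sizes))
            pos = rng.randrange(edge_clearance, sizes[chrom] - edge_clearance)
            if (chrom == gene.chrom
                    and gene.start - source_gene_clearance < pos
                    < gene.end + source_gene_clearance):
                continue
            if any(c == chrom and abs(p - pos) < min_site_gap
                   for c, p in taken):
                continue
            strand = rng.choice("+-")
            spec = SpikeSpec(gene_id=gene.gene_id, chrom=chrom, position=pos,
                             strand=strand, tsd_len=tsd, polyA_len=polya,
                             five_prime_truncation=trunc)
            ins = build_insert(spec, tx)
            ref = genome.sequence(chrom)
            # junction micro-homology makes the true breakpoint ambiguous:
            # reject sites where the insert ends match the adjoining
            # reference base, or where the following 4-mer matches (which
            # would let an aligner absorb the junction mismatch as a
            # sequencing error — poly-A tails beside reference A-runs)
            if ins[0] == ref[pos + tsd] or ins[-1] == ref[pos - 1]:
                continue
            if (ins[1:5] == ref[pos + tsd + 1:pos + tsd + 5]
                    or ins[-5:-1] == ref[pos - 5:pos - 1]):
                continue
            taken.append((chrom, pos))
            return spec
        raise ValueError("could not place spike; genome too crowded")

    for i in range(n_multi):
        gene = multi[i % len(multi)]
        tx_len = len(spliced_transcript(gene, genome))
        tsd = 0 if i < n_tsd_zero else rng.randint(*tsd_range)
        polya = rng.randint(*polyA_range)
        trunc = 0
        if rng.random() < truncation_prob and tx_len > min_insert_len + 40:
            trunc = rng.randint(1, min(tx_len // 2, tx_len - min_insert_len))
        specs.append(place(gene, tsd, polya, trunc))
    for i in range(n_single):
        gene = single[i % len(single)]
        specs.append(place(gene, rng.randint(*tsd_range),
                           rng.randint(*polyA_range), 0))
    return specs


# ---------------------------------------------------------------------------
# internal read mapper
# ---------------------------------------------------------------------------

@dataclass
class _Alignment:
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    clip_left: int
    clip_right: int
    seq: str     # reference-forward orientation
    score: int


class ReadMapper:
    """Seed-and-extend read mapper against a small reference.

    Indexes every reference position at ``seed_len``; a read is anchored
    by exact seed hits at three offsets (both strands), scored by total
    matches on the candidate diagonal, and trimmed to its well-aligned
    segment: extension beyond the longest exact run absorbs an isolated
    mismatch only when the following four bases match, so alignments
    stop base-precisely at insertion junctions and the remainder is
    soft-clipped.  MAPQ is 60 for a unique best diagonal, 0 for ties.
    """

    def __init__(self, genome: Genome, seed_len: int = 20,
                 max_seed_hits: int = 20):
        self.k = seed_len
        self.max_seed_hits = max_seed_hits
        self._seqs = {c: genome.sequence(c) for c in genome.chroms()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self._seqs.items():
            k = self.k
            idx = self._index
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i:i + k], []).append((chrom, i))

    def map(self, read: str) -> _Alignment | None:
        k, L = self.k, len(read)
        if L < k:
            return None
        cands: set[tuple[str, str, int]] = set()
        oriented = {"+": read, "-": revcomp(read)}
        for strand, s in oriented.items():
            for off in (0, (L - k) // 2, L - k):
                hits = self._index.get(s[off:off + k])
                if not hits or len(hits) > self.max_seed_hits:
                    continue
                for chrom, pos in hits:
                    cands.add((strand, chrom, pos - off))
        if not cands:
            return None
        scored = []
        for strand, chrom, start0 in cands:
            ref = self._seqs[chrom]
            lo, hi = max(0, start0), min(len(ref), start0 + L)
            if hi - lo < k:
                continue
            s = oriented[strand]
            seg, sub = s[lo - start0:hi - start0], ref[lo:hi]
            if seg == sub:
                score = hi - lo
            else:
                score = sum(a == b for a, b in zip(seg, sub))
            scored.append((score, chrom, start0, strand))
        if not scored:
            return None
        scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        score, chrom, start0, strand = scored[0]
        mapq = 60
        if len(scored) > 1 and scored[1][0] == score:
            mapq = 0
        s = oriented[strand]
        ref = self._seqs[chrom]
        matched = [0 <= start0 + i < len(ref) and s[i] == ref[start0 + i]
                   for i in range(L)]
        a, b = _well_aligned_segment(matched)
        if b - a < k:
            return None
        return _Alignment(chrom=chrom, start=start0 + a, end=start0 + b,
                          strand=strand, mapq=mapq, clip_left=a,
                          clip_right=L - b, seq=s, score=score)


def _well_aligned_segment(matched: list[bool]) -> tuple[int, int]:
    """[a, b) bounds of the aligned block given per-base match flags.

    Starts from the longest exact run; a flanking mismatch is absorbed
    only when the next four bases outward all match (a sequencing error,
    not a junction).
    """
    L = len(matched)
    best_len = best_start = 0
    run = start = 0
    for i, m in enumerate(matched):
        if m:
            if run == 0:
                start = i
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            run = 0
    if best_len == 0:
        return 0, 0
    a, b = best_start, best_start + best_len
    i = b
    while i < L:
        if matched[i]:
            b = i + 1
            i += 1
        elif i + 4 < L and all(matched[i + 1:i + 5]):
            b = i + 1
            i += 1
        else:
            break
    i = a - 1
    while i >= 0:
        if matched[i]:
            a = i
            i -= 1
        elif i - 4 >= 0 and all(matched[i - 4:i]):
            a = i
            i -= 1
        else:
            break
    return a, b


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(alleles: dict[str, str], reference: Genome,
                   coverage: float, stats: LibraryStats = DEFAULT_STATS,
                   error_rate: float = 0.001, seed: int = 0,
                   sample_id: str = "sim",
                   mapper: ReadMapper | None = None
                   ) -> list[ReadPairRecord]:
    """Sample FR read pairs from alleles and map them to the reference.

    Fragments are uniform over each allele with outer span ~
    Normal(median_insert, insert_sd); substitution errors at
    ``error_rate`` per base; deterministic for a given seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    if mapper is None:
        mapper = ReadMapper(reference)
    rl = stats.read_length
    pairs: list[ReadPairRecord] = []
    n_unmapped_pairs = 0
    for chrom in sorted(alleles):
        seq = alleles[chrom]
        n_frag = int(round(coverage * len(seq) / (2 * rl)))
        if n_frag == 0:
            continue
        frags = np.clip(np.rint(rng.normal(stats.median_insert,
                                           stats.insert_sd, n_frag)),
                        2 * rl + 2, max(2 * rl + 2, len(seq) - 1)).astype(int)
        starts = rng.integers(0, len(seq) - frags + 1)
        n_err = rng.binomial(rl, error_rate, size=(n_frag, 2))
        for i in range(n_frag):
            s0, frag = int(starts[i]), int(frags[i])
            r1 = seq[s0:s0 + rl]
            r2 = revcomp(seq[s0 + frag - rl:s0 + frag])
            if n_err[i, 0]:
                r1 = _mutate(r1, int(n_err[i, 0]), rng)
            if n_err[i, 1]:
                r2 = _mutate(r2, int(n_err[i, 1]), rng)
            a1, a2 = mapper.map(r1), mapper.map(r2)
            if a1 is None and a2 is None:
                n_unmapped_pairs += 1
                continue
            pairs.append(ReadPairRecord(
                query_name=f"{chrom}_{i:07d}", sample_id=sample_id,
                end1=_to_read_end(a1), end2=_to_read_end(a2)))
    if n_unmapped_pairs:
        log.debug("simulate_reads: %d pairs had no mappable end",
                  n_unmapped_pairs)
    return pairs


def _mutate(read: str, n: int, rng) -> str:
    chars = list(read)
    for p in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        old = chars[p]
        choices = [b for b in "ACGT" if b != old]
        chars[p] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def _to_read_end(a: _Alignment | None) -> ReadEnd | None:
    if a is None:
        return None
    cigar = ""
    if a.clip_left:
        cigar += f"{a.clip_left}S"
    cigar += f"{a.end - a.start}M"
    if a.clip_right:
        cigar += f"{a.clip_right}S"
    return ReadEnd(chrom=a.chrom, start=a.start, end=a.end, strand=a.strand,
                   mapq=a.mapq, cigar=cigar, seq=a.seq,
                   clip_left=a.clip_left, clip_right=a.clip_right)


# ---------------------------------------------------------------------------
# SAM/BAM output and downsampling
# ---------------------------------------------------------------------------

def write_pairs_sam(pairs: list[ReadPairRecord], reference: Genome,
                    path: str) -> None:
    """Write simulated pairs as SAM (unmapped mates placed at their mate)."""
    sizes = reference.chrom_sizes
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": n} for c, n in sizes.items()]}
    tid = {c: i for i, c in enumerate(sizes)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in pairs:
            ends = (rec.end1, rec.end2)
            for which, end in enumerate(ends):
                mate = ends[1 - which]
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.query_name
                flag = 1 | (64 if which == 0 else 128)
                anchor = end if end is not None else mate
                if end is None:
                    flag |= 4
                elif end.strand == "-":
                    flag |= 16
                if mate is None:
                    flag |= 8
                elif mate.strand == "-":
                    flag |= 32
                a.flag = flag
                a.reference_id = tid[anchor.chrom]
                a.reference_start = anchor.start if end is None else end.start
                if end is not None:
                    a.mapping_quality = end.mapq
                    a.cigarstring = end.cigar
                    a.query_sequence = end.seq
                else:
                    a.mapping_quality = 0
                    a.query_sequence = ""
                m_anchor = mate if mate is not None else end
                a.next_reference_id = tid[m_anchor.chrom]
                a.next_reference_start = (mate.start if mate is not None
                                          else anchor.start)
                out.write(a)


def to_sorted_bam(sam_path: str, bam_path: str) -> None:
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)


def downsample(pairs: list[ReadPairRecord], fraction: float,
               seed: int = 0) -> list[ReadPairRecord]:
    """Keep each pair independently with probability ``fraction``.

    Pairs are kept or dropped atomically, so no mate is ever orphaned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return list(pairs)
    rng = random.Random(seed)
    return [p for p in pairs if rng.random() < fraction]


def downsample_bam(path: str, out_path: str, fraction: float,
                   seed: int = 0) -> None:
    """File-level downsampling: per-query-name atomic keep/drop."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = random.Random(seed)
    decisions: dict[str, bool] = {}
    mode_in = "rb" if path.endswith(".bam") else "r"
    mode_out = "wb" if out_path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(path, mode_in, check_sq=False) as fin, \
            pysam.AlignmentFile(out_path, mode_out, template=fin) as fout:
        for aln in fin:
            keep = decisions.get(aln.query_name)
            if keep is None:
                keep = rng.random() < fraction
                decisions[aln.query_name] = keep
            if keep:
                fout.write(aln)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    coverage: float | None
    tp: int
    fp: int
    fn: int
    per_gene: pd.DataFrame = field(repr=False, default=None)

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)


def evaluate_calls(calls, truths: list[TruthRecord], match_slop: int = 100,
                   coverage: float | None = None) -> EvalReport:
    """Score PASS calls against spike truth.

    A truth is matched by a call of the same source gene whose interval
    lies within ``match_slop`` of the spiked site; each call matches at
    most one truth (nearest-site assignment).
    """
    rows = [c.row if hasattr(c, "row") else c for c in calls]
    rows = [r for r in rows if r.filter_status == "PASS"]
    assignments: list[tuple[int, int, int]] = []  # (distance, call, truth)
    for ci, r in enumerate(rows):
        for ti, t in enumerate(truths):
            if t.spec.gene_id != r.gene_id or t.spec.chrom != r.chrom:
                continue
            d = max(r.start - t.spec.position, t.spec.position - r.end, 0)
            if d <= match_slop:
                assignments.append((d, ci, ti))
    assignments.sort()
    used_calls: set[int] = set()
    matched_truth: set[int] = set()
    for d, ci, ti in assignments:
        if ci in used_calls or ti in matched_truth:
            continue
        used_calls.add(ci)
        matched_truth.add(ti)
    tp = len(matched_truth)
    fp = len(rows) - len(used_calls)
    fn = len(truths) - tp
    per_gene_rows = []
    by_gene: dict[str, list[int]] = {}
    for ti, t in enumerate(truths):
        by_gene.setdefault(t.spec.gene_id, []).append(ti)
    for gene_id in sorted(by_gene):
        tis = by_gene[gene_id]
        got = sum(1 for ti in tis if ti in matched_truth)
        per_gene_rows.append({"gene_id": gene_id, "n_truth": len(tis),
                              "n_detected": got,
                              "recall": got / len(tis)})
    return EvalReport(coverage=coverage, tp=tp, fp=fp, fn=fn,
                      per_gene=pd.DataFrame(per_gene_rows))


# ---------------------------------------------------------------------------
# end-to-end benchmark bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    genome: Genome
    genes: list[GeneModel]
    specs: list[SpikeSpec]
    truths: list[TruthRecord]
    pairs: list[ReadPairRecord]
    stats: LibraryStats
    coverage: float

    @property
    def multi_exon_truths(self) -> list[TruthRecord]:
        by_id = {g.gene_id: g for g in self.genes}
        return [t for t in self.truths if by_id[t.spec.gene_id].n_exons >= 2]

    @property
    def single_exon_truths(self) -> list[TruthRecord]:
        by_id = {g.gene_id: g for g in self.genes}
        return [t for t in self.truths if by_id[t.spec.gene_id].n_exons == 1]


def build_benchmark(seed: int,
                    chrom_sizes: dict[str, int] | None = None,
                    n_genes: int = 24, n_multi_spikes: int = 54,
                    n_single_spikes: int = 3, n_tsd_zero: int = 2,
                    coverage: float = 60.0, error_rate: float = 0.001,
                    stats: LibraryStats = DEFAULT_STATS) -> SimBundle:
    """The standard spike-in benchmark: genome, spikes, 60x mapped reads.

    Defaults are the shipped study conditions: a 2 x 200 kb genome, 24
    genes (one single-exon), 54 multi-exon spikes (two TSD-less) plus 3
    single-exon-gene spikes, TSD ~ U[5,25], poly-A ~ U[10,30], 40% of
    spikes 5'-truncated, 100 bp FR reads around a 500 bp outer fragment.
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 200_000, "chr2": 200_000}
    genome, genes = make_reference(seed, chrom_sizes, n_genes)
    specs = sample_spikes(seed + 1, genes, genome, n_multi=n_multi_spikes,
                          n_single=n_single_spikes, n_tsd_zero=n_tsd_zero)
    alleles, truths = apply_spikes(genome, genes, specs)
    pairs = simulate_reads(alleles, genome, coverage, stats=stats,
                           error_rate=error_rate, seed=seed + 2)
    return SimBundle(genome=genome, genes=genes, specs=specs, truths=truths,
                     pairs=pairs, stats=stats, coverage=coverage)
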