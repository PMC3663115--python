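"""Discordant-pair GRIP discovery.

A gene retrocopy insertion leaves a characteristic paired-end signature:
read pairs whose one end maps inside an exon of the source gene and
whose other end maps at a distant, mutually consistent locus.  At that
locus the forward-strand distal mates pile up on the 5' side of the
insertion point and the reverse-strand mates on the 3' side (FR
chemistry), so a genuine insertion shows two strand-coherent groups
facing each other.

A candidate becomes a call only if, after deduplicating identical
mappings, it has at least ``min_support`` distinct pairs with at least
``min_per_side`` spanning each junction, drawn from at least
``min_exons`` distinct exons, with the left group entirely on the ``+``
strand upstream of the ``-`` strand right group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from . import breakpoints as _breakpoints
from . import junctions as _junctions
from .formats import (CallTableRow, GeneModel, Genome, LibraryStats,
                      ReadEnd, ReadPairRecord, SampleInfo, iterate_read_pairs)
from .homology import screen_site

log = logging.getLogger("retrocall")


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the caller (defaults are the shipped ones)."""

    min_support: int = 8          # distinct discordant mappings per call
    min_per_side: int = 2         # distinct mappings spanning each junction
    min_exons: int = 2            # distinct source exons hit
    window: int = 500             # single-linkage clustering gap, bp
    min_mapq: int = 20            # both ends
    distal_flank: int = 10_000    # mate must map outside gene span +- this
    max_side_overlap: int = 30    # left/right groups may overlap by a TSD
    min_exon_overlap: int = 20    # bp of exon overlap to count as exonic
    merge_slop: int = 500         # cross-sample locus identity tolerance


@dataclass(frozen=True)
class DiscordantPair:
    """One gene-anchored discordant pair: exonic end + distal end."""

    sample_id: str
    gene_id: str
    exon_index: int               # transcription-order index, 1-based
    exonic: ReadEnd
    distal: ReadEnd
    query_name: str


@dataclass
class CandidateCluster:
    chrom: str
    gene_id: str
    members: list[DiscordantPair]

    @property
    def left(self) -> list[DiscordantPair]:
        return [m for m in self.members if m.distal.strand == "+"]

    @property
    def right(self) -> list[DiscordantPair]:
        return [m for m in self.members if m.distal.strand == "-"]


@dataclass
class InsertionCall:
    row: CallTableRow
    per_sample_support: dict[str, int]
    members: list[DiscordantPair] = field(default_factory=list)

    @property
    def status(self) -> str:
        return self.row.filter_status


# ---------------------------------------------------------------------------
# pair classification and harvesting
# ---------------------------------------------------------------------------

def classify_pair(rec: ReadPairRecord, stats: LibraryStats) -> str:
    """'concordant', 'discordant', or 'one_end_anchored'."""
    if rec.mate_unmapped:
        return "one_end_anchored"
    a, b = rec.end1, rec.end2
    if a.chrom != b.chrom:
        return "discordant"
    left, right = (a, b) if a.start <= b.start else (b, a)
    if not (left.strand == "+" and right.strand == "-"):
        return "discordant"
    span = right.end - left.start
    if span > stats.max_concordant_span:
        return "discordant"
    return "concordant"


class ExonIndex:
    """Interval lookup from genomic position to (gene, exon tx-index)."""

    def __init__(self, genes: list[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._spans: dict[str, tuple[str, int, int]] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for rank, (s, e) in enumerate(g.exons):
                tree[s:e] = (g.gene_id, g.exon_tx_index(rank))
            self._spans[g.gene_id] = (g.chrom, g.start, g.end)

    def exon_hits(self, end: ReadEnd, min_overlap: int):
        """Best (gene_id, exon_index, overlap) per gene overlapping end."""
        tree = self._trees.get(end.chrom)
        if tree is None:
            return {}
        best: dict[str, tuple[int, int]] = {}
        for iv in tree.overlap(end.start, end.end):
            ov = min(end.end, iv.end) - max(end.start, iv.begin)
            if ov < min_overlap:
                continue
            gene_id, exon_index = iv.data
            if gene_id not in best or ov > best[gene_id][1]:
                best[gene_id] = (exon_index, ov)
        return {g: idx for g, (idx, _ov) in best.items()}

    def outside_span(self, gene_id: str, end: ReadEnd, flank: int) -> bool:
        chrom, s, e = self._spans[gene_id]
        if end.chrom != chrom:
            return True
        return end.end <= s - flank or end.start >= e + flank


def harvest_discordants(pairs, genes: list[GeneModel] | ExonIndex,
                        stats: LibraryStats,
                        params: DetectionParams = DetectionParams()
                        ) -> list[DiscordantPair]:
    """Extract gene-anchored discordant pairs from a pair stream.

    Keeps pairs that are discordant, have both ends at mapq >=
    ``min_mapq``, exactly one end overlapping an exon of the anchor gene
    by >= ``min_exon_overlap`` bp, and the other end mapping outside the
    gene span +- ``distal_flank`` (or another chromosome).
    """
    index = genes if isinstance(genes, ExonIndex) else ExonIndex(genes)
    out: list[DiscordantPair] = []
    n_seen = n_rejected = 0
    for rec in pairs:
        n_seen += 1
        if classify_pair(rec, stats) != "discordant":
            continue
        a, b = rec.end1, rec.end2
        if a.mapq < params.min_mapq or b.mapq < params.min_mapq:
            n_rejected += 1
            continue
        for exonic, distal in ((a, b), (b, a)):
            for gene_id, exon_index in index.exon_hits(
                    exonic, params.min_exon_overlap).items():
                if not index.outside_span(gene_id, distal,
                                          params.distal_flank):
                    continue
                out.append(DiscordantPair(
                    sample_id=rec.sample_id, gene_id=gene_id,
                    exon_index=exon_index, exonic=exonic, distal=distal,
                    query_name=rec.query_name))
    log.debug("harvest: %d pairs seen, %d mapq-rejected, %d anchored",
              n_seen, n_rejected, len(out))
    return out


def pool_samples(per_sample: dict[str, list[DiscordantPair]]
                 ) -> list[DiscordantPair]:
    """Merge per-sample discordant pairs, keeping sample tags.

    Pooling lets low-coverage genomes contribute jointly to one call;
    every sample contributing reads to a call is considered a carrier.
    """
    merged: list[DiscordantPair] = []
    for sample_id, pairs in per_sample.items():
        for p in pairs:
            if p.sample_id != sample_id:
                raise ValueError(
                    f"pair tagged {p.sample_id!r} listed under {sample_id!r}")
            merged.append(p)
    return merged


# ---------------------------------------------------------------------------
# clustering and calling
# ---------------------------------------------------------------------------

def cluster_candidates(pairs: list[DiscordantPair],
                       window: int = 500) -> list[CandidateCluster]:
    """Single-linkage clustering of distal mappings, per gene.

    Mappings sorted by (chrom, start) join one cluster while the gap to
    the growing cluster's right edge is <= ``window``.
    """
    by_gene: dict[str, list[DiscordantPair]] = {}
    for p in pairs:
        by_gene.setdefault(p.gene_id, []).append(p)
    clusters: list[CandidateCluster] = []
    for gene_id in sorted(by_gene):
        members = sorted(by_gene[gene_id],
                         key=lambda p: (p.distal.chrom, p.distal.start,
                                        p.distal.end, p.query_name))
        current: list[DiscordantPair] = []
        right_edge = None
        chrom = None
        for p in members:
            if (current and p.distal.chrom == chrom
                    and p.distal.start - right_edge <= window):
                current.append(p)
                right_edge = max(right_edge, p.distal.end)
            else:
                if current:
                    clusters.append(CandidateCluster(chrom, gene_id, current))
                current = [p]
                chrom = p.distal.chrom
                right_edge = p.distal.end
        if current:
            clusters.append(CandidateCluster(chrom, gene_id, current))
    return clusters


def call_insertion(cluster: CandidateCluster,
                   params: DetectionParams = DetectionParams()
                   ) -> tuple[InsertionCall | None, str | None]:
    """Apply support / per-side / exon-diversity / orientation rules.

    Distinct mappings are deduplicated by (distal start, distal strand)
    before counting, so PCR/optical duplicates count once.  Returns
    (call, None) on success or (None, reason) on failure.
    """
    distinct: dict[tuple[int, str], DiscordantPair] = {}
    for p in sorted(cluster.members,
                    key=lambda p: (p.distal.start, p.distal.strand,
                                   p.sample_id, p.query_name)):
        distinct.setdefault((p.distal.start, p.distal.strand), p)
    members = list(distinct.values())
    left = [p for p in members if p.distal.strand == "+"]
    right = [p for p in members if p.distal.strand == "-"]
    if len(members) < params.min_support:
        return None, "support_total"
    if len(left) < params.min_per_side or len(right) < params.min_per_side:
        return None, "support_side"
    exons_hit = sorted({p.exon_index for p in members})
    if len(exons_hit) < params.min_exons:
        return None, "exon_diversity"
    max_left_end = max(p.distal.end for p in left)
    min_right_start = min(p.distal.start for p in right)
    if max_left_end > min_right_start + params.max_side_overlap:
        return None, "orientation"
    start, end = sorted((max_left_end, min_right_start))
    # every genome contributing reads (even duplicate-position ones) is a
    # carrier; support counts stay deduplicated
    samples = sorted({p.sample_id for p in cluster.members})
    support: dict[str, int] = {}
    for p in members:
        support[p.sample_id] = support.get(p.sample_id, 0) + 1
    row = CallTableRow(
        chrom=cluster.chrom, start=start, end=end, gene_id=cluster.gene_id,
        n_left=len(left), n_right=len(right), exons_hit=tuple(exons_hit),
        samples=tuple(samples))
    return InsertionCall(row=row, per_sample_support=support,
                         members=members), None


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def discover_from_pairs(per_sample_pairs: dict[str, list[ReadPairRecord]],
                        genes: list[GeneModel], genome: Genome | None,
                        stats: LibraryStats,
                        params: DetectionParams = DetectionParams(),
                        pseudogene_annotations=None,
                        annotate: bool = True) -> list[InsertionCall]:
    """Full pipeline over in-memory read pairs.

    harvest -> pool -> cluster -> call -> pseudogene screen ->
    breakpoint/TSD/poly-A and junction annotation.  Output order is
    deterministic: (chrom, start, gene_id).
    """
    index = ExonIndex(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    per_sample_disc = {
        sid: harvest_discordants(pairs, index, stats, params)
        for sid, pairs in per_sample_pairs.items()}
    pooled = pool_samples(per_sample_disc)
    clusters = cluster_candidates(pooled, params.window)
    log.info("discover: %d discordant pairs, %d candidate clusters",
             len(pooled), len(clusters))
    calls: list[InsertionCall] = []
    reasons: dict[str, int] = {}
    for c in clusters:
        call, reason = call_insertion(c, params)
        if call is None:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        calls.append(call)
    if reasons:
        log.info("discover: rejected clusters by reason: %s", reasons)
    if genome is not None:
        from .simulate import spliced_transcript
        for call in calls:
            gene = gene_by_id[call.row.gene_id]
            status = screen_site(
                call.row.chrom, call.row.start, call.row.end, gene, genome,
                pseudogene_annotations, spliced_transcript(gene, genome))
            if status != "pass":
                call.row.filter_status = f"FILTERED_pseudogene:{status}"
    if annotate and genome is not None:
        all_pairs = [p for pairs in per_sample_pairs.values() for p in pairs]
        pair_index = _PairLocusIndex(all_pairs)
        exon_edges: dict[str, set[int]] = {}
        for g in genes:
            edges = exon_edges.setdefault(g.chrom, set())
            for s, e in g.exons:
                edges.update((s, e))
        for call in calls:
            local = pair_index.near(call.row.chrom, call.row.start,
                                    call.row.end, radius=500)
            bset = _breakpoints.annotate_call(
                call.row, local, genome,
                exclude_positions=exon_edges.get(call.row.chrom))
            call.row.bp5 = bset.bp5
            call.row.bp3 = bset.bp3
            call.row.tsd_seq = bset.tsd_seq
            call.row.polyA_len = bset.polyA_len
            call.row.en_motif = bset.en_motif
            gene = gene_by_id[call.row.gene_id]
            juncs = _junctions.annotate_junctions(
                call.row, local, gene, genome, stats)
            call.row.junctions = tuple(
                f"{j.exon_i}-{j.exon_j}" for j in juncs)
    calls.sort(key=lambda c: (c.row.chrom, c.row.start, c.row.gene_id))
    return calls


class _PairLocusIndex:
    """Bucketed lookup of read pairs by mapped position (5 kb bins)."""

    BIN = 5000

    def __init__(self, pairs: list[ReadPairRecord]):
        self._bins: dict[tuple[str, int], list[ReadPairRecord]] = {}
        for p in pairs:
            seen = set()
            for e in p.mapped_ends:
                for b in range(e.start // self.BIN, e.end // self.BIN + 1):
                    key = (e.chrom, b)
                    if key not in seen:
                        self._bins.setdefault(key, []).append(p)
                        seen.add(key)

    def near(self, chrom: str, start: int, end: int,
             radius: int = 500) -> list[ReadPairRecord]:
        lo, hi = max(0, start - radius), end + radius
        out, seen = [], set()
        for b in range(lo // self.BIN, hi // self.BIN + 1):
            for p in self._bins.get((chrom, b), ()):
                if id(p) in seen:
                    continue
                if any(e.chrom == chrom and e.start < hi and e.end > lo
                       for e in p.mapped_ends):
                    out.append(p)
                    seen.add(id(p))
        return out


def discover(samples: list[SampleInfo], genes: list[GeneModel],
             genome: Genome | None, stats: LibraryStats,
             params: DetectionParams = DetectionParams(),
             pseudogene_annotations=None,
             annotate: bool = True) -> list[InsertionCall]:
    """Run discovery from alignment files listed in a sample sheet."""
    per_sample = {
        s.sample_id: list(iterate_read_pairs(s.path, s.sample_id))
        for s in samples}
    return discover_from_pairs(per_sample, genes, genome, stats, params,
                               pseudogene_annotations, annotate)
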