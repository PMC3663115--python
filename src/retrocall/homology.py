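"""Local homology search and the pseudogene site filter.

Candidate insertion sites that fall inside an existing copy of the
source gene — an annotated pseudogene, or an unannotated one detectable
by sequence homology — are artifacts of read mis-anchoring rather than
novel insertions, and are filtered out.  Because the source gene of each
candidate is already known, homology search is restricted to (site flank
x source transcript) and (site flank x annotation library): a seeded
ungapped local aligner is sufficient at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import GeneModel, Genome, revcomp


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped local alignment between query and target."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float      # percent, 0..100
    length: int          # aligned bases
    strand: str          # '+' target forward, '-' target reverse complement

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity out of [0,100]")


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _extend_diagonal(query: str, target: str, q0: int, q1: int, diag: int,
                     max_drop: int = 8):
    """Greedy two-sided extension of a seeded span along one diagonal.

    A mismatch is absorbed while the running score (match +1, mismatch -1)
    stays within ``max_drop`` of its maximum; the reported span ends at
    the score maximum on each side (X-drop style, ungapped).
    """
    # extend right
    best_q1, score, best = q1, 0, 0
    j = q1
    while j < len(query) and j + diag < len(target):
        score += 1 if query[j] == target[j + diag] else -1
        j += 1
        if score > best:
            best, best_q1 = score, j
        elif best - score > max_drop:
            break
    # extend left
    best_q0, score, best = q0, 0, 0
    j = q0
    while j > 0 and j + diag > 0:
        j -= 1
        score += 1 if query[j] == target[j + diag] else -1
        if score > best:
            best, best_q0 = score, j
        elif best - score > max_drop:
            break
    matches = sum(1 for x in range(best_q0, best_q1)
                  if query[x] == target[x + diag])
    return best_q0, best_q1, matches


def local_align(query: str, target: str, min_identity: float = 80.0,
                min_len: int = 100, seed_len: int = 11) -> list[HomologyHit]:
    """Seed-and-extend ungapped local alignment, both strands.

    Reports every distinct diagonal whose extended span meets
    ``min_identity`` (percent) over at least ``min_len`` aligned bases.
    """
    query = query.upper()
    hits: list[HomologyHit] = []
    for strand in "+-":
        tgt = target.upper() if strand == "+" else revcomp(target).upper()
        if len(query) < seed_len or len(tgt) < seed_len:
            continue
        idx = _seed_index(tgt, seed_len)
        # group seed matches per diagonal (target_pos - query_pos)
        diags: dict[int, tuple[int, int]] = {}
        step = max(1, seed_len // 2)
        for q in range(0, len(query) - seed_len + 1, step):
            kmer = query[q:q + seed_len]
            if "N" in kmer:
                continue
            for t in idx.get(kmer, ()):
                d = t - q
                lo, hi = diags.get(d, (q, q + seed_len))
                diags[d] = (min(lo, q), max(hi, q + seed_len))
        for d, (q0, q1) in sorted(diags.items()):
            b0, b1, matches = _extend_diagonal(query, tgt, q0, q1, d)
            length = b1 - b0
            if length < min_len:
                continue
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            t0, t1 = b0 + d, b1 + d
            if strand == "-":
                t0, t1 = len(tgt) - t1, len(tgt) - t0
            hits.append(HomologyHit(b0, b1, t0, t1, identity, length, strand))
    # collapse near-duplicate diagonals, keep the longest per query span
    hits.sort(key=lambda h: (-h.length, h.query_start, h.strand))
    kept: list[HomologyHit] = []
    for h in hits:
        if any(k.strand == h.strand
               and max(k.query_start, h.query_start) < min(k.query_end, h.query_end)
               and max(k.target_start, h.target_start) < min(k.target_end, h.target_end)
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.query_start, h.target_start, h.strand))
    return kept


def screen_site(chrom: str, start: int, end: int, gene: GeneModel,
                genome: Genome,
                pseudogene_annotations: list[tuple[str, int, int, str]] | None,
                transcript: str, flank: int = 500,
                min_identity: float = 80.0, min_len: int = 100) -> str:
    """Classify a candidate insertion site.

    Returns ``"pass"``, ``"fail_annotated"`` (site +- flank intersects an
    annotated pseudogene) or ``"fail_unannotated"`` (site flank carries
    local homology to the source gene's spliced transcript).
    """
    lo = max(0, start - flank)
    hi = min(genome.chrom_sizes[chrom], end + flank)
    if pseudogene_annotations:
        for pchrom, ps, pe, _name in pseudogene_annotations:
            if pchrom == chrom and ps < hi and pe > lo:
                return "fail_annotated"
    flank_seq = genome.fetch(chrom, lo, hi)
    if local_align(flank_seq, transcript, min_identity=min_identity,
                   min_len=min_len):
        return "fail_unannotated"
    return "pass"
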