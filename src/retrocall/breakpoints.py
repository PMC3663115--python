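"""Breakpoint refinement from soft-clipped reads.

Retrotransposed insertions leave base-precise scars: reads crossing a
junction align up to it and carry the inserted sequence as a soft-clip.
Staggered endonuclease nicks duplicate a short target tract (TSD), so
the two junction clip sites *cross* — the right-facing clip pile sits
``tsd_len`` bases to the right of the left-facing pile, and the
reference tract between them is the TSD.  The insertion-side 3' ends
terminate in poly-A, which also tells us the insertion's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import Genome, ReadPairRecord, revcomp

_COMP_ONLY = str.maketrans("ACGTN", "TGCAN")


@dataclass
class BreakpointSet:
    """Junction evidence for one call.

    ``bp5``/``bp3`` are the genomic coordinates where the insertion's
    5' and 3' ends attach; for a TSD-bearing event they flank the
    duplicated tract, so ``tsd_seq`` (when present) equals the reference
    sequence of ``[min(bp5,bp3), max(bp5,bp3))``.
    """

    bp5: int | None = None
    bp3: int | None = None
    tsd_seq: str | None = None
    polyA_len: int = 0
    en_motif: str | None = None
    insertion_strand: str | None = None
    n_clip_support_5: int = 0
    n_clip_support_3: int = 0


def find_softclip_breakpoints(pairs: list[ReadPairRecord], chrom: str,
                              start: int, end: int, min_clip: int = 10,
                              radius: int = 500, min_support: int = 2,
                              exclude_positions: set[int] | None = None):
    """Locate the two clip pile-ups around a call.

    Returns ``((pos_right, n_right, tails_right), (pos_left, n_left,
    tails_left))`` where *right* collects reads whose clipped tail is on
    the right (they enter the insertion from the left; modal aligned
    right edge) and *left* the mirror image.  A pile-up is reported only
    when >= ``min_support`` clips agree on the exact position; among
    qualifying pile-ups the one nearest the call interval wins (clips at
    a nearby gene's exon boundaries — splice-junction scars of *other*
    retrocopies — can outnumber the true junction but sit further away),
    with ties broken by support then coordinate.

    ``exclude_positions`` (typically the annotated exon boundaries near
    the locus) are never considered: clips piling exactly at an exon
    terminus are retrocopy reads mapping back to their source exon — a
    scar of some insertion *somewhere*, not evidence for a junction at
    this locus.
    """
    lo, hi = max(0, start - radius), end + radius
    excl = exclude_positions or ()
    votes_r: dict[int, list[str]] = {}
    votes_l: dict[int, list[str]] = {}
    for rec in pairs:
        for e in rec.mapped_ends:
            if e.chrom != chrom or e.end <= lo or e.start >= hi:
                continue
            if e.clip_right >= min_clip and e.end not in excl:
                votes_r.setdefault(e.end, []).append(e.right_tail)
            if e.clip_left >= min_clip and e.start not in excl:
                votes_l.setdefault(e.start, []).append(e.left_tail)

    def polya_scar(tails: list[str], base: str, leading: bool) -> bool:
        # Right-facing clips whose tails *begin* with a poly-A run (or
        # left-facing ones *ending* in poly-T, the strand mirror) are
        # the 3'-end scar of some other retrocopy's reads mapping back
        # to their source exon — never an insertion junction, whose
        # right tails carry transcript sequence or a poly-T prefix.
        n_run = 0
        for t in tails:
            if not t:
                continue
            probe = t if leading else t[::-1]
            run = len(probe) - len(probe.lstrip(base))
            if run >= 5:
                n_run += 1
        return n_run > len(tails) / 2

    votes_r = {pos: tails for pos, tails in votes_r.items()
               if not polya_scar(tails, "A", leading=True)}
    votes_l = {pos: tails for pos, tails in votes_l.items()
               if not polya_scar(tails, "T", leading=False)}

    def modal(votes):
        ranked = sorted(
            (max(start - pos, pos - end, 0), -len(tails), pos)
            for pos, tails in votes.items() if len(tails) >= min_support)
        if not ranked:
            return None, 0, []
        _, neg_n, pos = ranked[0]
        return pos, -neg_n, votes[pos]

    return modal(votes_r), modal(votes_l)


def detect_polyA(tails: list[str], min_run: int = 5,
                 max_mismatch_frac: float = 0.2) -> int:
    """Length of the terminal poly-A run across supporting tails.

    Tails must be oriented so the run is a prefix (i.e. reading into the
    insertion from its 3' junction).  A run absorbs isolated non-A bases
    while they stay under ``max_mismatch_frac`` of its length, and
    terminates at two consecutive non-A bases; the reported length ends
    on an A.

    Tails long enough to see past the run ("terminated": a non-A base
    follows) measure it exactly and vote; the modal measurement wins
    (larger on ties), which makes the estimate robust to a stray
    boundary sequencing error.  Tails that are pure run are only lower
    bounds and are used when no tail terminates.  Invariant to
    duplicated tails.  Returns 0 below ``min_run``.
    """
    exact: dict[int, int] = {}
    bound = 0
    for tail in tails:
        best = 0
        non_a = 0
        prev_non_a = False
        for i, ch in enumerate(tail):
            if ch == "A":
                prev_non_a = False
                if non_a <= max_mismatch_frac * (i + 1):
                    best = i + 1
            else:
                non_a += 1
                if prev_non_a:
                    break
                prev_non_a = True
        if best < len(tail):
            exact[best] = exact.get(best, 0) + 1
        else:
            bound = max(bound, best)
    if exact:
        run = max(exact, key=lambda k: (exact[k], k))
        run = max(run, 0)
    else:
        run = bound
    return run if run >= min_run else 0


def detect_tsd(genome: Genome, chrom: str, bp5: int, bp3: int,
               max_tsd: int = 50, inner_tails: list[str] | None = None,
               chrom3: str | None = None) -> str | None:
    """Target site duplication between the two junction coordinates.

    Returns the reference tract ``[min(bp5,bp3), max(bp5,bp3))`` when it
    is 1..``max_tsd`` bp and, if junction tails are supplied, when the
    right-facing clipped tails are genuinely inserted sequence (they must
    *not* simply continue the reference past the clip site).  Returns
    ``None`` for blunt (zero-width) or oversized separations.
    """
    if chrom3 is not None and chrom3 != chrom:
        raise ValueError("breakpoints on different chromosomes")
    lo, hi = min(bp5, bp3), max(bp5, bp3)
    gap = hi - lo
    if gap == 0 or gap > max_tsd:
        return None
    tract = genome.fetch(chrom, lo, hi)
    if inner_tails:
        size = genome.chrom_sizes[chrom]
        probe = genome.fetch(chrom, hi, min(size, hi + 12))
        confirmed = False
        for tail in inner_tails:
            t = tail[: len(probe)]
            if not t:
                continue
            mism = sum(1 for a, b in zip(t, probe) if a != b)
            if mism >= max(2, len(t) // 4):
                confirmed = True
                break
        if not confirmed:
            return None
    return tract


def en_cleavage_site(genome: Genome, chrom: str, bp5: int,
                     insertion_strand: str = "+") -> str | None:
    """4+4 bp context around the endonuclease nick, on the nicked strand.

    For a top-strand insertion the LINE-1 endonuclease nicks the bottom
    strand, so the window is reverse-complemented; the ``/`` marks the
    scissile position.  L1-preferred sites read ``TTTT/AA...``.  Returns
    ``None`` when the window would leave the chromosome.
    """
    size = genome.chrom_sizes[chrom]
    if bp5 < 4 or bp5 + 4 > size:
        return None
    window = genome.fetch(chrom, bp5 - 4, bp5 + 4)
    if insertion_strand == "+":
        window = revcomp(window)
    return window[:4] + "/" + window[4:]


def annotate_call(row, pairs: list[ReadPairRecord], genome: Genome,
                  min_clip: int = 10, radius: int = 500, max_tsd: int = 50,
                  exclude_positions: set[int] | None = None) -> BreakpointSet:
    """Full breakpoint/TSD/poly-A/motif annotation for one call row.

    Both insertion orientations are scored (poly-A should appear on the
    left-facing tails for a top-strand insertion, as a poly-T prefix on
    the right-facing tails for a bottom-strand one) and the higher-
    scoring orientation is kept.
    """
    (pos_r, n_r, tails_r), (pos_l, n_l, tails_l) = find_softclip_breakpoints(
        pairs, row.chrom, row.start, row.end, min_clip=min_clip,
        radius=radius, exclude_positions=exclude_positions)
    bset = BreakpointSet()
    if pos_r is None and pos_l is None:
        return bset
    # orientation from which junction shows the poly-A tail
    score_plus = detect_polyA([t[::-1] for t in tails_l]) if tails_l else 0
    score_minus = (detect_polyA([t.translate(_COMP_ONLY) for t in tails_r])
                   if tails_r else 0)
    if score_plus >= score_minus:
        strand, polya = "+", score_plus
        bset.bp5, bset.n_clip_support_5 = pos_r, n_r
        bset.bp3, bset.n_clip_support_3 = pos_l, n_l
    else:
        strand, polya = "-", score_minus
        bset.bp5, bset.n_clip_support_5 = pos_l, n_l
        bset.bp3, bset.n_clip_support_3 = pos_r, n_r
    bset.insertion_strand = strand
    bset.polyA_len = polya
    if bset.bp5 is not None and bset.bp3 is not None:
        bset.tsd_seq = detect_tsd(genome, row.chrom, bset.bp5, bset.bp3,
                                  max_tsd=max_tsd, inner_tails=tails_r)
    if bset.bp5 is not None:
        bset.en_motif = en_cleavage_site(genome, row.chrom, bset.bp5, strand)
    return bset
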