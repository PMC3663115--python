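# Methods

This note documents the models, thresholds, numerical choices and known
limitations of `retrocall`.

## Detection model

Paired-end sequencing of a genome carrying a retrocopy insertion
produces read pairs whose ends map to two distant reference locations:
the source gene's exons and the insertion site.  The caller works on
this signal alone; split-read-only calling and intron-retaining
(unspliced) insertions are out of scope.

**Pair classification.**  A pair is *concordant* iff both ends map to
one chromosome in FR orientation (leftmost mate `+`, rightmost `-`)
with outer span ≤ `median_insert + 4·insert_sd`; *discordant*
otherwise; *one-end-anchored* (OEA) if exactly one end maps.
`median_insert` is the median outer fragment span (both sequenced ends
plus the unsequenced gap — a 100 bp paired library with a 300 bp
unsequenced insert has `median_insert = 500`).  OEA pairs are used only
for junction assembly, not discovery.

**Harvesting.**  A discordant pair anchors gene *g* when one end
overlaps an exon of *g* by ≥ 20 bp and the other maps outside the gene
span ± 10 kb (or another chromosome), with both ends at MAPQ ≥ 20.
The 10 kb flank separates genuine retrocopies from local structural
noise around the source locus; MAPQ 20 excludes ambiguous anchors that
would fabricate "distinct" support.  A pair whose distal end falls in
a *different* gene's exon still anchors *g* — insertions into other
genes' exons are real and reportable.

**Clustering and calling.**  Distal mappings are clustered per gene by
single linkage with a 500 bp gap, the same locality used everywhere
else in the pipeline (junction read collection, homology screen,
cross-sample locus identity).  Distinct mappings are deduplicated by
(distal start, distal strand) so PCR/optical duplicates count once.
Thresholds: ≥ 8 distinct mappings, ≥ 2 per side, ≥ 2 distinct exons,
`+` group left of `-` group with ≤ 30 bp overlap allowance (a TSD makes
junction-proximal mates straddle).  The call interval is the gap
between the innermost edges of the two groups (the overlap tract when
they cross).  Sample attribution is pre-deduplication: every genome
contributing any supporting read is a carrier.  Output order and all
tie-breaks are deterministic, so discovery is invariant to input read
order.

**Pseudogene screen.**  A site ± 500 bp is rejected if it intersects an
annotated pseudogene, or if a seed-and-extend local alignment (11-mer
seeds, ungapped X-drop extension, both strands) of the flank against
the source gene's spliced transcript finds ≥ 80% identity over
≥ 100 bp.  Because each candidate's source gene is known, homology
search is restricted to (flank × transcript) — no genome-wide search is
needed.  Lowering the identity threshold can only move calls from pass
to fail (monotonicity is a tested property).

## Breakpoints, TSD, poly-A, endonuclease motif

Reads crossing a junction align up to it and carry inserted sequence as
a soft clip.  Clips ≥ 10 bp vote for a breakpoint; ≥ 2 exact-position
agreements are required (bwa-style clips are base-precise, so no fuzz
is allowed).  Two heuristics protect the vote from *other* events'
scars, which matter whenever an insertion lands inside or near another
gene's exons:

* clip pile-ups whose right-facing tails begin with a poly-A run (or
  left-facing tails end in poly-T) are transcript-3'-end scars of some
  retrocopy's reads mapping back to their source exon, never an
  insertion junction, and are discarded;
* votes at annotated exon boundaries are excluded for the same reason
  (transcript-terminus and splice-junction scars pile exactly there);
* among surviving pile-ups, the one nearest the call interval wins
  (ties: more support, then lower coordinate).

For a TSD-bearing insertion the two junction coordinates *cross*: the
5'-junction clip site sits `tsd_len` bases right of the 3'-junction
site, and the reference tract between them (1–50 bp) is the TSD.  The
tract is only reported when the junction tails are genuinely inserted
sequence (they must not continue the reference past the clip), which
guards against coincidental breakpoint spacing.  Insertion orientation
is inferred from which junction shows the poly-A (a bottom-strand
insert shows it as a poly-T prefix on the other side); both
orientations are scored and the better kept.  The poly-A length is the
modal terminated A-run across supporting tails — a run absorbs isolated
non-A bases under 20% of its length, stops at two consecutive non-A
bases, and ends on an A; tails that are pure run are lower bounds only.
The modal rule makes the estimate invariant to duplicated tails and
robust to a single boundary sequencing error.  The endonuclease context
is the 4+4 bp window around the 5' junction read on the nicked strand
(bottom strand for a top-strand insertion), written `NNNN/NNNN`;
L1-preferred sites read `TTTT/AA...`.

## Junction assembly

Junction-informative reads — discordant, OEA, or soft-clipped pairs
mapping within 500 bp of the call, with their mates — are assembled by
a minimal de Bruijn assembler: k-mer counting on both strands, k-mers
below count 2 pruned (kills isolated sequencing errors), unbranched
paths emitted as contigs ≥ 2k−1 bp, lexicographic traversal order so
assembly is deterministic for a given read multiset.  The primary pass
uses k = 31; calls yielding no junction are retried at k = 21, which
tolerates thinner coverage.  A junction is reported when the last 20 bp
of one exon are immediately followed in a contig by the first 20 bp of
a later exon (both contig orientations; exon skips reported as-is; an
intron-retaining contig can never match).  Exact flank matching is the
default; one mismatch per flank can be allowed for noisier data.

## Simulation harness

The generator emulates the study conditions the caller is designed
for, and doubles as the test fixture factory.  Defaults (chosen once):

| parameter | default | note |
|---|---|---|
| genome | 2 × 200 kb chromosomes | random uniform base composition |
| genes | 24 (23 multi-exon, 1 single-exon) | 2–6 exons of 80–250 bp, introns 200–800 bp, random strand |
| spikes | 54 multi-exon + 3 single-exon | ≥ 50 multi-exon events for stable rates |
| TSD | uniform 5–25 bp (two spikes at 0) | zero-TSD insertions stay representable |
| poly-A | uniform 10–30 bp | |
| 5' truncation | 40% of spikes, ≤ 50% of transcript | insert kept ≥ 250 bp |
| reads | 100 bp FR, 500 bp outer fragment (sd 30) | i.e. a 300 bp unsequenced insert |
| errors | 0.1% substitutions, no indels | |
| coverage | 60×, downsampled 60/40/30/20/10/5× | pairs dropped atomically |

Spiking operates at the sequence level: the allele is
`ref[:pos+tsd] + insert + ref[pos:]`, so the duplicated tract flanks
the insert on both sides.  Reads are sampled uniformly from the
modified alleles and mapped back to the *unmodified* reference by an
internal seed-and-extend mapper (20-mer exact seeds at three read
offsets, both strands; candidate diagonals scored by total matches;
the aligned block grows from the longest exact run and absorbs an
isolated mismatch only when the next four bases match, so alignments
stop base-precisely at insertion junctions and the remainder is
soft-clipped; MAPQ 60 unique / 0 tied).  An external SAM-emitting
mapper can be substituted where realism matters more than
self-containment.

**What the generator deliberately does not emulate.**  Insertion sites
are resampled until there is no junction micro-homology (the first and
last inserted bases differ from the adjoining reference bases, and the
junction-adjacent 4-mers differ too), and generated transcripts end in
two non-A bases.  Without these constraints the true junction
coordinate, TSD length and poly-A length are ambiguous *in principle*
(micro-homology makes multiple breakpoint placements equally
consistent with every read), so exact parameter-recovery tests could
not be stated.  Real genomes offer no such guarantee: on real data,
breakpoints and TSD lengths can be off by the micro-homology length,
and poly-A tails adjacent to genomic A-runs are over-measured.  Passing
recovery tests therefore demonstrate correctness of the inference given
unambiguous evidence, not immunity to genuinely ambiguous junctions.
Also absent: quality-score structure, indels and background SVs,
repeat families, GC bias, and chimeric fragments.

Scoring matches calls to truth by source gene and site proximity
(≤ 100 bp), one call per truth (nearest assignment).  At the default
conditions the caller attains 100% precision at 60× with recall ≈ 1
for multi-exon spikes; recall is non-increasing down the coverage
ladder, and single-exon spikes are never called — the caller's designed
blind spot.  Problem sizes were chosen so the full benchmark (build +
map + discover) completes in well under a minute on one core.

## Cohort and population genetics

Calls are unified into loci per gene by single-linkage interval merging
(500 bp slop) across samples; a profile matrix cell is true iff the
sample contributed support.  Jaccard distances between profiles are
computed exactly on sets; hierarchical clustering uses average linkage
by default (`complete` and `single` available) with lexicographic
label order for deterministic ties, exported as Newick and nested
lists.  Somatic subtraction vetoes a tumor call on a *single*
discordant pair at the same gene/locus (± 500 bp) in the matched normal
or any other cohort sample — the veto scans raw pairs, not calls,
which is the stricter reading of "no corresponding read pairs".
Reference-resident retrocopies are recovered from deletion calls that
fully contain a pseudogene annotation, span ≤ 3× its length (UTR
repeat allowance) and are homologous to the source transcript.

Estimators: `a_n = Σ 1/i` exactly summed; `θ̂_W = S/a_n`;
`μ = θ/(4·N_e)` with the reciprocal rounded to the nearest integer;
`θ̂_T = Σ 2k(n−k)/(n(n−1))` over carrier counts, evaluated in exact
rational arithmetic; Tajima's D with the standard coefficient chain
(b₁, b₂, c₁, c₂, e₁, e₂) for V̂.  A user-supplied V̂ is accepted so
published worked examples can be reproduced verbatim when their
variance derivation is not stated.  The ±2.0 critical values are
reported as an interpretive label only.  The one-sample proportions
test is the Yates-corrected chi-square with the correction clamped at
|x − np₀| (statistic exactly 0 when observed equals expected),
matching R's `prop.test`; annotation coverage is exact rational
interval-union arithmetic.

## Degenerate inputs and tie-breaks

* Jaccard distance of two empty profiles, clustering of < 2 samples,
  non-segregating carrier counts, V ≤ 0, degenerate p₀ ∈ {0, 1} and
  out-of-bounds intervals raise `ValueError` rather than guessing.
* Zero-width breakpoint separation → blunt insertion, no TSD; > 50 bp
  separation → no TSD.
* Empty read sets assemble to an empty contig list; a cluster failing
  any rule returns a reason code rather than a partial call.
* All output orderings (calls, contigs, junctions, loci, dendrogram
  leaves) are deterministic.

## Known limitations

* Single-exon retrocopies are invisible by design (exon-diversity
  rule); the paper's false-negative mode is reproduced, not fixed.
* Twin-priming/inverted structures, 3' transductions and
  intron-retaining copies are not modeled.
* The homology screen is ungapped; a heavily indel-diverged pseudogene
  decoy could evade it.
* The internal read mapper is built for the simulation's error model
  (substitutions only); real-data workflows should map with a
  production aligner and feed the BAM in.
* Region queries re-scan the file rather than using the index, which is
  simple and correct but not suited to multi-gigabyte BAMs.
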