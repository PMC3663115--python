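"""Multi-sample reasoning over GRIP calls.

Presence/absence profiles across samples, Jaccard distances and
hierarchical clustering of those profiles, per-population carrier
frequencies, somatic subtraction for tumor/normal pairs, and detection
of retrocopies already present in the reference (which appear as
deletions in other individuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats import CallTableRow, GeneModel, Genome
from .homology import local_align

log = logging.getLogger("retrocall")


@dataclass(frozen=True)
class GripLocus:
    """Identity key for "the same GRIP" across samples."""

    chrom: str
    start: int
    end: int
    gene_id: str

    @property
    def label(self) -> str:
        return f"{self.gene_id}@{self.chrom}:{self.start}-{self.end}"


@dataclass
class ProfileMatrix:
    """Samples x loci boolean presence matrix."""

    matrix: pd.DataFrame
    loci: list[GripLocus]
    populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates or self.matrix.columns.has_duplicates:
            raise ValueError("duplicate sample or locus labels")

    def locus_set(self, sample: str) -> frozenset[str]:
        row = self.matrix.loc[sample]
        return frozenset(row.index[row])


def build_profile_matrix(calls, merge_slop: int = 500,
                         populations: dict[str, str] | None = None
                         ) -> ProfileMatrix:
    """Unify calls across samples into loci and tabulate carriers.

    Loci of the same source gene are merged by single-linkage when their
    intervals come within ``merge_slop`` bp; a cell is true iff the
    sample contributed supporting reads to the merged locus.
    """
    rows = [c.row if hasattr(c, "row") else c for c in calls]
    by_gene: dict[str, list[CallTableRow]] = {}
    for r in rows:
        by_gene.setdefault(r.gene_id, []).append(r)
    loci: list[GripLocus] = []
    carriers: dict[GripLocus, set[str]] = {}
    for gene_id in sorted(by_gene):
        grouped = sorted(by_gene[gene_id], key=lambda r: (r.chrom, r.start))
        cluster: list[CallTableRow] = []
        edge = None
        chrom = None

        def flush():
            if not cluster:
                return
            locus = GripLocus(chrom=cluster[0].chrom,
                              start=min(r.start for r in cluster),
                              end=max(r.end for r in cluster),
                              gene_id=gene_id)
            loci.append(locus)
            carriers[locus] = {s for r in cluster for s in r.samples}

        for r in grouped:
            if cluster and r.chrom == chrom and r.start - edge <= merge_slop:
                cluster.append(r)
                edge = max(edge, r.end)
            else:
                flush()
                cluster = [r]
                chrom, edge = r.chrom, r.end
        flush()
    samples = sorted({s for c in carriers.values() for s in c})
    data = {locus.label: [s in carriers[locus] for s in samples]
            for locus in loci}
    matrix = pd.DataFrame(data, index=samples, dtype=bool)
    return ProfileMatrix(matrix=matrix, loci=loci, populations=populations)


def jaccard_distance(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard distance (|A u B| - |A n B|) / |A u B|, exact on sets."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard distance undefined for two empty sets")
    return float(Fraction(union - len(a & b), union))


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray
    newick: str
    nested: list


def cluster_profiles(profile: ProfileMatrix,
                     linkage_method: str = "average") -> Dendrogram:
    """Agglomerative clustering of samples on pairwise Jaccard distance.

    Samples are taken in lexicographic label order (deterministic ties);
    exported both as a Newick string and a nested list.
    """
    labels = sorted(profile.matrix.index)
    if len(labels) < 2:
        raise ValueError("need at least two samples to cluster")
    sets = {s: profile.locus_set(s) for s in labels}
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = jaccard_distance(sets[labels[i]],
                                                   sets[labels[j]])
    Z = hierarchy.linkage(squareform(dm, checks=False),
                          method=linkage_method)
    tree = hierarchy.to_tree(Z)

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = newick(node.left), newick(node.right)
        dl = node.dist - (node.left.dist if not node.left.is_leaf() else 0)
        dr = node.dist - (node.right.dist if not node.right.is_leaf() else 0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    def nested(node):
        if node.is_leaf():
            return labels[node.id]
        return [nested(node.left), nested(node.right)]

    return Dendrogram(labels=labels, linkage=Z, newick=newick(tree) + ";",
                      nested=nested(tree))


def population_frequencies(profile: ProfileMatrix,
                           populations: dict[str, str] | None = None
                           ) -> pd.DataFrame:
    """Carrier frequency of each locus in each population (loci x pops)."""
    pops = populations or profile.populations
    if pops is None:
        raise ValueError("population labels required")
    for s in profile.matrix.index:
        if s not in pops:
            raise ValueError(f"sample {s!r} has no population label")
    groups: dict[str, list[str]] = {}
    for s in profile.matrix.index:
        groups.setdefault(pops[s], []).append(s)
    out = {}
    for pop in sorted(groups):
        members = groups[pop]
        out[pop] = profile.matrix.loc[members].sum(axis=0) / len(members)
    return pd.DataFrame(out)


def somatic_calls(tumor_calls, normal_pairs, cohort_pairs,
                  merge_slop: int = 500):
    """Tumor calls with zero supporting evidence anywhere else.

    A tumor call survives only if *no* discordant pair anchored to the
    same source gene maps within ``merge_slop`` of its locus in the
    matched normal or in any other cohort sample — a single read pair
    vetoes, with no call-level threshold applied to the veto.
    """
    veto = list(normal_pairs) + list(cohort_pairs)
    out = []
    for call in tumor_calls:
        row = call.row if hasattr(call, "row") else call
        lo, hi = row.start - merge_slop, row.end + merge_slop
        vetoed = any(
            p.gene_id == row.gene_id and p.distal.chrom == row.chrom
            and p.distal.start < hi and p.distal.end > lo
            for p in veto)
        if not vetoed:
            out.append(call)
    return out


@dataclass(frozen=True)
class ReferenceGrip:
    chrom: str
    deletion_start: int
    deletion_end: int
    pseudogene_name: str
    source_gene: str
    identity: float


def reference_grips(deletions: list[tuple[str, int, int]],
                    pseudogenes: list[tuple[str, int, int, str]],
                    genome: Genome, genes: list[GeneModel],
                    max_size_ratio: float = 3.0, min_identity: float = 80.0,
                    min_len: int = 100) -> list[ReferenceGrip]:
    """Retrocopies present in the reference, seen as deletions elsewhere.

    A deletion call qualifies when it fully contains a pseudogene
    annotation, spans at most ``max_size_ratio`` times the annotation
    (UTR repeats allowance), and the deleted sequence is homologous to
    the source gene's spliced transcript.  Pseudogene names carry their
    source gene as ``name|source_gene`` (a bare name is taken as the
    source gene itself when it matches a known gene).
    """
    from .simulate import spliced_transcript
    gene_by_id = {g.gene_id: g for g in genes}
    out: list[ReferenceGrip] = []
    for pchrom, ps, pe, name in pseudogenes:
        if "|" in name:
            pg_name, source = name.split("|", 1)
        else:
            pg_name, source = name, name
        gene = gene_by_id.get(source)
        if gene is None:
            log.warning("pseudogene %r has no resolvable source gene; "
                        "skipped", name)
            continue
        transcript = spliced_transcript(gene, genome)
        ann_len = pe - ps
        for dchrom, ds, de in deletions:
            if dchrom != pchrom or ds > ps or de < pe:
                continue
            if de - ds > max_size_ratio * ann_len:
                continue
            hits = local_align(genome.fetch(dchrom, ds, de), transcript,
                               min_identity=min_identity, min_len=min_len)
            if not hits:
                continue
            out.append(ReferenceGrip(
                chrom=dchrom, deletion_start=ds, deletion_end=de,
                pseudogene_name=pg_name, source_gene=source,
                identity=max(h.identity for h in hits)))
    out.sort(key=lambda r: (r.chrom, r.deletion_start, r.source_gene))
    return out
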