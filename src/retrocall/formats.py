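"""Readers, writers and shared data conventions.

Every genomic interval inside the package is **0-based, half-open**.
SAM and VCF coordinates (1-based) are converted at the I/O boundary and
nowhere else.  Secondary, supplementary and duplicate-flagged alignments
are dropped at ingest so that "distinct mappings" downstream are never
inflated by multi-reporting.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pysam
from pyfaidx import Fasta

log = logging.getLogger("retrocall")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene: chromosome, strand and ordered exon intervals.

    ``exons`` are sorted ascending in genomic coordinates and
    non-overlapping.  Exon *transcription-order* indices (1-based) run
    left-to-right for ``+`` genes and right-to-left for ``-`` genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_like: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        last = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e}) in {self.gene_id}")
            if last is not None and s < last:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            last = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def tx_exons(self) -> list[tuple[int, tuple[int, int]]]:
        """Exons as (transcription-order index, interval), index from 1."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        return [(i + 1, iv) for i, iv in enumerate(order)]

    def exon_tx_index(self, genomic_ordinal: int) -> int:
        """Transcription-order index (1-based) of the exon at genomic rank."""
        if self.strand == "+":
            return genomic_ordinal + 1
        return len(self.exons) - genomic_ordinal


@dataclass(frozen=True)
class LibraryStats:
    """Paired-end library model (Illumina forward-reverse layout).

    ``median_insert`` is the median *outer* fragment span: both sequenced
    ends plus the unsequenced gap.  A 100 bp paired library with a 300 bp
    unsequenced insert therefore has median_insert = 500.
    """

    read_length: int
    median_insert: int
    insert_sd: int
    orientation: str = "FR"

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.median_insert < 2 * self.read_length:
            raise ValueError("median_insert must cover both sequenced ends")
        if self.orientation != "FR":
            raise ValueError("only FR libraries are modeled")

    @property
    def max_concordant_span(self) -> int:
        return self.median_insert + 4 * self.insert_sd


@dataclass(frozen=True)
class ReadEnd:
    """One mapped end of a pair, with soft-clip bookkeeping.

    ``seq`` is stored in reference-forward orientation (SAM convention);
    ``clip_left``/``clip_right`` are soft-clip lengths on each side of the
    aligned block, so the clipped tails are ``seq[:clip_left]`` and
    ``seq[len(seq)-clip_right:]``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    cigar: str
    seq: str
    clip_left: int = 0
    clip_right: int = 0

    @property
    def soft_clipped(self) -> bool:
        return self.clip_left > 0 or self.clip_right > 0

    @property
    def left_tail(self) -> str:
        return self.seq[: self.clip_left]

    @property
    def right_tail(self) -> str:
        return self.seq[len(self.seq) - self.clip_right:] if self.clip_right else ""


@dataclass(frozen=True)
class ReadPairRecord:
    """A reunited read pair from one sample; either end may be unmapped."""

    query_name: str
    sample_id: str
    end1: ReadEnd | None
    end2: ReadEnd | None

    def __post_init__(self) -> None:
        if self.end1 is None and self.end2 is None:
            raise ValueError(f"pair {self.query_name} has no mapped end")

    @property
    def mate_unmapped(self) -> bool:
        return self.end1 is None or self.end2 is None

    @property
    def soft_clipped(self) -> bool:
        return any(e is not None and e.soft_clipped for e in (self.end1, self.end2))

    @property
    def mapped_ends(self) -> list[ReadEnd]:
        return [e for e in (self.end1, self.end2) if e is not None]


@dataclass
class CallTableRow:
    """One row of the call table (mirrors the TSV/BED output)."""

    chrom: str
    start: int
    end: int
    gene_id: str
    n_left: int
    n_right: int
    exons_hit: tuple[int, ...]
    samples: tuple[str, ...]
    filter_status: str = "PASS"
    bp5: int | None = None
    bp3: int | None = None
    tsd_seq: str | None = None
    polyA_len: int = 0
    en_motif: str | None = None
    junctions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end in call row")

    @property
    def n_support_total(self) -> int:
        return self.n_left + self.n_right


CALL_COLUMNS = [
    "chrom", "start", "end", "gene_id", "n_support_total", "n_left",
    "n_right", "exons_hit", "samples", "filter_status", "bp5", "bp3",
    "tsd_seq", "polyA_len", "en_motif", "junctions",
]


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    path: str
    population: str = "NA"
    pair_id: str = "NA"
    tissue: str = "NA"


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------

class Genome:
    """Uniform accessor over a FASTA file or an in-memory sequence dict.

    Subsequence queries are 0-based half-open and always uppercase.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        fa = Fasta(path, as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequence(chrom)
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"{chrom}:{start}-{end} out of range (length {len(seq)})")
        return seq[start:end]

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        try:
            Fasta(path)  # builds the .fai index alongside
        except Exception:  # pragma: no cover - index build is best effort
            pass


def load_genome(path: str) -> Genome:
    """Load a FASTA (index built if absent) into a :class:`Genome`."""
    return Genome.from_fasta(path)


# ---------------------------------------------------------------------------
# gene models (BED12)
# ---------------------------------------------------------------------------

def parse_bed12_line(line: str, lineno: int = 0) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"BED12 parse error at line {lineno}: "
                         f"expected 12 columns, got {len(f)}")
    try:
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"BED12 parse error at line {lineno}: {exc}") from exc
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(
            f"BED12 parse error at line {lineno}: blockCount {n_blocks} does "
            f"not match blockSizes/blockStarts lists")
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons,
                     cds_like=thick_start < thick_end)


def load_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from a BED12 file.

    Malformed lines raise (naming the line number); records whose blocks
    overlap are rejected with a warning and skipped.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                genes.append(parse_bed12_line(line, lineno))
            except ValueError as exc:
                if "overlap" in str(exc):
                    log.warning("skipping record at line %d: %s", lineno, exc)
                    continue
                raise
    return genes


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    """Serialize gene models back to BED12 (exon structure preserved)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            thick = (g.start, g.end) if g.cds_like else (g.start, g.start)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                thick[0], thick[1], "0", g.n_exons, sizes, offsets,
            ])) + "\n")


# ---------------------------------------------------------------------------
# read pairs (SAM/BAM)
# ---------------------------------------------------------------------------

def _read_end_from_segment(aln: pysam.AlignedSegment) -> ReadEnd | None:
    if aln.is_unmapped:
        return None
    clip_left = clip_right = 0
    ct = aln.cigartuples or []
    if ct and ct[0][0] == 4:
        clip_left = ct[0][1]
    if len(ct) > 1 and ct[-1][0] == 4:
        clip_right = ct[-1][1]
    return ReadEnd(
        chrom=aln.reference_name,
        start=aln.reference_start,
        end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
        cigar=aln.cigarstring or "",
        seq=aln.query_sequence or "",
        clip_left=clip_left,
        clip_right=clip_right,
    )


def iterate_read_pairs(path: str, sample_id: str = "sample",
                       region: tuple[str, int, int] | None = None):
    """Yield :class:`ReadPairRecord` from a SAM/BAM file.

    Pairs are reunited by query name; secondary, supplementary and
    duplicate alignments are excluded.  With ``region`` given, only pairs
    with at least one mapped end overlapping the interval are yielded
    (mate information is still complete, which is why the whole file is
    scanned rather than a coordinate slice).
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            other = pending.pop(aln.query_name, None)
            if other is None:
                pending[aln.query_name] = aln
                continue
            first, second = (other, aln) if other.is_read1 else (aln, other)
            rec = ReadPairRecord(
                query_name=aln.query_name,
                sample_id=sample_id,
                end1=_read_end_from_segment(first),
                end2=_read_end_from_segment(second),
            )
            if region is None or _pair_overlaps(rec, region):
                yield rec
    for qname, aln in pending.items():
        if aln.is_unmapped:
            continue
        end = _read_end_from_segment(aln)
        e1, e2 = (end, None) if aln.is_read1 else (None, end)
        rec = ReadPairRecord(query_name=qname, sample_id=sample_id,
                             end1=e1, end2=e2)
        if region is None or _pair_overlaps(rec, region):
            yield rec


def _pair_overlaps(rec: ReadPairRecord, region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    return any(e.chrom == chrom and e.start < end and e.end > start
               for e in rec.mapped_ends)


# ---------------------------------------------------------------------------
# call table
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v) if v else "."
    return str(v)


def write_calls(rows: list[CallTableRow], tsv_path: str,
                bed_path: str | None = None) -> None:
    """Write the call table as TSV plus a companion BED of loci."""
    if bed_path is None:
        root, _ = os.path.splitext(tsv_path)
        bed_path = root + ".bed"
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), r.gene_id,
                str(r.n_support_total), str(r.n_left), str(r.n_right),
                _fmt(r.exons_hit), _fmt(r.samples), r.filter_status,
                _fmt(r.bp5), _fmt(r.bp3), _fmt(r.tsd_seq),
                str(r.polyA_len), _fmt(r.en_motif), _fmt(r.junctions),
            ]) + "\n")
    with open(bed_path, "w") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\n")


def _unfmt(v: str):
    return None if v == "." else v


def read_calls(tsv_path: str) -> list[CallTableRow]:
    """Read a call table written by :func:`write_calls` (lossless)."""
    rows: list[CallTableRow] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise ValueError(f"unexpected call-table header in {tsv_path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            d = dict(zip(CALL_COLUMNS, f))
            rows.append(CallTableRow(
                chrom=d["chrom"], start=int(d["start"]), end=int(d["end"]),
                gene_id=d["gene_id"], n_left=int(d["n_left"]),
                n_right=int(d["n_right"]),
                exons_hit=tuple(int(x) for x in d["exons_hit"].split(","))
                if d["exons_hit"] != "." else (),
                samples=tuple(d["samples"].split(","))
                if d["samples"] != "." else (),
                filter_status=d["filter_status"],
                bp5=int(d["bp5"]) if d["bp5"] != "." else None,
                bp3=int(d["bp3"]) if d["bp3"] != "." else None,
                tsd_seq=_unfmt(d["tsd_seq"]),
                polyA_len=int(d["polyA_len"]),
                en_motif=_unfmt(d["en_motif"]),
                junctions=tuple(d["junctions"].split(","))
                if d["junctions"] != "." else (),
            ))
    return rows


# ---------------------------------------------------------------------------
# deletions (VCF) and auxiliary tables
# ---------------------------------------------------------------------------

def read_deletions_vcf(path: str) -> list[tuple[str, int, int]]:
    """Extract deletion intervals (0-based half-open) from a VCF.

    Handles symbolic ``<DEL>`` records (via INFO/END) and explicit
    REF/ALT length differences; records without a resolvable span are
    skipped with a warning.
    """
    out: list[tuple[str, int, int]] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alts = rec.alts or ()
            symbolic = any(a in ("<DEL>",) for a in alts)
            indel_del = any(len(a) < len(rec.ref) for a in alts
                            if not a.startswith("<"))
            if not symbolic and not indel_del:
                log.debug("skipping non-deletion record at %s:%d",
                          rec.chrom, rec.pos)
                continue
            # POS anchors the padding base; deleted tract starts one past it
            start = rec.start + 1
            end = rec.stop
            if end <= start:
                log.warning("deletion at %s:%d has no resolvable span; "
                            "skipped", rec.chrom, rec.pos)
                continue
            out.append((rec.chrom, start, end))
    return out


def read_bed_intervals(path: str) -> list[tuple[str, int, int, str]]:
    """Plain BED reader: (chrom, start, end, name-or-empty)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else ""
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out


def read_sample_sheet(path: str) -> list[SampleInfo]:
    """TSV with columns sample_id, path, population, pair_id, tissue."""
    samples: list[SampleInfo] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample_id", "path"]
        for col in required:
            if col not in header:
                raise ValueError(f"sample sheet missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def get(col: str, default: str = "NA") -> str:
                return f[idx[col]] if col in idx and idx[col] < len(f) else default

            samples.append(SampleInfo(
                sample_id=get("sample_id"), path=get("path"),
                population=get("population"), pair_id=get("pair_id"),
                tissue=get("tissue")))
    seen = set()
    for s in samples:
        if s.sample_id in seen:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
    return samples
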