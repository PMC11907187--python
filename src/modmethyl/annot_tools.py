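"""Genomic interval arithmetic and annotation tables.

All coordinates inside the package are 1-based closed (SAM/tabix convention).
BED input (0-based half-open) is converted on read, as is the UCSC-style CpG
island table whose printed ``length`` equals ``end - start`` under a half-open
reading; the printed length field is preserved as metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str = "*"
    meta: tuple = field(default_factory=tuple)  # ordered (key, value) pairs

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def meta_dict(self) -> dict:
        return dict(self.meta)

    def with_meta(self, **kv) -> "GenomicInterval":
        merged = dict(self.meta)
        merged.update(kv)
        return GenomicInterval(
            self.chrom, self.start, self.end, self.strand, tuple(merged.items())
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ExonRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_id: str
    symbol: str


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    symbol: str

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.start,
            self.end,
            self.strand,
            (("gene_id", self.gene_id), ("symbol", self.symbol)),
        )


@dataclass(frozen=True)
class CgiRecord:
    """One CpG island with the UCSC per-island statistics."""

    chrom: str
    start: int  # 1-based closed (converted from source half-open)
    end: int
    length: int  # printed source length (end - start, half-open)
    cpg_num: int
    gc_num: int
    per_cpg: float
    per_gc: float
    obs_exp: float

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, "*")


EXON_COLUMNS = ["gene_id", "chr", "strand", "start", "end", "transcript_id", "symbol"]


def read_exons(path: str | Path) -> list[ExonRecord]:
    """Read the 7-column exon annotation table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    missing = set(EXON_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"exon table missing columns: {sorted(missing)}")
    return [
        ExonRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chr),
            strand=str(r.strand),
            start=int(r.start),
            end=int(r.end),
            transcript_id=str(r.transcript_id),
            symbol=str(r.symbol),
        )
        for r in df.itertuples(index=False)
    ]


def write_exons(exons: Sequence[ExonRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (e.gene_id, e.chrom, e.strand, e.start, e.end, e.transcript_id, e.symbol)
            for e in exons
        ],
        columns=EXON_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def exons_to_genes(exons: Sequence[ExonRecord]) -> list[GeneRecord]:
    """Collapse exon records to one span per gene (min start, max end).

    Every exon of a gene must share one chromosome and strand.
    """
    by_gene: dict[str, list[ExonRecord]] = {}
    for e in exons:
        by_gene.setdefault(e.gene_id, []).append(e)
    genes = []
    for gid, recs in by_gene.items():
        chroms = {r.chrom for r in recs}
        strands = {r.strand for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {gid} spans multiple chromosomes/strands: {chroms}, {strands}"
            )
        genes.append(
            GeneRecord(
                gene_id=gid,
                chrom=recs[0].chrom,
                strand=recs[0].strand,
                start=min(r.start for r in recs),
                end=max(r.end for r in recs),
                symbol=recs[0].symbol,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def promoters(
    gene: GeneRecord | GenomicInterval, upstream: int, downstream: int
) -> GenomicInterval:
    """Fixed window around the TSS, strand-aware.

    '+' strand: [start - upstream, start + downstream - 1];
    '-' strand: [end - downstream + 1, end + upstream].
    Width is always upstream + downstream unless truncated at position 1.
    """
    if upstream < 0 or downstream < 0:
        raise AnnotationError("upstream/downstream must be non-negative")
    iv = gene.interval() if isinstance(gene, GeneRecord) else gene
    if iv.strand == "-":
        start = iv.end - downstream + 1
        end = iv.end + upstream
    else:
        start = iv.start - upstream
        end = iv.start + downstream - 1
    if start < 1:
        warnings.warn(
            f"promoter window truncated at chromosome start for {iv.chrom}:{iv.start}",
            stacklevel=2,
        )
        start = 1
    return GenomicInterval(iv.chrom, start, max(start, end), iv.strand, iv.meta)


def overlap_intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersect-join: one row per overlapping (a_i, b_j) pair.

    The output range is the intersection; metadata is the union of both rows'
    metadata (b overrides a on key clashes). A range overlapping k features
    yields k rows. Output is ordered by (a index, b index), a stable order.
    """
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[1].start, t[0]))
    out: list[tuple[int, int, GenomicInterval]] = []
    for i, av in enumerate(a):
        for j, bv in by_chrom.get(av.chrom, []):
            if bv.start > av.end:
                break
            if bv.end < av.start:
                continue
            meta = dict(av.meta)
            meta.update(dict(bv.meta))
            out.append(
                (
                    i,
                    j,
                    GenomicInterval(
                        av.chrom,
                        max(av.start, bv.start),
                        min(av.end, bv.end),
                        av.strand if av.strand != "*" else bv.strand,
                        tuple(meta.items()),
                    ),
                )
            )
    out.sort(key=lambda t: (t[0], t[1]))
    return [iv for _, _, iv in out]


def cgi_stats(length: int, cpg_num: int, gc_num: int) -> tuple[float, float]:
    """Per-island CpG and GC percentages, reported to 1 decimal.

    per_cpg = 100 * 2 * cpg_num / length (each CpG covers two bases);
    per_gc = 100 * gc_num / length.
    """
    if length <= 0:
        raise AnnotationError("island length must be positive")
    if 2 * cpg_num > length or gc_num > length:
        raise AnnotationError("base counts exceed island length")
    per_cpg = round(100.0 * 2 * cpg_num / length, 1)
    per_gc = round(100.0 * gc_num / length, 1)
    return per_cpg, per_gc


def read_cgi(path: str | Path) -> list[CgiRecord]:
    """Read a CpG-island table (chr, start, end, length, cpgNum, gcNum, perCpg,
    perGc, obsExp). Source coordinates are half-open (length == end - start);
    converted to 1-based closed, preserving the printed length."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n.lower() in cols:
                return cols[n.lower()]
        raise AnnotationError(f"CGI table missing column {names[0]!r}")

    out = []
    for r in df.itertuples(index=False):
        d = r._asdict() if hasattr(r, "_asdict") else dict(zip(df.columns, r))
        start0 = int(d[col("start")])
        end = int(d[col("end")])
        out.append(
            CgiRecord(
                chrom=str(d[col("chr", "chrom")]),
                start=start0 + 1,
                end=end,
                length=int(d[col("length")]),
                cpg_num=int(d[col("cpgNum", "cpg_num")]),
                gc_num=int(d[col("gcNum", "gc_num")]),
                per_cpg=float(d[col("perCpg", "per_cpg")]),
                per_gc=float(d[col("perGc", "per_gc")]),
                obs_exp=float(d[col("obsExp", "obs_exp")]),
            )
        )
    return out


def write_cgi(records: Sequence[CgiRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                c.chrom,
                c.start - 1,  # back to the source half-open convention
                c.end,
                c.length,
                c.cpg_num,
                c.gc_num,
                c.per_cpg,
                c.per_gc,
                c.obs_exp,
            )
            for c in records
        ],
        columns=[
            "chr",
            "start",
            "end",
            "length",
            "cpgNum",
            "gcNum",
            "perCpg",
            "perGc",
            "obsExp",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+/BED6 reader; converts 0-based half-open to 1-based closed."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"BED line {ln}: fewer than 3 columns")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "*"
            meta = (("name", name),) if name else ()
            out.append(GenomicInterval(chrom, start0 + 1, end, strand, meta))
    return out
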