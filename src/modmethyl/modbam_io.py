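"""Decoding of per-read base-modification calls from modBAM MM/ML tags.

Nanopore (and PacBio) basecallers report base modifications as two optional
SAM tags: ``MM`` lists, per modification type, delta-encoded skip counts over
the canonical base in the *original* (basecalled) read orientation, and ``ML``
carries an 8-bit probability for each listed position. This module decodes
those tags, projects the read-space offsets onto reference coordinates through
the alignment CIGAR, and streams per-read, per-site :class:`ModCall` records
from indexed BAM files.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("modmethyl")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: modBAM probability bins: an 8-bit ML value q represents the interval
#: [q/256, (q+1)/256); its midpoint is the point estimate used throughout.
ML_PROB_MIN = 0.5 / 256.0
ML_PROB_MAX = 255.5 / 256.0


class ModBamError(ValueError):
    """Malformed MM/ML tag content or inconsistent alignment record."""


@dataclass(frozen=True)
class ModCall:
    """One per-read, per-site modification call projected to the reference.

    ``pos`` is the 1-based reference position of the modified base on the
    alignment strand of the read: for a reverse-strand read the 5mC sits on
    the bottom strand, i.e. at the reference G of the CpG, unless strand
    collapsing was requested at extraction.
    """

    sample: str
    read_id: str
    chrom: str
    pos: int
    strand: str
    prob: float
    mod_code: str


@dataclass(frozen=True)
class ModBamSpec:
    """A modBAM file paired with the sample identifier it belongs to."""

    path: str
    sample: str


@dataclass
class SampleSheet:
    """Sample annotation: one row per input file, `sample` and `group` required."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample", "group"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing required columns: {sorted(missing)}")
        if self.frame["sample"].duplicated().any():
            dup = self.frame.loc[self.frame["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample"].tolist()

    @property
    def groups(self) -> list[str]:
        return self.frame["group"].tolist()

    def group_of(self, sample: str) -> str:
        rows = self.frame.loc[self.frame["sample"] == sample, "group"]
        if rows.empty:
            raise KeyError(f"sample {sample!r} not in sample sheet")
        return rows.iloc[0]


# MM item header: canonical base, strand, one or more mod codes (letters) or a
# single numeric ChEBI code, optional '.'/'?' skip-mode flag.
_MM_ITEM_RE = re.compile(r"^([ACGTUN])([+-])((?:[a-zA-Z]+)|(?:\d+))([.?]?)$")


def _parse_mm_items(mm: str) -> list[tuple[str, str, list[str], str, list[int]]]:
    items = []
    for raw in mm.rstrip(";").split(";"):
        if not raw:
            continue
        head, *deltas_s = raw.split(",")
        m = _MM_ITEM_RE.match(head)
        if m is None:
            raise ModBamError(f"malformed MM tag item {head!r} in {mm!r}")
        base, strand, codes_s, mode = m.groups()
        codes = [codes_s] if codes_s.isdigit() else list(codes_s)
        try:
            deltas = [int(d) for d in deltas_s]
        except ValueError as exc:
            raise ModBamError(f"non-integer delta in MM item {raw!r}") from exc
        if any(d < 0 for d in deltas):
            raise ModBamError(f"negative delta in MM item {raw!r}")
        items.append((base, strand, codes, mode, deltas))
    return items


def decode_mm_ml(
    seq: str,
    mm: str,
    ml: Sequence[int],
    mod_code: str = "m",
) -> list[tuple[int, float, str]]:
    """Decode MM/ML tags into (read offset, probability, code) triples.

    ``seq`` is the read in its original basecalled orientation. Offsets are
    0-based positions of the canonical base within ``seq`` selected by the
    delta-skip encoding; probabilities are ML bin midpoints ``(q + 0.5)/256``.
    Only calls for ``mod_code`` are returned, but ML bookkeeping walks every
    listed modification so multi-code tags stay consistent.

    Canonical bases *not* listed in MM yield no call regardless of the
    skip-mode flag ('.' or '?'): the downstream store only represents assayed
    sites.
    """
    if not mm:
        if ml:
            raise ModBamError("empty MM tag but non-empty ML array")
        return []
    items = _parse_mm_items(mm)
    total = sum(len(deltas) * len(codes) for _, _, codes, _, deltas in items)
    if total != len(ml):
        raise ModBamError(
            f"ML length {len(ml)} does not match {total} calls implied by MM tag"
        )
    seq_u = seq.upper()
    out: list[tuple[int, float, str]] = []
    ml_idx = 0
    for base, strand, codes, _mode, deltas in items:
        if strand == "-":
            # Modification of the opposite-strand base; not produced by CpG
            # 5mC callers. Consume the ML block and skip.
            warnings.warn(
                f"skipping MM item with '-' strand for base {base}", stacklevel=2
            )
            ml_idx += len(deltas) * len(codes)
            continue
        base_positions = _canonical_positions(seq_u, base)
        cursor = -1
        for delta in deltas:
            target = cursor + delta + 1  # skip `delta` canonical bases
            if target >= len(base_positions):
                raise ModBamError(
                    f"MM delta walks past the last {base} in the read "
                    f"(needed occurrence {target + 1}, found {len(base_positions)})"
                )
            cursor = target
            offset = base_positions[target]
            for code in codes:
                q = ml[ml_idx]
                ml_idx += 1
                if not 0 <= q <= 255:
                    raise ModBamError(f"ML value {q} outside 8-bit range")
                if code == mod_code:
                    out.append((offset, (q + 0.5) / 256.0, code))
    return out


def _canonical_positions(seq_u: str, base: str) -> list[int]:
    if base == "N":
        return list(range(len(seq_u)))
    return [i for i, b in enumerate(seq_u) if b == base]


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def project_to_reference(
    offsets: Sequence[int],
    cigar: str,
    aln_start: int,
    is_reverse: bool = False,
    read_len: int | None = None,
) -> list[int | None]:
    """Map original-orientation read offsets to 1-based reference positions.

    Offsets falling in insertions or soft-clips map to ``None``. For a
    reverse-strand alignment an original-orientation offset ``k`` corresponds
    to stored-orientation offset ``read_len - 1 - k``.
    """
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ModBamError(f"unparseable CIGAR {cigar!r}")
    qlen = sum(int(n) for n, o in ops if o in _QUERY_OPS)
    if read_len is None:
        read_len = qlen
    elif qlen != read_len:
        raise ModBamError(
            f"CIGAR consumes {qlen} query bases but read length is {read_len}"
        )
    # ref position (1-based) for each stored-orientation query offset; None in
    # soft-clips and insertions.
    qpos_to_ref: list[int | None] = [None] * read_len
    q = 0
    r = aln_start
    for n_s, op in ops:
        n = int(n_s)
        if op in "M=X":
            for i in range(n):
                qpos_to_ref[q + i] = r + i
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H and P consume neither

    out: list[int | None] = []
    for k in offsets:
        if k < 0 or k >= read_len:
            raise ModBamError(f"read offset {k} out of bounds for length {read_len}")
        stored = read_len - 1 - k if is_reverse else k
        out.append(qpos_to_ref[stored])
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _get_mod_tags(aln: pysam.AlignedSegment) -> tuple[str, Sequence[int]] | None:
    mm = ml = None
    for tag in ("MM", "Mm"):
        if aln.has_tag(tag):
            mm = aln.get_tag(tag)
            break
    for tag in ("ML", "Ml"):
        if aln.has_tag(tag):
            ml = list(aln.get_tag(tag))
            break
    if mm is None or ml is None:
        return None
    return mm, ml


def extract_calls(
    bam: ModBamSpec,
    region: "GenomicInterval | None" = None,
    mod_code: str = "m",
    min_mapq: int = 0,
    collapse_strands: bool = False,
) -> Iterator[ModCall]:
    """Stream ModCalls from one modBAM file, optionally restricted to a region.

    Unmapped, secondary and supplementary records are skipped, as are records
    below ``min_mapq``. Primary records lacking MM/ML raise a warning and are
    skipped. With ``collapse_strands``, reverse-strand calls at a CpG are
    shifted by -1 onto the forward-strand C and reported with strand '+'.
    """
    with pysam.AlignmentFile(bam.path, "rb") as fh:
        if region is not None:
            if region.chrom not in fh.references:
                raise ModBamError(
                    f"region chromosome {region.chrom!r} absent from BAM header"
                )
            it = fh.fetch(region.chrom, region.start - 1, region.end)
        else:
            it = fh.fetch()
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            tags = _get_mod_tags(aln)
            if tags is None:
                warnings.warn(
                    f"read {aln.query_name} lacks MM/ML tags; skipped", stacklevel=2
                )
                continue
            mm, ml = tags
            stored_seq = aln.query_sequence
            if stored_seq is None:
                continue
            orig_seq = (
                reverse_complement(stored_seq) if aln.is_reverse else stored_seq
            )
            decoded = decode_mm_ml(orig_seq, mm, ml, mod_code=mod_code)
            if not decoded:
                continue
            offsets = [d[0] for d in decoded]
            positions = project_to_reference(
                offsets,
                aln.cigarstring,
                aln.reference_start + 1,
                is_reverse=aln.is_reverse,
                read_len=len(stored_seq),
            )
            strand = "-" if aln.is_reverse else "+"
            calls = []
            for (off, prob, code), pos in zip(decoded, positions):
                if pos is None:
                    continue  # insertion or soft-clip: no reference coordinate
                p, s = pos, strand
                if collapse_strands and strand == "-":
                    p, s = pos - 1, "+"
                calls.append(
                    ModCall(
                        sample=bam.sample,
                        read_id=aln.query_name,
                        chrom=aln.reference_name,
                        pos=p,
                        strand=s,
                        prob=prob,
                        mod_code=code,
                    )
                )
            calls.sort(key=lambda c: c.pos)
            yield from calls


def extract_all(
    bams: Sequence[ModBamSpec],
    region: "GenomicInterval | None" = None,
    mod_code: str = "m",
    min_mapq: int = 0,
    collapse_strands: bool = False,
) -> Iterator[ModCall]:
    """Chain :func:`extract_calls` across several sample BAMs."""
    for spec in bams:
        yield from extract_calls(
            spec,
            region=region,
            mod_code=mod_code,
            min_mapq=min_mapq,
            collapse_strands=collapse_strands,
        )
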