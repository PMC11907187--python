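"""Sorted, BGZF-compressed, tabix-indexed per-site methylation store.

Each row is a single CpG call from a single read: ``sample, chrom, pos,
strand, statistic, read_id``, with ``statistic`` the natural-log odds
ln(p/(1-p)) of modification, positive exactly when the modification
probability exceeds 0.5. Rows are globally sorted by (chrom, pos) —
chromosomes lexicographic — so the file can be streamed and tabix-queried.
"""

from __future__ import annotations

import heapq
import math
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .modbam_io import ModCall

#: rows buffered in memory before spilling a sorted run to disk
DEFAULT_CHUNK_ROWS = 500_000


class StoreError(ValueError):
    pass


@dataclass(frozen=True)
class StoreRecord:
    sample: str
    chrom: str
    pos: int  # 1-based
    strand: str
    statistic: float
    read_id: str

    @property
    def prob(self) -> float:
        return 1.0 / (1.0 + math.exp(-self.statistic))

    def to_row(self) -> str:
        return (
            f"{self.sample}\t{self.chrom}\t{self.pos}\t{self.strand}"
            f"\t{self.statistic:.4f}\t{self.read_id}"
        )

    @classmethod
    def from_row(cls, line: str) -> "StoreRecord":
        sample, chrom, pos, strand, stat, read_id = line.rstrip("\n").split("\t")
        return cls(sample, chrom, int(pos), strand, float(stat), read_id)


def statistic_from_prob(prob: float) -> float:
    """Natural-log odds of modification; > 0 iff prob > 0.5."""
    if not 0.0 < prob < 1.0:
        raise StoreError(f"probability {prob} outside open interval (0, 1)")
    return math.log(prob / (1.0 - prob))


def _sort_key(rec: StoreRecord) -> tuple:
    # ties broken by sample then read_id for byte-reproducible stores
    return (rec.chrom, rec.pos, rec.sample, rec.read_id)


class MethylStore:
    """Handle to a written store; supports region queries and full scans."""

    def __init__(self, path: str | Path):
        self.path = str(path)
        if not Path(self.path).exists():
            raise StoreError(f"store file {self.path} does not exist")

    def query_region(self, chrom: str, start: int, end: int) -> list[StoreRecord]:
        """Records with matching chrom and start <= pos <= end (1-based closed).

        An unknown chromosome yields an empty list, not an error.
        """
        if start > end:
            raise StoreError(f"query start {start} > end {end}")
        out = []
        with pysam.TabixFile(self.path) as tbx:
            if chrom not in tbx.contigs:
                return []
            for line in tbx.fetch(chrom, start - 1, end):
                out.append(StoreRecord.from_row(line))
        return out

    def __iter__(self) -> Iterator[StoreRecord]:
        with pysam.BGZFile(self.path) as fh:
            for raw in fh:
                line = raw.decode()
                if line.strip():
                    yield StoreRecord.from_row(line)

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self:
            seen.setdefault(rec.sample, None)
        return list(seen)


def write_store(
    calls: Iterable[ModCall],
    out_path: str | Path,
    chunk_rows: int = DEFAULT_CHUNK_ROWS,
) -> MethylStore:
    """Serialize calls to a sorted BGZF TSV with a tabix index.

    Input may be unsorted and multi-sample; an external merge-sort (sorted
    runs spilled to temporary files, then a heap merge) keeps memory bounded.
    An empty input produces a valid zero-row store.
    """
    out_path = Path(out_path)
    runs: list[Path] = []
    buf: list[StoreRecord] = []
    with tempfile.TemporaryDirectory(prefix="methylstore_") as tmpdir:

        def spill() -> None:
            buf.sort(key=_sort_key)
            run = Path(tmpdir) / f"run_{len(runs)}.tsv"
            with open(run, "w") as fh:
                fh.writelines(rec.to_row() + "\n" for rec in buf)
            runs.append(run)
            buf.clear()

        for call in calls:
            buf.append(
                StoreRecord(
                    sample=call.sample,
                    chrom=call.chrom,
                    pos=call.pos,
                    strand=call.strand,
                    statistic=statistic_from_prob(call.prob),
                    read_id=call.read_id,
                )
            )
            if len(buf) >= chunk_rows:
                spill()
        if buf:
            spill()

        plain = Path(tmpdir) / "merged.tsv"
        with open(plain, "w") as out:
            handles = [open(r) for r in runs]
            try:
                streams = (
                    ((_sort_key(StoreRecord.from_row(ln)), ln) for ln in fh)
                    for fh in handles
                )
                for _, line in heapq.merge(*streams):
                    out.write(line)
            finally:
                for fh in handles:
                    fh.close()

        if out_path.exists():
            out_path.unlink()
        pysam.tabix_compress(str(plain), str(out_path), force=True)
        pysam.tabix_index(
            str(out_path),
            seq_col=1,
            start_col=2,
            end_col=2,
            zerobased=False,
            force=True,
        )
    return MethylStore(out_path)
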