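"""Binarized methylation count matrices (BSseq-style M / coverage storage).

Per-read calls are binarized at modification probability 0.5 (statistic 0;
ties count as unmethylated) and tallied into two (site x sample) integer
matrices: M (methylated reads) and Cov (covering reads). Sites are keyed per
strand; strand collapsing, when wanted, happens upstream at extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annot_tools import GenomicInterval
from .methyl_store import MethylStore, StoreRecord
from .modbam_io import SampleSheet


class MatrixError(ValueError):
    pass


@dataclass
class SiteMatrix:
    """Methylated and coverage counts over (site, sample).

    ``sites`` has columns chrom, pos, strand, sorted genomically; sample order
    follows the sample sheet. 0 <= M <= Cov elementwise.
    """

    sites: pd.DataFrame
    samples: list[str]
    groups: list[str]
    M: np.ndarray
    Cov: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = self.M.shape
        assert self.Cov.shape == (n_sites, n_samples)
        assert len(self.sites) == n_sites
        assert len(self.samples) == n_samples == len(self.groups)
        if (self.M > self.Cov).any() or (self.M < 0).any():
            raise MatrixError("M must satisfy 0 <= M <= Cov elementwise")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group])

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[f"M_{s}"] = self.M[:, j]
            df[f"Cov_{s}"] = self.Cov[:, j]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class RegionMatrix:
    """M/Cov summed over the sites inside each region, per sample."""

    regions: list[GenomicInterval]
    samples: list[str]
    groups: list[str]
    M: np.ndarray
    Cov: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, s in enumerate(self.samples):
            df[f"M_{s}"] = self.M[:, j]
            df[f"Cov_{s}"] = self.Cov[:, j]
        df.to_csv(path, sep="\t", index=False)


def binarize_call(record: StoreRecord) -> bool:
    """True iff the call is methylated: statistic > 0, i.e. prob > 0.5.

    Exact ties (statistic == 0) count as unmethylated.
    """
    return record.statistic > 0.0


def build_site_matrix(store: MethylStore, sheet: SampleSheet) -> SiteMatrix:
    """Tally binarized calls into a SiteMatrix over all sites in the store."""
    samples = sheet.samples
    groups = sheet.groups
    col = {s: j for j, s in enumerate(samples)}
    counts: dict[tuple[str, int, str], np.ndarray] = {}
    for rec in store:
        if rec.sample not in col:
            raise MatrixError(f"store sample {rec.sample!r} missing from sample sheet")
        key = (rec.chrom, rec.pos, rec.strand)
        row = counts.get(key)
        if row is None:
            row = counts[key] = np.zeros(2 * len(samples), dtype=np.int64)
        j = col[rec.sample]
        row[2 * j + 1] += 1  # coverage
        if binarize_call(rec):
            row[2 * j] += 1  # methylated
    keys = sorted(counts)
    n = len(keys)
    M = np.zeros((n, len(samples)), dtype=np.int64)
    Cov = np.zeros((n, len(samples)), dtype=np.int64)
    for i, key in enumerate(keys):
        row = counts[key]
        M[i, :] = row[0::2]
        Cov[i, :] = row[1::2]
    sites = pd.DataFrame(keys, columns=["chrom", "pos", "strand"])
    return SiteMatrix(sites=sites, samples=samples, groups=groups, M=M, Cov=Cov)


def filter_low_coverage(sm: SiteMatrix) -> tuple[SiteMatrix, dict[str, float]]:
    """Drop sites where any group's samples all have zero coverage.

    Returns the retained matrix plus the proportions of flagged (dropped) and
    unflagged (kept) sites. Applying the filter twice is a no-op.
    """
    group_names = list(dict.fromkeys(sm.groups))
    if not group_names:
        raise MatrixError("no groups assigned")
    flagged = np.zeros(sm.n_sites, dtype=bool)
    for g in group_names:
        cols = sm.group_columns(g)
        flagged |= (sm.Cov[:, cols] == 0).all(axis=1)
    keep = ~flagged
    kept = SiteMatrix(
        sites=sm.sites.loc[keep].reset_index(drop=True),
        samples=sm.samples,
        groups=sm.groups,
        M=sm.M[keep],
        Cov=sm.Cov[keep],
    )
    n = max(sm.n_sites, 1)
    fractions = {
        "flagged": float(flagged.sum()) / n,
        "unflagged": float(keep.sum()) / n,
    }
    return kept, fractions


def region_counts(sm: SiteMatrix, regions: Sequence[GenomicInterval]) -> RegionMatrix:
    """Sum M/Cov over the sites inside each region (1-based closed).

    A site inside two overlapping regions contributes to both; a region with
    no sites gets 0/0.
    """
    n_regions = len(regions)
    M = np.zeros((n_regions, len(sm.samples)), dtype=np.int64)
    Cov = np.zeros_like(M)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in sm.sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = sm.sites["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], idx[order])
    for i, region in enumerate(regions):
        entry = by_chrom.get(region.chrom)
        if entry is None:
            continue
        pos, idx = entry
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="right")
        if hi > lo:
            rows = idx[lo:hi]
            M[i, :] = sm.M[rows].sum(axis=0)
            Cov[i, :] = sm.Cov[rows].sum(axis=0)
    return RegionMatrix(
        regions=list(regions), samples=sm.samples, groups=sm.groups, M=M, Cov=Cov
    )


def log_methy_ratio(M, Cov, prior: float = 2.0):
    """log2((M + prior) / (Cov - M + prior)); finite for all valid counts.

    The prior is the small offset that keeps empty and fully-methylated sites
    finite; an empty site (0/0) maps to exactly 0.
    """
    M = np.asarray(M, dtype=float)
    Cov = np.asarray(Cov, dtype=float)
    if prior <= 0:
        raise MatrixError("prior must be positive")
    if (M > Cov).any() or (M < 0).any():
        raise MatrixError("require 0 <= M <= Cov")
    return np.log2((M + prior) / (Cov - M + prior))
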