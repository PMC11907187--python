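"""Differentially methylated regions: import, a simplified caller, and
promoter association.

Serious DMR inference belongs to dedicated statistical packages; this module
provides (a) an importer for their region tables, (b) a deliberately simple
caller — smoothed pooled-proportion differences segmented into same-sign runs
and tested by whole-sample label permutation — useful as plumbing on data
where the effect is large, and (c) the promoter-window overlap step that turns
regions into candidate gene associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annot_tools import GeneRecord, GenomicInterval, overlap_intersect, promoters
from .count_matrices import SiteMatrix

DEFAULT_MIN_SITES = 20
DEFAULT_MAX_GAP = 1000
DEFAULT_EFFECT_CUTOFF = 0.1
DEFAULT_N_PERM = 200
DEFAULT_SMOOTH_SITES = 5
#: designs with at most this many distinct relabelings are enumerated exactly
EXHAUSTIVE_LIMIT = 1000


class DmrError(ValueError):
    pass


@dataclass(frozen=True)
class DMRecord:
    region: GenomicInterval
    n_sites: int
    area: float | None = None
    beta: float | None = None
    stat: float | None = None
    pval: float | None = None
    qval: float | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DmrError("n_sites must be >= 1")
        for p in (self.pval, self.qval):
            if p is not None and not 0.0 <= p <= 1.0:
                raise DmrError(f"p/q value {p} outside [0, 1]")


def import_dmrs(path: str | Path) -> list[DMRecord]:
    """Read a DMR table (TSV with chrom/start/end plus optional stat columns).

    Coordinates are taken as 1-based closed. Missing statistic fields are
    stored as None.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty and len(df.columns) == 0:
        return []
    cols = {c.lower(): c for c in df.columns}

    def get(row, *names, cast=float):
        for n in names:
            if n in cols:
                v = row[cols[n]]
                if pd.isna(v):
                    return None
                return cast(v)
        return None

    need = [n for n in ("start", "end") if n not in cols]
    chrom_col = cols.get("chrom") or cols.get("chr") or cols.get("seqnames")
    if need or chrom_col is None:
        raise DmrError(f"DMR table must have chrom/start/end columns, got {list(df.columns)}")
    out = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header line
        try:
            start = int(row[cols["start"]])
            end = int(row[cols["end"]])
            region = GenomicInterval(str(row[chrom_col]), start, end)
        except (ValueError, TypeError) as exc:
            raise DmrError(f"malformed coordinates on line {i}: {exc}") from exc
        n_sites = get(row, "n_sites", "l", cast=int)
        out.append(
            DMRecord(
                region=region,
                n_sites=n_sites if n_sites is not None else 1,
                area=get(row, "area"),
                beta=get(row, "beta"),
                stat=get(row, "stat"),
                pval=get(row, "pval", "p", "pvalue"),
                qval=get(row, "qval", "q", "fdr"),
            )
        )
    return out


def export_dmrs(dmrs: Sequence[DMRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [d.region.chrom for d in dmrs],
            "start": [d.region.start for d in dmrs],
            "end": [d.region.end for d in dmrs],
            "n_sites": [d.n_sites for d in dmrs],
            "area": [d.area for d in dmrs],
            "beta": [d.beta for d in dmrs],
            "stat": [d.stat for d in dmrs],
            "pval": [d.pval for d in dmrs],
            "qval": [d.qval for d in dmrs],
        }
    ).to_csv(path, sep="\t", index=False)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise DmrError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _pooled_diff(
    M: np.ndarray, Cov: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pooled-proportion difference (a - b) and a validity mask
    (both groups covered)."""
    ma = M[:, cols_a].sum(axis=1)
    ca = Cov[:, cols_a].sum(axis=1)
    mb = M[:, cols_b].sum(axis=1)
    cb = Cov[:, cols_b].sum(axis=1)
    ok = (ca > 0) & (cb > 0)
    diff = np.zeros(len(ma))
    diff[ok] = ma[ok] / ca[ok] - mb[ok] / cb[ok]
    return diff, ok


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) == 0:
        return values.astype(float)
    half = window // 2
    csum = np.cumsum(np.insert(values.astype(float), 0, 0.0))
    n = len(values)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _candidate_runs(
    smoothed: np.ndarray,
    valid: np.ndarray,
    pos: np.ndarray,
    min_sites: int,
    max_gap: int,
    effect_cutoff: float,
) -> list[tuple[int, int]]:
    """Maximal runs (index ranges, inclusive) of valid sites with same-sign
    smoothed difference beyond the cutoff and inter-site gaps <= max_gap."""
    runs = []
    start = None
    sign = 0
    prev_pos = None
    for i in range(len(smoothed)):
        s = 0
        if valid[i]:
            if smoothed[i] > effect_cutoff:
                s = 1
            elif smoothed[i] < -effect_cutoff:
                s = -1
        broken = (
            s == 0
            or s != sign
            or (prev_pos is not None and pos[i] - prev_pos > max_gap)
        )
        if start is not None and broken:
            if i - start >= min_sites:
                runs.append((start, i - 1))
            start = None
            sign = 0
        if s != 0 and start is None:
            start, sign = i, s
        prev_pos = pos[i] if valid[i] else prev_pos
    if start is not None and len(smoothed) - start >= min_sites:
        runs.append((start, len(smoothed) - 1))
    return runs


def _group_relabelings(groups: Sequence[str]) -> tuple[list[np.ndarray], str, str]:
    names = list(dict.fromkeys(groups))
    if len(names) != 2:
        raise DmrError(f"exactly 2 groups required, got {names}")
    a_name, b_name = names
    idx_a = [i for i, g in enumerate(groups) if g == a_name]
    idx_all = list(range(len(groups)))
    labelings = [np.array(c) for c in combinations(idx_all, len(idx_a))]
    return labelings, a_name, b_name


def call_dmrs(
    sm: SiteMatrix,
    min_sites: int = DEFAULT_MIN_SITES,
    max_gap: int = DEFAULT_MAX_GAP,
    effect_cutoff: float = DEFAULT_EFFECT_CUTOFF,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    smooth_sites: int = DEFAULT_SMOOTH_SITES,
) -> list[DMRecord]:
    """Simplified two-group DMR caller on a site matrix.

    Pooled per-site group proportion differences are smoothed (rolling mean
    over ``smooth_sites`` sites within a chromosome) and segmented into
    maximal same-sign runs beyond ``effect_cutoff`` with gaps <= ``max_gap``
    and at least ``min_sites`` sites. Each region's statistic is its area (sum
    of smoothed site differences); significance comes from whole-sample group
    relabelings: exhaustive when few exist, otherwise ``n_perm`` random draws.
    q-values are Benjamini-Hochberg adjusted. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise DmrError("n_perm must be >= 1")
    labelings, a_name, b_name = _group_relabelings(sm.groups)
    cols_a_obs = sm.group_columns(a_name)
    cols_b_obs = sm.group_columns(b_name)
    for g, cols in ((a_name, cols_a_obs), (b_name, cols_b_obs)):
        if len(cols) < 2:
            raise DmrError(f"group {g!r} needs >= 2 samples for permutation")

    chroms = sm.sites["chrom"].to_numpy()
    pos_all = sm.sites["pos"].to_numpy()
    candidates: list[tuple[np.ndarray, int, int]] = []  # (chrom row idx, run lo, run hi)
    regions_meta = []
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        pos = pos_all[rows]
        diff, ok = _pooled_diff(sm.M[rows], sm.Cov[rows], cols_a_obs, cols_b_obs)
        smoothed = _smooth(diff, smooth_sites)
        for lo, hi in _candidate_runs(smoothed, ok, pos, min_sites, max_gap, effect_cutoff):
            candidates.append((rows, lo, hi))
            area = float(smoothed[lo : hi + 1].sum())
            beta = float(diff[lo : hi + 1].mean())
            regions_meta.append(
                (
                    GenomicInterval(str(chrom), int(pos[lo]), int(pos[hi])),
                    hi - lo + 1,
                    area,
                    beta,
                )
            )
    if not candidates:
        return []

    # permutation null: re-derive each candidate region's |area| under group
    # relabelings of the whole sample columns
    all_idx = set(range(len(sm.samples)))
    if len(labelings) <= EXHAUSTIVE_LIMIT:
        perms = labelings
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(labelings), size=n_perm, replace=True)
        perms = [labelings[int(i)] for i in picks]
        exhaustive = False

    pvals = []
    for (rows, lo, hi), (region, n_sites, area, beta) in zip(candidates, regions_meta):
        Msub, Covsub = sm.M[rows], sm.Cov[rows]
        obs = abs(area)
        hits = 0
        for cols_a in perms:
            cols_b = np.array(sorted(all_idx - set(cols_a.tolist())))
            d, _ = _pooled_diff(Msub, Covsub, cols_a, cols_b)
            s = _smooth(d, smooth_sites)
            if abs(float(s[lo : hi + 1].sum())) >= obs - 1e-12:
                hits += 1
        if exhaustive:
            pvals.append(hits / len(perms))
        else:
            pvals.append((1 + hits) / (1 + len(perms)))
    qvals = bh_adjust(pvals)
    return [
        DMRecord(
            region=region,
            n_sites=n_sites,
            area=area,
            beta=beta,
            stat=area,
            pval=float(p),
            qval=float(q),
        )
        for (region, n_sites, area, beta), p, q in zip(regions_meta, pvals, qvals)
    ]


def dmr_gene_overlap(
    dmrs: Sequence[DMRecord],
    genes: Sequence[GeneRecord],
    upstream: int = 5000,
    downstream: int = 5000,
    q_cutoff: float | None = None,
) -> pd.DataFrame:
    """Associate DMRs with genes whose promoter window they overlap.

    Promoters are ``upstream``/``downstream`` windows around each gene's TSS;
    each overlapping (DMR, promoter) pair becomes one output row carrying the
    gene symbol and the DMR's coordinates and q-value. With ``q_cutoff``, rows
    are filtered to qval < q_cutoff (rows lacking a q-value are dropped).
    """
    dmr_ivs = [d.region.with_meta(qval=d.qval) for d in dmrs]
    prom_ivs = [
        promoters(g, upstream, downstream).with_meta(symbol=g.symbol, gene_id=g.gene_id)
        for g in genes
    ]
    rows = []
    for iv in overlap_intersect(dmr_ivs, prom_ivs):
        meta = iv.meta_dict
        qval = meta.get("qval")
        if q_cutoff is not None and (qval is None or not qval < q_cutoff):
            continue
        rows.append(
            {
                "symbol": meta.get("symbol"),
                "gene_id": meta.get("gene_id"),
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": "*",
                "qval": qval,
            }
        )
    return pd.DataFrame(
        rows, columns=["symbol", "gene_id", "chrom", "start", "end", "strand", "qval"]
    )
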