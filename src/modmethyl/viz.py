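"""Gene/region plot assembly and rendering.

A gene plot stacks three tracks: a rolling-smoothed per-group methylation
trend, a read-level heatmap in which non-overlapping reads share a row
(first-fit packing), and an exon/isoform track, with optional highlighted
regions (e.g. DMRs). The data assembly (:func:`gene_plot_data`) is separated
from rendering so plots are testable without a display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annot_tools import ExonRecord, GenomicInterval, exons_to_genes
from .methyl_store import MethylStore, StoreRecord
from .modbam_io import SampleSheet
from .profiles_mds import AggregateProfile, MdsResult, site_group_proportion

DEFAULT_GENE_FLANK_BP = 2000
DEFAULT_SMOOTH_WINDOW_BP = 2000
DEFAULT_HIGHLIGHT_COLOR = "#009E73"  # colorblind-safe green


class VizError(ValueError):
    pass


@dataclass
class ReadRow:
    """One packed heatmap row: non-overlapping read segments."""

    read_ids: list[str]
    spans: list[tuple[int, int]]
    sites: list[list[tuple[int, float]]]  # per segment: (pos, prob)


@dataclass
class GenePlotData:
    window: GenomicInterval
    trend: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (pos, smoothed)
    heatmap: dict[str, list[ReadRow]]  # group -> packed rows
    exon_track: dict[str, list[ExonRecord]]  # transcript_id -> exons in window
    highlights: list[GenomicInterval] = field(default_factory=list)
    title: str = ""


def pack_reads(spans: Sequence[tuple[int, int]]) -> list[int]:
    """First-fit greedy packing of read spans into non-overlapping rows.

    Spans are processed in order of start (ties by end, then input order);
    each goes to the lowest-numbered row whose rightmost end is strictly left
    of its start. Returns the row index per input span.
    """
    for s, e in spans:
        if s > e:
            raise VizError(f"span start {s} > end {e}")
    order = sorted(range(len(spans)), key=lambda i: (spans[i][0], spans[i][1], i))
    row_ends: list[int] = []
    rows = [0] * len(spans)
    for i in order:
        start, end = spans[i]
        for r, rend in enumerate(row_ends):
            if rend < start:
                rows[i] = r
                row_ends[r] = end
                break
        else:
            rows[i] = len(row_ends)
            row_ends.append(end)
    return rows


def trend_smooth(
    sites: Sequence[tuple[int, float]], window_bp: int
) -> list[tuple[int, float]]:
    """Centered rolling mean over all sites within +/- window_bp/2 of each
    position. Output is parallel to the (sorted) input."""
    if not sites:
        return []
    pos = np.array([p for p, _ in sites], dtype=float)
    val = np.array([v for _, v in sites], dtype=float)
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    csum = np.insert(np.cumsum(val), 0, 0.0)
    smoothed = np.clip((csum[hi] - csum[lo]) / (hi - lo), 0.0, 1.0)
    return [(int(p), float(v)) for p, v in zip(pos, smoothed)]


def _resolve_target(
    target: str | GenomicInterval, exons: Sequence[ExonRecord]
) -> tuple[GenomicInterval, str]:
    if isinstance(target, GenomicInterval):
        return target, f"{target.chrom}:{target.start}-{target.end}"
    genes = {g.symbol: g for g in exons_to_genes(exons)}
    if target not in genes:
        near = [s for s in genes if s.lower().startswith(target[:3].lower())]
        raise VizError(f"unknown gene symbol {target!r}; near matches: {sorted(near)[:5]}")
    g = genes[target]
    return g.interval(), target


def gene_plot_data(
    store: MethylStore,
    target: str | GenomicInterval,
    sheet: SampleSheet,
    exons: Sequence[ExonRecord] = (),
    flank_bp: int = DEFAULT_GENE_FLANK_BP,
    smooth_window_bp: int = DEFAULT_SMOOTH_WINDOW_BP,
    highlights: Sequence[GenomicInterval] = (),
) -> GenePlotData:
    """Assemble trend, packed read heatmap, exon track and highlights for a
    gene symbol or explicit region, over the region +/- flank_bp."""
    region, title = _resolve_target(target, exons)
    window = GenomicInterval(
        region.chrom, max(1, region.start - flank_bp), region.end + flank_bp, region.strand
    )
    records = store.query_region(window.chrom, window.start, window.end)
    group_of = dict(zip(sheet.samples, sheet.groups))
    groups = list(dict.fromkeys(sheet.groups))

    # group trend: pooled per-site proportions, rolling-smoothed along position
    by_site: dict[int, list[StoreRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.pos, []).append(rec)
    trend: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in groups:
        pts = []
        for pos in sorted(by_site):
            props = site_group_proportion(by_site[pos], group_of)
            if g in props:
                pts.append((pos, props[g]))
        sm = trend_smooth(pts, smooth_window_bp)
        trend[g] = (
            np.array([p for p, _ in sm], dtype=int),
            np.array([v for _, v in sm], dtype=float),
        )

    # heatmap: per group, per read spans and site probabilities, first-fit packed
    heatmap: dict[str, list[ReadRow]] = {}
    for g in groups:
        reads: dict[str, list[tuple[int, float]]] = {}
        for rec in records:
            if group_of[rec.sample] == g:
                reads.setdefault(rec.read_id, []).append((rec.pos, rec.prob))
        read_ids = sorted(reads)
        spans = []
        for rid in read_ids:
            sites = sorted(reads[rid])
            spans.append((sites[0][0], sites[-1][0]))
        rows_idx = pack_reads(spans)
        n_rows = max(rows_idx) + 1 if rows_idx else 0
        packed = [ReadRow(read_ids=[], spans=[], sites=[]) for _ in range(n_rows)]
        for rid, span, r in zip(read_ids, spans, rows_idx):
            packed[r].read_ids.append(rid)
            packed[r].spans.append(span)
            packed[r].sites.append(sorted(reads[rid]))
        heatmap[g] = packed

    exon_track: dict[str, list[ExonRecord]] = {}
    for e in exons:
        if e.chrom == window.chrom and e.start <= window.end and e.end >= window.start:
            exon_track.setdefault(e.transcript_id, []).append(e)

    clipped = [
        GenomicInterval(
            h.chrom, max(h.start, window.start), min(h.end, window.end), h.strand, h.meta
        )
        for h in highlights
        if h.overlaps(window)
    ]
    return GenePlotData(
        window=window,
        trend=trend,
        heatmap=heatmap,
        exon_track=exon_track,
        highlights=clipped,
        title=title,
    )


# ---------------------------------------------------------------- rendering


def render_gene_plot(
    data: GenePlotData,
    out_path: str | Path,
    highlight_color: str = DEFAULT_HIGHLIGHT_COLOR,
) -> None:
    """Render trend + heatmap + exon track to PNG/SVG."""
    groups = list(data.trend)
    n_heat = len(groups)
    fig, axes = plt.subplots(
        2 + n_heat,
        1,
        figsize=(10, 4 + 1.2 * n_heat),
        sharex=True,
        gridspec_kw={"height_ratios": [2] + [1] * n_heat + [1]},
    )
    ax_trend, *ax_heats, ax_exon = axes
    cmap = plt.get_cmap("coolwarm")
    for g in groups:
        pos, val = data.trend[g]
        if len(pos):
            ax_trend.plot(pos, val, label=g)
    ax_trend.set_ylim(-0.05, 1.05)
    ax_trend.set_ylabel("methylation")
    ax_trend.legend(loc="upper right", fontsize=8)
    ax_trend.set_title(data.title)

    for ax, g in zip(ax_heats, groups):
        for r, row in enumerate(data.heatmap[g]):
            for span, sites in zip(row.spans, row.sites):
                ax.plot(span, [r, r], color="0.8", lw=2, zorder=1)
                if sites:
                    xs = [p for p, _ in sites]
                    cs = [cmap(p) for _, p in sites]
                    ax.scatter(xs, [r] * len(xs), c=cs, s=6, zorder=2)
        ax.set_ylabel(g, fontsize=8)
        ax.invert_yaxis()

    for tid, tx_exons in data.exon_track.items():
        y = list(data.exon_track).index(tid)
        tx_exons = sorted(tx_exons, key=lambda e: e.start)
        ax_exon.plot(
            [tx_exons[0].start, tx_exons[-1].end], [y, y], color="k", lw=0.8, zorder=1
        )
        for e in tx_exons:
            ax_exon.add_patch(
                plt.Rectangle((e.start, y - 0.3), e.end - e.start + 1, 0.6, color="k")
            )
    ax_exon.set_ylim(-1, max(len(data.exon_track), 1))
    ax_exon.set_yticks([])
    ax_exon.set_xlabel(f"{data.window.chrom} position")

    for ax in axes:
        for h in data.highlights:
            ax.axvspan(h.start, h.end, color=highlight_color, alpha=0.25, zorder=0)
        ax.set_xlim(data.window.start, data.window.end)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def render_aggregate_profile(profile: AggregateProfile, out_path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    for g, vals in profile.smoothed.items():
        ax.plot(profile.bins, vals, label=g)
    for x in (0.0, 1.0):
        ax.axvline(x, color="0.8", lw=0.8)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel(
        f"relative position (width {profile.width_mean:.0f} ± {profile.width_sd:.0f} bp)"
    )
    ax.set_ylabel("mean methylation proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def render_mds(
    mds: MdsResult, groups: Sequence[str] | None, out_path: str | Path
) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    if groups is None:
        groups = ["all"] * len(mds.samples)
    for g in dict.fromkeys(groups):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        ax.scatter(mds.coords[idx, 0], mds.coords[idx, 1], label=g)
    for i, s in enumerate(mds.samples):
        ax.annotate(s, mds.coords[i], fontsize=7)
    v1, v2 = mds.variance_explained
    ax.set_xlabel(f"dim 1 ({100 * v1:.0f}%)")
    ax.set_ylabel(f"dim 2 ({100 * v2:.0f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
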