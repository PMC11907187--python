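"""Region-relative aggregate methylation profiles and MDS sample embedding.

Aggregate profiles map every assayed site to a coordinate relative to its
region — body linearly on [0, 1], flanks on [-f, 0) and (1, 1+f] — pool each
group's read calls into a per-site methylation proportion, and average those
proportions per group in fixed bins of relative position. The MDS embedding
is classical (Torgerson) scaling of Euclidean distances between samples over
the most variable log-methylation-ratio features, the standard quick look at
sample-level methylation structure.
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

DEFAULT_FLANK_BP = 2000
DEFAULT_REL_FLANK = 0.33
DEFAULT_N_BINS = 100
DEFAULT_SMOOTH_BINS = 5
DEFAULT_TOP_K = 500
PROB_THRESHOLD = 0.5


class ProfileError(ValueError):
    pass


@dataclass
class AggregateProfile:
    """Binned mean methylation proportion per group across relative positions."""

    bins: np.ndarray  # bin centers, strictly increasing over [-f, 1+f]
    means: dict[str, np.ndarray]  # group -> per-bin mean proportion (nan if empty)
    smoothed: dict[str, np.ndarray]  # rolling-mean smoothed trend per group
    n_obs: dict[str, np.ndarray]  # group -> observations per bin
    width_mean: float
    width_sd: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center": self.bins})
        for g in self.means:
            df[f"mean_{g}"] = self.means[g]
            df[f"smoothed_{g}"] = self.smoothed[g]
            df[f"n_{g}"] = self.n_obs[g]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MdsResult:
    samples: list[str]
    coords: np.ndarray  # (n_samples, 2)
    variance_explained: tuple[float, float]
    features_used: int
    distance: str = "euclidean/sqrt(k)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "dim1": self.coords[:, 0],
                "dim2": self.coords[:, 1],
            }
        )


def site_group_proportion(
    records: Sequence[StoreRecord],
    group_of: dict[str, str],
    threshold: float = PROB_THRESHOLD,
) -> dict[str, float]:
    """Pooled methylation proportion per group at one site.

    Read calls are pooled across a group's samples (methylated / total), so a
    deeply covered sample weighs more than a shallow one; groups with no calls
    at the site are omitted.
    """
    if not records:
        raise ProfileError("no records at site")
    meth: dict[str, int] = {}
    tot: dict[str, int] = {}
    for rec in records:
        g = group_of[rec.sample]
        tot[g] = tot.get(g, 0) + 1
        if rec.prob > threshold:
            meth[g] = meth.get(g, 0) + 1
    return {g: meth.get(g, 0) / n for g, n in tot.items()}


def relative_position(
    pos: int, region: GenomicInterval, flank_bp: int, rel_flank: float = DEFAULT_REL_FLANK
) -> float | None:
    """Map a genomic position to a region-relative coordinate.

    Body maps linearly to [0, 1]; the upstream flank to [-f, 0) and the
    downstream flank to (1, 1+f]. '-' strand regions are mirrored so 0 is
    always the 5' end. Positions outside the flanked window return None.
    """
    if pos < region.start - flank_bp or pos > region.end + flank_bp:
        return None
    width = region.width
    if pos < region.start:
        rel = -rel_flank * (region.start - pos) / flank_bp if flank_bp else None
    elif pos > region.end:
        rel = 1.0 + rel_flank * (pos - region.end) / flank_bp if flank_bp else None
    else:
        rel = (pos - region.start) / (width - 1) if width > 1 else 0.5
    if rel is None:
        return None
    if region.strand == "-":
        rel = 1.0 - rel
    return rel


def aggregate_profile(
    store: MethylStore,
    regions: Sequence[GenomicInterval],
    sheet: SampleSheet,
    flank_bp: int = DEFAULT_FLANK_BP,
    n_bins: int = DEFAULT_N_BINS,
    rel_flank: float = DEFAULT_REL_FLANK,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
    threshold: float = PROB_THRESHOLD,
) -> AggregateProfile:
    """Group-mean methylation proportion in bins of region-relative position.

    Every (region, site) pair contributes the site's pooled group proportion
    at its relative coordinate; bins average those observations per group.
    """
    if not regions:
        raise ProfileError("no regions supplied")
    group_of = dict(zip(sheet.samples, sheet.groups))
    groups = list(dict.fromkeys(sheet.groups))
    lo, hi = -rel_flank, 1.0 + rel_flank
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sums = {g: np.zeros(n_bins) for g in groups}
    counts = {g: np.zeros(n_bins, dtype=np.int64) for g in groups}
    total_obs = 0
    for region in regions:
        recs = store.query_region(
            region.chrom, max(1, region.start - flank_bp), region.end + flank_bp
        )
        by_site: dict[tuple[int, str], list[StoreRecord]] = {}
        for rec in recs:
            by_site.setdefault((rec.pos, rec.strand), []).append(rec)
        for (pos, _strand), site_recs in by_site.items():
            rel = relative_position(pos, region, flank_bp, rel_flank)
            if rel is None:
                continue
            props = site_group_proportion(site_recs, group_of, threshold)
            b = min(int((rel - lo) / (hi - lo) * n_bins), n_bins - 1)
            for g, p in props.items():
                sums[g][b] += p
                counts[g][b] += 1
                total_obs += 1
    if total_obs == 0:
        raise ProfileError("no methylation observations fall inside the regions")
    means = {}
    smoothed = {}
    for g in groups:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), np.nan)
        means[g] = mean
        smoothed[g] = _rolling_mean_nan(mean, smooth_bins)
    widths = np.array([r.width for r in regions], dtype=float)
    return AggregateProfile(
        bins=centers,
        means=means,
        smoothed=smoothed,
        n_obs=counts,
        width_mean=float(widths.mean()),
        width_sd=float(widths.std(ddof=1)) if len(widths) > 1 else 0.0,
    )


def _rolling_mean_nan(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean ignoring NaNs; window clipped at the edges."""
    n = len(x)
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        seg = x[max(0, i - half) : min(n, i + half + 1)]
        good = ~np.isnan(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def mds_coords(
    lmr: np.ndarray | pd.DataFrame,
    samples: Sequence[str] | None = None,
    top_k: int = DEFAULT_TOP_K,
) -> MdsResult:
    """Classical (Torgerson) MDS of samples over the most variable features.

    Rows of ``lmr`` are features (regions or sites), columns are samples. The
    ``top_k`` rows by cross-sample variance are kept; pairwise Euclidean
    sample distances are scaled by 1/sqrt(k) (a root-mean-square difference),
    double-centered and eigendecomposed. The embedding is unique only up to
    axis sign and rotation.
    """
    if isinstance(lmr, pd.DataFrame):
        if samples is None:
            samples = list(lmr.columns)
        lmr = lmr.to_numpy(dtype=float)
    else:
        lmr = np.asarray(lmr, dtype=float)
    n_feat, n_samples = lmr.shape
    if samples is None:
        samples = [f"sample_{j}" for j in range(n_samples)]
    if n_samples < 3:
        raise ProfileError("MDS needs at least 3 samples")
    if top_k < 2:
        raise ProfileError("top_k must be at least 2")
    k = min(top_k, n_feat)
    variances = lmr.var(axis=1, ddof=1)
    top = np.argsort(variances, kind="stable")[::-1][:k]
    X = lmr[np.sort(top)].T  # (samples, features)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2)) / np.sqrt(k)
    D2 = D**2
    J = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:2], 0.0, None)
    coords = evecs[:, :2] * np.sqrt(lam)
    pos_sum = np.clip(evals, 0.0, None).sum()
    ve = tuple(float(l / pos_sum) if pos_sum > 0 else 0.0 for l in lam)
    return MdsResult(
        samples=list(samples),
        coords=coords,
        variance_explained=ve,  # type: ignore[arg-type]
        features_used=k,
    )
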