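"""Synthetic modBAM datasets with planted methylation structure.

The generator emulates a haplotyped two-group, three-replicate CpG-methylation
experiment: a toy chromosome with planted CpG sites, per-group piecewise
site-methylation probabilities (e.g. one differentially methylated window on a
hypermethylated background), error-free pre-aligned long reads on both
strands, and per-call emitted probabilities drawn from modes concentrated near
0 and 1, 8-bit quantized exactly as an ML tag stores them. Everything is
reproducible from the seed, and the ground truth (per-read planted calls,
per-site tallies, DMR windows) is returned alongside the files so downstream
stages can be checked bit-for-bit.

It does not model basecalling error, alignment artefacts, mapping ambiguity or
non-CpG methylation.
"""

from __future__ import annotations

import json
from array import array
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm

from .annot_tools import CgiRecord, ExonRecord, GenomicInterval, write_cgi, write_exons
from .count_matrices import SiteMatrix
from .modbam_io import ModBamSpec, SampleSheet, reverse_complement


class SimError(ValueError):
    pass


@dataclass
class MethylProfile:
    """Piecewise per-site methylation probability for one group: ``windows``
    are (start, end, p) on 1-based closed coordinates, else ``background``."""

    background: float
    windows: list[tuple[int, int, float]] = field(default_factory=list)

    def prob_at(self, pos: int) -> float:
        for start, end, p in self.windows:
            if start <= pos <= end:
                return p
        return self.background


@dataclass
class SimConfig:
    chrom: str = "chrS"
    genome_length: int = 20_000
    cpg_spacing: int = 50  # mean distance between planted CpG sites
    samples: tuple[tuple[str, str], ...] = (
        ("s1_mat", "mat"),
        ("s1_pat", "pat"),
        ("s2_mat", "mat"),
        ("s2_pat", "pat"),
        ("s3_mat", "mat"),
        ("s3_pat", "pat"),
    )
    profiles: dict[str, MethylProfile] = field(
        default_factory=lambda: {
            "mat": MethylProfile(background=0.75, windows=[(8000, 9500, 0.9)]),
            "pat": MethylProfile(background=0.75, windows=[(8000, 9500, 0.3)]),
        }
    )
    dmr_windows: tuple[tuple[int, int], ...] = ((8000, 9500),)
    reads_per_sample: int = 120
    read_length_mean: int = 3000
    read_length_sd: int = 500
    frac_reverse: float = 0.5
    high_mode: float = 0.95
    low_mode: float = 0.05
    mode_sd: float = 0.03  # noise knob; widen to make 0.5-binarization lossy
    mod_code: str = "m"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample < 1:
            raise SimError("reads_per_sample must be >= 1")
        for g, prof in self.profiles.items():
            probs = [prof.background] + [p for _, _, p in prof.windows]
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise SimError(f"profile probabilities for {g!r} outside [0, 1]")
        groups = {g for _, g in self.samples}
        missing = groups - set(self.profiles)
        if missing:
            raise SimError(f"no methylation profile for groups {sorted(missing)}")


@dataclass
class PlantedCall:
    read_id: str
    chrom: str
    pos: int  # 1-based, on the call's strand (reverse calls at the CpG G)
    strand: str
    prob: float  # 8-bit-quantized bin midpoint, exactly as ML stores it


@dataclass
class GroundTruth:
    cpg_positions: list[int]  # forward-strand C of each CpG
    site_probs: dict[str, dict[int, float]]  # group -> pos -> true p
    dmr_intervals: list[GenomicInterval]
    calls: dict[str, list[PlantedCall]]  # sample -> planted calls

    def total_calls(self) -> int:
        return sum(len(v) for v in self.calls.values())

    def site_tallies(self) -> dict[tuple[str, str, int, str], tuple[int, int]]:
        """(sample, chrom, pos, strand) -> (methylated, coverage), binarized
        at probability 0.5 with ties unmethylated."""
        out: dict[tuple[str, str, int, str], list[int]] = {}
        for sample, calls in self.calls.items():
            for c in calls:
                key = (sample, c.chrom, c.pos, c.strand)
                entry = out.setdefault(key, [0, 0])
                entry[1] += 1
                if c.prob > 0.5:
                    entry[0] += 1
        return {k: (m, cov) for k, (m, cov) in out.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cpg_positions": self.cpg_positions,
            "site_probs": {g: {str(k): v for k, v in d.items()} for g, d in self.site_probs.items()},
            "dmr_intervals": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                for iv in self.dmr_intervals
            ],
            "calls": {
                s: [asdict(c) for c in calls] for s, calls in self.calls.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SimResult:
    bams: list[ModBamSpec]
    sheet: SampleSheet
    sheet_path: Path
    exons_path: Path
    cgi_path: Path
    truth: GroundTruth
    truth_path: Path


def _make_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Toy chromosome whose only CpG dinucleotides are the planted ones."""
    L = cfg.genome_length
    seq = list(rng.choice(list("ACGT"), size=L))
    for i in range(L - 1):  # break accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    n_sites = max(1, (L - 200) // cfg.cpg_spacing)
    raw = 100 + np.sort(rng.choice(np.arange(0, L - 200, 2), size=n_sites, replace=False))
    positions: list[int] = []
    last = -10
    for p0 in raw.tolist():
        if p0 - last < 2:
            continue
        positions.append(p0 + 1)  # to 1-based
        seq[p0] = "C"
        seq[p0 + 1] = "G"
        last = p0
    return "".join(seq), positions


def _quantize(p: float) -> tuple[int, float]:
    q = int(np.clip(int(p * 256), 0, 255))
    return q, (q + 0.5) / 256.0


def _emit_prob(state: bool, cfg: SimConfig, rng: np.random.Generator) -> tuple[int, float]:
    mode = cfg.high_mode if state else cfg.low_mode
    p = float(np.clip(rng.normal(mode, cfg.mode_sd), 1e-4, 1 - 1e-4))
    return _quantize(p)


def effective_methylation_prob(p: float, cfg: SimConfig) -> float:
    """Probability an emitted call binarizes as methylated given true state
    probability p (accounts for emission-mode crossover past 0.5)."""
    hi_cross = float(norm.sf(0.5, loc=cfg.high_mode, scale=cfg.mode_sd))
    lo_cross = float(norm.sf(0.5, loc=cfg.low_mode, scale=cfg.mode_sd))
    return p * hi_cross + (1 - p) * lo_cross


def _mm_ml_for_read(
    orig_seq: str, call_offsets: Sequence[int], quals: Sequence[int], mod_code: str
) -> tuple[str, list[int]]:
    """Delta-encode calls (offsets in original orientation) over the canonical
    C positions of the original-orientation sequence."""
    c_positions = [i for i, b in enumerate(orig_seq) if b == "C"]
    index_of = {p: i for i, p in enumerate(c_positions)}
    deltas = []
    prev = -1
    for off in call_offsets:
        i = index_of[off]
        deltas.append(i - prev - 1)
        prev = i
    if not deltas:
        return "", []
    mm = f"C+{mod_code}?," + ",".join(str(d) for d in deltas) + ";"
    return mm, list(quals)


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Write one indexed modBAM per sample plus sample sheet, exon and CGI
    annotation and the ground truth; returns handles to everything."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, cpg_positions = _make_genome(cfg, rng)
    L = cfg.genome_length
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": cfg.chrom, "LN": L}]}
    cpg_arr = np.array(cpg_positions)

    truth_calls: dict[str, list[PlantedCall]] = {}
    bam_specs: list[ModBamSpec] = []
    for sample, group in cfg.samples:
        prof = cfg.profiles[group]
        reads = []
        calls: list[PlantedCall] = []
        for k in range(cfg.reads_per_sample):
            length = int(np.clip(rng.normal(cfg.read_length_mean, cfg.read_length_sd), 200, L))
            start = int(rng.integers(1, max(2, L - length + 1)))  # 1-based
            end = start + length - 1
            is_reverse = bool(rng.random() < cfg.frac_reverse)
            read_id = f"{sample}_read{k:05d}"
            seg = genome[start - 1 : end]
            # CpGs fully inside the read (need both C and G covered)
            lo = np.searchsorted(cpg_arr, start, side="left")
            hi = np.searchsorted(cpg_arr, end - 1, side="right")
            site_pos = cpg_arr[lo:hi]
            orig_seq = reverse_complement(seg) if is_reverse else seg
            entries = []  # (orig offset, q, prob, ref pos of the called C)
            for p in site_pos.tolist():
                state = bool(rng.random() < prof.prob_at(p))
                q, prob = _emit_prob(state, cfg, rng)
                if is_reverse:
                    call_ref = p + 1  # bottom-strand C sits at the forward G
                    off = end - call_ref
                else:
                    call_ref = p
                    off = p - start
                entries.append((off, q, prob, call_ref))
            entries.sort(key=lambda t: t[0])
            mm, ml = _mm_ml_for_read(
                orig_seq, [e[0] for e in entries], [e[1] for e in entries], cfg.mod_code
            )
            strand = "-" if is_reverse else "+"
            for off, q, prob, call_ref in entries:
                calls.append(PlantedCall(read_id, cfg.chrom, call_ref, strand, prob))
            reads.append((start, read_id, seg, is_reverse, mm, ml))
        reads.sort(key=lambda r: (r[0], r[1]))
        path = out_dir / f"{sample}.bam"
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for start, read_id, seg, is_reverse, mm, ml in reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = read_id
                a.query_sequence = seg
                a.flag = 16 if is_reverse else 0
                a.reference_id = 0
                a.reference_start = start - 1
                a.mapping_quality = 60
                a.cigartuples = [(0, len(seg))]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seg))
                if mm:
                    a.set_tag("MM", mm, value_type="Z")
                    a.set_tag("ML", array("B", ml))
                bam.write(a)
        pysam.index(str(path))
        bam_specs.append(ModBamSpec(path=str(path), sample=sample))
        truth_calls[sample] = calls

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": [s for s, _ in cfg.samples],
                "group": [g for _, g in cfg.samples],
            }
        )
    )
    sheet_path = out_dir / "sample_anno.tsv"
    sheet.to_tsv(sheet_path)

    exons_path = out_dir / "exons.tsv"
    write_exons(_toy_exons(cfg), exons_path)
    cgi_path = out_dir / "cgi.tsv"
    write_cgi(_toy_cgis(cfg, genome), cgi_path)

    truth = GroundTruth(
        cpg_positions=cpg_positions,
        site_probs={
            g: {p: cfg.profiles[g].prob_at(p) for p in cpg_positions}
            for g in cfg.profiles
        },
        dmr_intervals=[
            GenomicInterval(cfg.chrom, s, e) for s, e in cfg.dmr_windows
        ],
        calls=truth_calls,
    )
    truth_path = out_dir / "ground_truth.json"
    truth.to_json(truth_path)
    return SimResult(
        bams=bam_specs,
        sheet=sheet,
        sheet_path=sheet_path,
        exons_path=exons_path,
        cgi_path=cgi_path,
        truth=truth,
        truth_path=truth_path,
    )


def _toy_exons(cfg: SimConfig) -> list[ExonRecord]:
    """Three toy genes: one whose promoter covers the first DMR window."""
    dmr_start = cfg.dmr_windows[0][0] if cfg.dmr_windows else cfg.genome_length // 2
    L = cfg.genome_length
    genes = [
        ("g1", "+", dmr_start, min(dmr_start + 4000, L - 100), "geneA"),
        ("g2", "-", max(1, L // 10), max(2, L // 10 + 2500), "geneB"),
        ("g3", "+", max(1, 7 * L // 10), min(7 * L // 10 + 3000, L - 1), "geneC"),
    ]
    exons = []
    for gid, strand, start, end, symbol in genes:
        mid = (start + end) // 2
        exons.append(ExonRecord(gid, cfg.chrom, strand, start, mid - 100, f"{gid}_t1", symbol))
        exons.append(ExonRecord(gid, cfg.chrom, strand, mid + 100, end, f"{gid}_t1", symbol))
    return exons


def _toy_cgis(cfg: SimConfig, genome: str) -> list[CgiRecord]:
    out = []
    for start, end in cfg.dmr_windows or ((1, min(1000, cfg.genome_length)),):
        seg = genome[start - 1 : end]
        length = end - (start - 1)  # source half-open convention
        cpg_num = seg.count("CG")
        gc_num = seg.count("G") + seg.count("C")
        per_cpg = round(100.0 * 2 * cpg_num / length, 1)
        per_gc = round(100.0 * gc_num / length, 1)
        out.append(
            CgiRecord(
                chrom=cfg.chrom,
                start=start,
                end=end,
                length=length,
                cpg_num=cpg_num,
                gc_num=gc_num,
                per_cpg=per_cpg,
                per_gc=per_gc,
                obs_exp=1.0,
            )
        )
    return out


def simulate_site_matrix(
    cfg: SimConfig, depth: float = 20.0, seed: int | None = None
) -> SiteMatrix:
    """Fast path: draw a SiteMatrix directly from the planted profiles.

    Coverage per (site, sample) is Poisson(depth); methylated counts are
    Binomial(coverage, p_eff) with p_eff the planted probability corrected for
    emission-mode crossover at the 0.5 threshold. Equivalent in distribution
    to the full read-level pipeline at matched depth, and orders of magnitude
    faster — used for power/null studies.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome_rng = np.random.default_rng(cfg.seed)
    _, cpg_positions = _make_genome(cfg, genome_rng)
    samples = [s for s, _ in cfg.samples]
    groups = [g for _, g in cfg.samples]
    n, m = len(cpg_positions), len(samples)
    Cov = rng.poisson(depth, size=(n, m)).astype(np.int64)
    M = np.zeros_like(Cov)
    for j, g in enumerate(groups):
        prof = cfg.profiles[g]
        p_eff = np.array(
            [effective_methylation_prob(prof.prob_at(p), cfg) for p in cpg_positions]
        )
        M[:, j] = rng.binomial(Cov[:, j], p_eff)
    sites = pd.DataFrame(
        {
            "chrom": [cfg.chrom] * n,
            "pos": cpg_positions,
            "strand": ["+"] * n,
        }
    )
    return SiteMatrix(sites=sites, samples=samples, groups=groups, M=M, Cov=Cov)
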