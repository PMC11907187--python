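"""Interval arithmetic, annotation records, overlap joins, CGI statistics."""

import numpy as np
import pytest

from modmethyl import (
    ExonRecord,
    GeneRecord,
    GenomicInterval,
    cgi_stats,
    exons_to_genes,
    overlap_intersect,
    promoters,
    read_bed,
    read_cgi,
    read_exons,
    write_cgi,
    write_exons,
)
from modmethyl.annot_tools import AnnotationError, CgiRecord


def exon(gene, start, end, strand="-", chrom="chr7", tx="t1", symbol="sym"):
    return ExonRecord(gene, chrom, strand, start, end, tx, symbol)


class TestExonsToGenes:
    def test_multi_exon_gene_span(self):
        # olfactory-receptor-like gene with exons across two transcripts
        exons = [
            exon("100009609", 84935565, 84941088, tx="60883", symbol="Vmn2r65"),
            exon("100009609", 84943141, 84943264, tx="60883", symbol="Vmn2r65"),
            exon("100009609", 84963816, 84964115, tx="60883", symbol="Vmn2r65"),
            exon("100009609", 84935565, 84941088, tx="60884", symbol="Vmn2r65"),
        ]
        genes = exons_to_genes(exons)
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end, g.symbol) == (84935565, 84964115, "Vmn2r65")

    def test_single_exon_gene(self):
        g = exons_to_genes([exon("g", 10, 20)])[0]
        assert (g.start, g.end) == (10, 20)

    def test_matches_min_max_oracle_and_count(self):
        rng = np.random.default_rng(8)
        exons = []
        for gid in range(30):
            chrom = f"chr{rng.integers(1, 4)}"
            strand = "+-"[rng.integers(0, 2)]
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(1, 10**6))
                exons.append(
                    exon(f"g{gid}", s, s + int(rng.integers(1, 5000)), strand, chrom)
                )
        genes = exons_to_genes(exons)
        assert len(genes) == len({e.gene_id for e in exons})
        for g in genes:
            mine = [e for e in exons if e.gene_id == g.gene_id]
            assert g.start == min(e.start for e in mine)
            assert g.end == max(e.end for e in mine)
        assert genes == sorted(genes, key=lambda g: (g.chrom, g.start))

    def test_gene_on_two_chromosomes_raises(self):
        with pytest.raises(AnnotationError):
            exons_to_genes([exon("g", 1, 10, chrom="chr1"), exon("g", 1, 10, chrom="chr2")])

    def test_tsv_round_trip(self, tmp_path):
        exons = [exon("g1", 5, 50, "+", "chr1")]
        path = tmp_path / "exons.tsv"
        write_exons(exons, path)
        assert read_exons(path) == exons


class TestPromoters:
    def test_forward_window(self):
        g = GeneRecord("g", "chr1", "+", 10000, 50000, "s")
        iv = promoters(g, 5000, 5000)
        assert (iv.start, iv.end) == (5000, 14999)

    def test_reverse_window(self):
        g = GeneRecord("g", "chr1", "-", 1000, 20000, "s")
        iv = promoters(g, 5000, 5000)
        assert (iv.start, iv.end) == (15001, 25000)

    def test_tss_only(self):
        g = GeneRecord("g", "chr1", "+", 100, 500, "s")
        iv = promoters(g, 0, 1)
        assert (iv.start, iv.end) == (100, 100)

    def test_width_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            start = int(rng.integers(50_000, 10**6))
            g = GeneRecord("g", "chr1", "+-"[rng.integers(0, 2)], start, start + 1000, "s")
            up, down = int(rng.integers(0, 9000)), int(rng.integers(1, 9000))
            iv = promoters(g, up, down)
            assert iv.width == up + down

    def test_truncation_at_chromosome_start_warns(self):
        g = GeneRecord("g", "chr1", "+", 100, 500, "s")
        with pytest.warns(UserWarning, match="truncated"):
            iv = promoters(g, 5000, 5000)
        assert iv.start == 1


class TestOverlapIntersect:
    def test_basic_intersection(self):
        out = overlap_intersect(
            [GenomicInterval("c", 100, 200)], [GenomicInterval("c", 150, 300)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(150, 200)]

    def test_disjoint_empty(self):
        assert overlap_intersect(
            [GenomicInterval("c", 1, 10)], [GenomicInterval("c", 20, 30)]
        ) == []

    def test_one_range_two_features_yields_two_rows(self):
        # one DMR spanning two gene promoters: one row per gene, same range
        dmr = GenomicInterval("chr7", 6727308, 6731838, meta=(("qval", 0.0402),))
        proms = [
            GenomicInterval("chr7", 6725000, 6735000, meta=(("symbol", "Peg3"),)),
            GenomicInterval("chr7", 6724000, 6734000, meta=(("symbol", "Usp29"),)),
        ]
        out = overlap_intersect([dmr], proms)
        assert len(out) == 2
        assert {(iv.start, iv.end) for iv in out} == {(6727308, 6731838)}
        assert {iv.meta_dict["symbol"] for iv in out} == {"Peg3", "Usp29"}
        assert all(iv.meta_dict["qval"] == 0.0402 for iv in out)

    def test_matches_all_pairs_brute_force_oracle(self):
        rng = np.random.default_rng(13)

        def random_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(1, 5000))
                out.append(
                    GenomicInterval(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(0, 400)))
                )
            return out

        a, b = random_set(150), random_set(200)
        got = {
            (iv.chrom, iv.start, iv.end)
            for iv in overlap_intersect(a, b)
        }
        expected = set()
        for av in a:
            for bv in b:
                if av.overlaps(bv):
                    expected.add((av.chrom, max(av.start, bv.start), min(av.end, bv.end)))
        assert got == expected
        # row count must match the number of overlapping pairs, not unique ranges
        n_pairs = sum(av.overlaps(bv) for av in a for bv in b)
        assert len(overlap_intersect(a, b)) == n_pairs


class TestCgi:
    @pytest.mark.parametrize(
        "length,cpg,gc,per_cpg,per_gc",
        [
            (236, 22, 147, 18.6, 62.3),
            (375, 28, 249, 14.9, 66.4),
            (247, 27, 152, 21.9, 61.5),
        ],
    )
    def test_stats_match_reference_islands(self, length, cpg, gc, per_cpg, per_gc):
        got_cpg, got_gc = cgi_stats(length, cpg, gc)
        assert got_cpg == per_cpg
        assert got_gc == per_gc

    def test_saturated_island(self):
        assert cgi_stats(6, 3, 6) == (100.0, 100.0)

    def test_counts_exceeding_length_raise(self):
        with pytest.raises(AnnotationError):
            cgi_stats(10, 6, 5)

    def test_reader_converts_half_open_and_preserves_length(self, tmp_path):
        rec = CgiRecord("chr7", 3181032, 3181267, 236, 22, 147, 18.6, 62.3, 1.0)
        path = tmp_path / "cgi.tsv"
        write_cgi([rec], path)
        back = read_cgi(path)[0]
        assert back == rec
        assert back.end - (back.start - 1) == back.length


class TestBed:
    def test_bed_converts_to_one_based_closed(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t100\tx\t0\t-\nchr2\t50\t60\n")
        ivs = read_bed(path)
        assert (ivs[0].start, ivs[0].end, ivs[0].strand) == (1, 100, "-")
        assert (ivs[1].start, ivs[1].end) == (51, 60)
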