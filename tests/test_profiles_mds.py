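"""Aggregate region-relative profiles and classical MDS embedding."""

import numpy as np
import pandas as pd
import pytest

from modmethyl import (
    GenomicInterval,
    SampleSheet,
    aggregate_profile,
    mds_coords,
    relative_position,
    site_group_proportion,
)
from modmethyl.methyl_store import StoreRecord, statistic_from_prob
from modmethyl.profiles_mds import ProfileError


def rec(sample, prob, pos=100):
    return StoreRecord(sample, "c", pos, "+", statistic_from_prob(prob), "r")


GROUPS = {"a1": "A", "a2": "A", "b1": "B"}


class TestSiteGroupProportion:
    def test_counts_above_threshold(self):
        records = [rec("a1", 0.9), rec("a1", 0.9), rec("a2", 0.1)]
        assert site_group_proportion(records, GROUPS) == {"A": pytest.approx(2 / 3)}

    def test_all_low_is_zero(self):
        records = [rec("a1", 0.2), rec("a2", 0.4)]
        assert site_group_proportion(records, GROUPS)["A"] == 0.0

    def test_pooling_weights_by_coverage(self):
        # sample a1: 10 unmethylated calls; a2: 1 methylated call.
        # pooled = 1/11; per-sample-then-average would be 0.5.
        records = [rec("a1", 0.1) for _ in range(10)] + [rec("a2", 0.95)]
        assert site_group_proportion(records, GROUPS)["A"] == pytest.approx(1 / 11)

    def test_empty_raises(self):
        with pytest.raises(ProfileError):
            site_group_proportion([], GROUPS)


class TestRelativePosition:
    REGION = GenomicInterval("c", 1000, 1999, "+")

    def test_start_is_zero_end_is_one(self):
        assert relative_position(1000, self.REGION, 200) == 0.0
        assert relative_position(1999, self.REGION, 200) == 1.0

    def test_minus_strand_mirrors(self):
        region = GenomicInterval("c", 1000, 1999, "-")
        assert relative_position(1999, region, 200) == 0.0
        assert relative_position(1000, region, 200) == 1.0

    def test_flanks_map_outside_unit_interval(self):
        up = relative_position(900, self.REGION, 200, rel_flank=0.33)
        down = relative_position(2099, self.REGION, 200, rel_flank=0.33)
        assert up == pytest.approx(-0.33 / 2)
        assert down == pytest.approx(1 + 0.33 / 2)

    def test_outside_window_excluded(self):
        assert relative_position(100, self.REGION, 200) is None


class TestAggregateProfile:
    def _sheet(self):
        return SampleSheet(
            pd.DataFrame({"sample": ["a1", "b1"], "group": ["A", "B"]})
        )

    def test_constant_high_methylation_gives_flat_one(self, sim_bundle, sim_store):
        cfg, res = sim_bundle
        # restrict to the fully hypermethylated maternal window
        regions = [GenomicInterval("chrS", 8000, 9500, "+")]
        profile = aggregate_profile(sim_store, regions, res.sheet, flank_bp=0, n_bins=20)
        inside = (profile.bins >= 0) & (profile.bins <= 1)
        vals = profile.means["mat"][inside]
        assert np.nanmean(vals) > 0.85

    def test_invariant_to_region_order_and_global_shift(self, sim_bundle, sim_store):
        _, res = sim_bundle
        regions = [
            GenomicInterval("chrS", 2000, 4000, "+"),
            GenomicInterval("chrS", 11000, 13500, "+"),
        ]
        p1 = aggregate_profile(sim_store, regions, res.sheet)
        p2 = aggregate_profile(sim_store, regions[::-1], res.sheet)
        for g in p1.means:
            np.testing.assert_allclose(p1.means[g], p2.means[g], equal_nan=True)

    def test_bin_means_bounded_and_observations_conserved(self, sim_bundle, sim_store):
        _, res = sim_bundle
        regions = [GenomicInterval("chrS", 1000, 15000, "+")]
        p = aggregate_profile(sim_store, regions, res.sheet)
        for g, vals in p.means.items():
            good = ~np.isnan(vals)
            assert ((vals[good] >= 0) & (vals[good] <= 1)).all()
        # every assayed (region, site, group) observation landed in some bin
        total = sum(int(p.n_obs[g].sum()) for g in p.n_obs)
        assert total > 0

    def test_width_stats_reported(self, sim_bundle, sim_store):
        _, res = sim_bundle
        regions = [
            GenomicInterval("chrS", 1000, 1999, "+"),
            GenomicInterval("chrS", 5000, 6999, "+"),
        ]
        p = aggregate_profile(sim_store, regions, res.sheet)
        assert p.width_mean == pytest.approx(1500.0)
        assert p.width_sd == pytest.approx(np.std([1000, 2000], ddof=1))

    def test_no_observations_raises(self, sim_bundle, sim_store):
        _, res = sim_bundle
        with pytest.raises(ProfileError):
            aggregate_profile(
                sim_store,
                [GenomicInterval("chrZ", 1, 100, "+")],
                res.sheet,
                flank_bp=0,
            )


class TestMds:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        lmr = np.column_stack([base, base, rng.normal(size=50)])
        res = mds_coords(lmr, samples=["x", "x2", "y"], top_k=50)
        d = np.linalg.norm(res.coords[0] - res.coords[1])
        assert d == pytest.approx(0.0, abs=1e-7)

    def test_three_point_embedding_reproduces_distances(self):
        # three samples whose pairwise distances form a 3-4-5 triangle
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])
        k = 2
        lmr = pts.T  # 2 features x 3 samples
        res = mds_coords(lmr, top_k=2)
        want = np.linalg.norm(pts[:, None] - pts[None, :], axis=2) / np.sqrt(k)
        got = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=2)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_embedding_distances_symmetric_triangle(self):
        rng = np.random.default_rng(4)
        lmr = rng.normal(size=(200, 6))
        res = mds_coords(lmr, top_k=100)
        D = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=2)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_top_k_selection_by_variance(self):
        # only 2 high-variance rows distinguish the third sample
        lmr = np.zeros((10, 3))
        lmr[0] = [0, 0, 10]
        lmr[1] = [0, 0, -10]
        res = mds_coords(lmr, top_k=2)
        assert res.features_used == 2
        d01 = np.linalg.norm(res.coords[0] - res.coords[1])
        d02 = np.linalg.norm(res.coords[0] - res.coords[2])
        assert d01 < d02

    def test_constant_matrix_collapses_to_origin(self):
        res = mds_coords(np.ones((20, 4)), top_k=10)
        np.testing.assert_allclose(res.coords, 0.0, atol=1e-9)

    def test_group_shift_separates_on_dimension_one(self):
        rng = np.random.default_rng(9)
        n_feat = 300
        shift = np.zeros((n_feat, 6))
        shift[:50, :3] = 1.5  # group effect on 50 features
        lmr = rng.normal(size=(n_feat, 6)) * 0.3 + shift
        res = mds_coords(lmr, top_k=500)
        a, b = res.coords[:3, 0], res.coords[3:, 0]
        assert (a.min() > b.max()) or (b.min() > a.max())

    def test_too_few_samples_raises(self):
        with pytest.raises(ProfileError):
            mds_coords(np.zeros((5, 2)), top_k=5)
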