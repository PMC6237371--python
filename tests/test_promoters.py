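"""Promoter construction, active-region post-processing, enrichment, profiles."""

import numpy as np
import pandas as pd
import pytest

from vlincscope import (
    EnrichmentResult,
    GenomeLayout,
    IntervalSet,
    PromoterParams,
    PromoterSet,
    active_regions,
    candidate_promoters,
    density_profile,
    expression_stratified_overlap,
    overlap_enrichment,
    refine_promoters,
)
from vlincscope.discovery import VlincCall

from conftest import active_regions_oracle


PARAMS = PromoterParams(active_states=frozenset({"Active"}), n_shuffles=200)


class TestCandidatePromoters:
    LAYOUT = GenomeLayout([("chr1", 1_000_000, True)])

    def test_plus_strand_window(self):
        pset = candidate_promoters([VlincCall("chr1", 100_000, 160_000, "+", "v1")], self.LAYOUT)
        r = pset.df.loc["v1"]
        assert (r["cand_start"], r["cand_end"]) == (90_000, 110_000)

    def test_minus_strand_uses_end_coordinate(self):
        pset = candidate_promoters([VlincCall("chr1", 100_000, 160_000, "-", "v1")], self.LAYOUT)
        r = pset.df.loc["v1"]
        assert (r["cand_start"], r["cand_end"]) == (150_000, 170_000)

    def test_clipped_at_chromosome_start(self):
        pset = candidate_promoters([VlincCall("chr1", 3_000, 60_000, "+", "v1")], self.LAYOUT)
        r = pset.df.loc["v1"]
        assert (r["cand_start"], r["cand_end"]) == (0, 13_000)

    def test_unstranded_call_rejected(self):
        iset = IntervalSet.from_records([("chr1", 0, 60_000, ".", "v1")])
        with pytest.raises(ValueError, match="strand"):
            candidate_promoters(iset, self.LAYOUT)


class TestActiveRegions:
    def seg(self, *recs):
        return IntervalSet.from_records([(c, s, e, ".", lab, None) for c, s, e, lab in recs])

    def test_merge_and_keep(self):
        # two 300 bp active segments 800 bp apart -> one 1400 bp region, kept
        states = self.seg(("chr1", 1_000, 1_300, "Active"), ("chr1", 2_100, 2_400, "Active"))
        out = active_regions(states, PARAMS)
        assert out.to_dataframe()[["start", "end"]].values.tolist() == [[1_000, 2_400]]

    def test_short_isolated_segment_dropped(self):
        states = self.seg(("chr1", 0, 399, "Active"))
        assert len(active_regions(states, PARAMS)) == 0
        states400 = self.seg(("chr1", 0, 400, "Active"))
        assert len(active_regions(states400, PARAMS)) == 1  # ">= 400 bp" inclusive

    def test_no_active_states_empty(self):
        states = self.seg(("chr1", 0, 5_000, "Quiescent"))
        assert len(active_regions(states, PARAMS)) == 0

    def test_unknown_label_with_vocabulary(self):
        states = self.seg(("chr1", 0, 1_000, "Weird"))
        with pytest.raises(ValueError, match="Weird"):
            active_regions(states, PARAMS, known_states={"Active", "Quiescent"})

    def test_matches_filter_merge_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(40):
            n = rng.integers(1, 25)
            recs = []
            for _ in range(n):
                s = int(rng.integers(0, 18_000))
                recs.append(("chr1", s, s + int(rng.integers(50, 1_200)),
                             str(rng.choice(["Active", "Quiescent", "Enh"]))))
            # oracle needs disjoint input bases: merge overlapping same-label first is
            # unnecessary since masks are boolean
            states = self.seg(*recs)
            got = [(r.chrom, r.start, r.end) for r in active_regions(states, PARAMS)]
            exp = active_regions_oracle(recs, {"Active"}, PARAMS.state_merge_gap,
                                        PARAMS.min_active_len, 20_000)
            assert sorted(got) == exp


class TestRefinePromoters:
    def pset(self):
        df = pd.DataFrame({"chrom": ["chr1"], "strand": ["+"],
                           "cand_start": [10_000], "cand_end": [30_000]}, index=["v1"])
        return PromoterSet(df)

    def test_longest_overlapping_region_wins(self):
        active = IntervalSet.from_records([("chr1", 12_000, 12_500, "."),
                                           ("chr1", 20_000, 22_000, ".")])
        out = refine_promoters(self.pset(), active)
        assert (out.df.loc["v1", "ref_start"], out.df.loc["v1", "ref_end"]) == (20_000, 22_000)
        assert out.n_refined == 1 and out.refined_fraction == 1.0

    def test_no_overlap_stays_unrefined(self):
        active = IntervalSet.from_records([("chr1", 500_000, 502_000, ".")])
        out = refine_promoters(self.pset(), active)
        assert pd.isna(out.df.loc["v1", "ref_start"]) and out.n_refined == 0

    def test_equal_length_tie_leftmost(self):
        active = IntervalSet.from_records([("chr1", 25_000, 26_000, "."),
                                           ("chr1", 15_000, 16_000, ".")])
        out = refine_promoters(self.pset(), active)
        assert out.df.loc["v1", "ref_start"] == 15_000


class TestOverlapEnrichment:
    LAYOUT = GenomeLayout([("chr1", 2_000_000, True)])

    def make_pset(self, n, width=20_000, seed=0):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 2_000_000 - width, size=n)
        df = pd.DataFrame({"chrom": "chr1", "strand": "+",
                           "cand_start": starts, "cand_end": starts + width},
                          index=[f"p{i}" for i in range(n)])
        return PromoterSet(df)

    def test_genome_wide_active_gives_fold_one(self):
        pset = self.make_pset(10)
        active = IntervalSet.from_records([("chr1", 0, 2_000_000, ".")])
        res = overlap_enrichment(pset, active, self.LAYOUT, PARAMS, seed=1)
        assert res.n_obs_overlap == 10 and res.fold == 1.0
        assert np.all(res.random_overlap_counts == 10)

    def test_empty_active_gives_zero_fold_with_warning(self):
        pset = self.make_pset(5)
        with pytest.warns(UserWarning, match="fold"):
            res = overlap_enrichment(pset, IntervalSet.empty(), self.LAYOUT, PARAMS, seed=1)
        assert res.n_obs_overlap == 0 and res.fold == 0.0

    def test_worked_example_from_counts(self):
        # 79/256 observed vs mean random 36/256: 2.2-fold enrichment
        res = EnrichmentResult.from_counts(79, 36.0, 256)
        assert res.fold == pytest.approx(79 / 36)
        assert round(res.fold, 1) == 2.2
        assert res.fisher_table == [[79, 177], [36, 220]]
        assert 100 * res.obs_fraction == pytest.approx(30.859375)
        assert 100 * res.mean_random_fraction == pytest.approx(14.0625)

    def test_permutation_p_bounds(self):
        pset = self.make_pset(20, seed=2)
        active = IntervalSet.from_records([("chr1", 0, 1_000_000, ".")])
        res = overlap_enrichment(pset, active, self.LAYOUT, PARAMS, seed=3)
        assert 1 / (PARAMS.n_shuffles + 1) <= res.permutation_p <= 1.0
        assert res.fisher_table[0][0] + res.fisher_table[0][1] == res.n


class TestStratifiedOverlap:
    def test_bin_sizes_8x32(self):
        rng = np.random.default_rng(30)
        starts = np.arange(256) * 30_000
        df = pd.DataFrame({"chrom": "chr1", "strand": "+",
                           "cand_start": starts, "cand_end": starts + 20_000},
                          index=[f"p{i}" for i in range(256)])
        pset = PromoterSet(df)
        expr = pd.Series(rng.random(256), index=pset.ids)
        out = expression_stratified_overlap(pset, IntervalSet.empty(), expr, n_bins=8)
        assert list(out["n"]) == [32] * 8

    def test_all_overlapping_gives_unit_fractions(self):
        df = pd.DataFrame({"chrom": "chr1", "strand": "+",
                           "cand_start": [0, 50_000], "cand_end": [20_000, 70_000]},
                          index=["a", "b"])
        pset = PromoterSet(df)
        active = IntervalSet.from_records([("chr1", 0, 100_000, ".")])
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        out = expression_stratified_overlap(pset, active, expr, n_bins=2)
        assert (out["fraction"] == 1.0).all()

    def test_highest_expression_is_bin_one(self):
        df = pd.DataFrame({"chrom": "chr1", "strand": "+",
                           "cand_start": [0, 50_000], "cand_end": [20_000, 70_000]},
                          index=["low", "high"])
        pset = PromoterSet(df)
        active = IntervalSet.from_records([("chr1", 55_000, 56_000, ".")])  # hits 'high' only
        expr = pd.Series({"low": 1.0, "high": 9.0})
        out = expression_stratified_overlap(pset, active, expr, n_bins=2)
        assert out.loc[out["bin"] == 1, "fraction"].iloc[0] == 1.0
        assert out.loc[out["bin"] == 2, "fraction"].iloc[0] == 0.0

    def test_missing_expression_raises(self):
        df = pd.DataFrame({"chrom": "chr1", "strand": "+",
                           "cand_start": [0], "cand_end": [20_000]}, index=["a"])
        with pytest.raises(ValueError, match="missing expression"):
            expression_stratified_overlap(PromoterSet(df), IntervalSet.empty(),
                                          pd.Series(dtype=float))


class TestDensityProfile:
    LAYOUT = GenomeLayout([("chr1", 1_000_000, True)])

    def regions(self):
        return IntervalSet.from_records([("chr1", 490_000, 510_000, "+", "r1")])

    def uniform_track(self, depth=3):
        from vlincscope import CoverageTrack

        return CoverageTrack({("chr1", "."): (np.array([0]), np.array([1_000_000]),
                                              np.array([depth]))}, layout=self.LAYOUT)

    def test_uniform_signal_flat_profile(self):
        mat = density_profile(self.uniform_track(), self.regions(), window=10_000, n_bins=20)
        vals = mat.iloc[0].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_center_concentration(self):
        from vlincscope import CoverageTrack

        track = CoverageTrack({("chr1", "."): (np.array([499_500]), np.array([500_500]),
                                               np.array([50]))}, layout=self.LAYOUT)
        mat = density_profile(track, self.regions(), window=10_000, n_bins=20)
        vals = mat.iloc[0].to_numpy()
        assert vals.argmax() in (9, 10)
        assert vals[0] == 0 and vals[-1] == 0

    def test_scale_invariance(self):
        m1 = density_profile(self.uniform_track(3), self.regions(), window=10_000, n_bins=10)
        m2 = density_profile(self.uniform_track(6), self.regions(), window=10_000, n_bins=10)
        assert np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_out_of_genome_bins_missing(self):
        regions = IntervalSet.from_records([("chr1", 0, 2_000, "+", "edge")])
        mat = density_profile(self.uniform_track(), regions, window=10_000, n_bins=10)
        assert np.isnan(mat.iloc[0, 0]) and not np.isnan(mat.iloc[0, -1])
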