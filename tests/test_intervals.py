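"""Interval algebra: merging, subtraction, distance filtering, shuffling, BED I/O."""

import numpy as np
import pytest

from vlincscope import (
    GenomeLayout,
    IntervalSet,
    StrandedInterval,
    distance_filter,
    merge_within,
    read_bed,
    shuffle_intervals,
    subtract,
    write_bed,
)

from conftest import mask_from_intervals, merge_mask_oracle, runs_from_mask


def iv(*args):
    return IntervalSet.from_records(list(args))


class TestMergeWithin:
    @pytest.mark.parametrize(
        "intervals,gap,expected",
        [
            # gap 350 < 500: united
            ([("chr1", 0, 100, "+"), ("chr1", 450, 500, "+")], 500, [(0, 500)]),
            # gap exactly 500: NOT merged ("less than" is strict)
            ([("chr1", 0, 100, "+"), ("chr1", 600, 700, "+")], 500, [(0, 100), (600, 700)]),
            ([("chr1", 0, 100, "+")], 500, [(0, 100)]),
        ],
    )
    def test_gap_rule(self, intervals, gap, expected):
        got = merge_within(iv(*intervals), gap).to_dataframe()
        assert list(zip(got["start"], got["end"])) == expected

    def test_strand_and_chrom_separation(self):
        s = iv(("chr1", 0, 100, "+"), ("chr1", 150, 200, "-"), ("chr2", 120, 130, "+"))
        got = merge_within(s, 10_000)
        assert len(got) == 3

    def test_idempotent_and_monotone_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(1, 30)
            starts = rng.integers(0, 5_000, size=n)
            lens = rng.integers(1, 400, size=n)
            s = iv(*[("chr1", int(a), int(a + l), "+") for a, l in zip(starts, lens)])
            prev_count, prev_bases = None, None
            for gap in (1, 10, 100, 1000):
                m = merge_within(s, gap)
                again = merge_within(m, gap)
                assert m.to_dataframe().equals(again.to_dataframe())  # idempotent
                if prev_count is not None:
                    assert len(m) <= prev_count
                    assert m.total_length >= prev_bases
                prev_count, prev_bases = len(m), m.total_length

    def test_matches_mask_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 20)
            starts = rng.integers(0, 2_000, size=n)
            lens = rng.integers(1, 300, size=n)
            gap = int(rng.integers(1, 500))
            s = iv(*[("chr1", int(a), int(a + l), "+") for a, l in zip(starts, lens)])
            m = mask_from_intervals(s, "chr1", "+", 3_000)
            got = merge_within(s, gap).to_dataframe()
            assert list(zip(got["start"], got["end"])) == merge_mask_oracle(m, gap)


class TestSubtract:
    def test_splits_interval(self):
        got = subtract(iv(("chr1", 0, 100, "+")), iv(("chr1", 50, 60, "+"))).to_dataframe()
        assert list(zip(got["start"], got["end"])) == [(0, 50), (60, 100)]

    def test_opposite_strand_untouched(self):
        a = iv(("chr1", 0, 100, "+"))
        got = subtract(a, iv(("chr1", 50, 60, "-")))
        assert got.to_dataframe()[["start", "end"]].values.tolist() == [[0, 100]]

    def test_empty_b_is_identity(self):
        a = iv(("chr1", 0, 100, "+"), ("chr2", 5, 10, "-"))
        assert subtract(a, IntervalSet.empty()).total_length == a.total_length

    def test_strand_agnostic_mode(self):
        a = iv(("chr1", 0, 100, "+"))
        got = subtract(a, iv(("chr1", 50, 60, "-")), strand_aware=False).to_dataframe()
        assert list(zip(got["start"], got["end"])) == [(0, 50), (60, 100)]

    def test_base_count_conservation_vs_mask_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            def rand_set():
                n = rng.integers(0, 15)
                return iv(*[("chr1", int(a), int(a + l), "+")
                            for a, l in zip(rng.integers(0, 2_000, size=n),
                                            rng.integers(1, 300, size=n))])
            a, b = rand_set(), rand_set()
            ma = mask_from_intervals(a, "chr1", "+", 3_000)
            mb = mask_from_intervals(b, "chr1", "+", 3_000)
            got = subtract(a, b)
            # result bases == a and not b (as a base set)
            mg = np.zeros(3_000, dtype=bool)
            for r in got:
                mg[r.start:r.end] = True
            assert np.array_equal(mg, ma & ~mb)


class TestDistanceFilter:
    def test_gap_arithmetic(self):
        a = iv(("chr1", 100_000, 160_000, "+"))
        genes = iv(("chr1", 80_000, 89_999, "-"))  # gap 10001 >= 10000
        assert len(distance_filter(a, genes, 10_000)) == 1
        genes2 = iv(("chr1", 80_000, 90_001, "-"))  # gap 9999 < 10000
        assert len(distance_filter(a, genes2, 10_000)) == 0

    def test_overlap_counts_as_zero(self):
        a = iv(("chr1", 100, 200, "+"))
        assert len(distance_filter(a, iv(("chr1", 150, 160, "+")), 1)) == 0

    def test_empty_b_keeps_all(self):
        a = iv(("chr1", 0, 10, "+"), ("chr2", 0, 10, "-"))
        assert len(distance_filter(a, IntervalSet.empty(), 10_000)) == 2

    def test_strand_is_ignored(self):
        a = iv(("chr1", 50_000, 120_000, "+"))
        genes = iv(("chr1", 45_000, 48_000, "+"))  # same strand, gap 2000
        assert len(distance_filter(a, genes, 10_000)) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            na, nb = rng.integers(1, 10, size=2)
            a = iv(*[("chr1", int(s), int(s + l), "+")
                     for s, l in zip(rng.integers(0, 5_000, na), rng.integers(1, 500, na))])
            b = iv(*[("chr1", int(s), int(s + l), "-")
                     for s, l in zip(rng.integers(0, 5_000, nb), rng.integers(1, 500, nb))])
            d = int(rng.integers(1, 1_000))
            got = {(r.start, r.end) for r in distance_filter(a, b, d)}
            exp = set()
            for x in a:
                gaps = [max(y.start - x.end, x.start - y.end, 0) for y in b]
                if all(g >= d for g in gaps):
                    exp.add((x.start, x.end))
            assert got == exp


class TestShuffle:
    def test_zero_reps(self, toy_layout):
        assert shuffle_intervals(iv(("chr1", 0, 100, "+")), toy_layout, 0, 1) == []

    def test_forced_placement(self):
        layout = GenomeLayout([("chr1", 500, True)])
        reps = shuffle_intervals(iv(("chr1", 0, 500, "+")), layout, 5, 7)
        assert all(r.df["start"].tolist() == [0] for r in reps)

    def test_lengths_and_bounds_preserved(self, toy_layout):
        src = iv(("chr1", 10, 5_010, "+"), ("chr2", 0, 49_000, "-"), ("chr1", 0, 200, "+"))
        for rep in shuffle_intervals(src, toy_layout, 20, 11):
            assert sorted(rep.df["end"] - rep.df["start"]) == [200, 5_000, 49_000]
            for r in rep:
                assert r.end <= toy_layout.length_of(r.chrom)

    def test_deterministic_given_seed(self, toy_layout):
        src = iv(("chr1", 10, 1_010, "+"))
        a = shuffle_intervals(src, toy_layout, 4, 99)
        b = shuffle_intervals(src, toy_layout, 4, 99)
        assert all(x.to_dataframe().equals(y.to_dataframe()) for x, y in zip(a, b))

    def test_mean_overlap_matches_uniform_expectation(self):
        # a region covering half of a one-chromosome genome should catch ~50%
        # of shuffled bases
        layout = GenomeLayout([("chr1", 100_000, True)])
        region = iv(("chr1", 0, 50_000, "."))
        src = iv(("chr1", 0, 100, "+"))
        reps = shuffle_intervals(src, layout, 1000, 123)
        fracs = []
        for rep in reps:
            r = next(iter(rep))
            ov = max(0, min(r.end, 50_000) - max(r.start, 0))
            fracs.append(ov / 100)
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_exclude_region_is_avoided(self, toy_layout):
        excl = iv(("chr1", 0, 100_000, "."))  # all of chr1
        reps = shuffle_intervals(iv(("chr1", 0, 1_000, "+")), toy_layout, 50, 5, exclude=excl)
        for rep in reps:
            assert all(r.chrom == "chr2" for r in rep)

    def test_unplaceable_raises(self):
        layout = GenomeLayout([("chr1", 10_000, True)])
        excl = iv(("chr1", 0, 10_000, "."))
        with pytest.raises(RuntimeError, match="exclude"):
            shuffle_intervals(iv(("chr1", 0, 100, "+")), layout, 1, 3, exclude=excl)


class TestBedIO:
    def test_read_bed6(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tx\t0\t+\n")
        got = read_bed(p, toy_layout)
        r = next(iter(got))
        assert (r.chrom, r.start, r.end, r.strand, r.name) == ("chr1", 0, 100, "+", "x")

    def test_empty_file(self, tmp_path, toy_layout):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p, toy_layout)) == 0

    def test_invalid_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t500\t400\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_unknown_chrom_skip_vs_error(self, tmp_path, toy_layout):
        p = tmp_path / "u.bed"
        p.write_text("chrUn\t0\t100\n")
        with pytest.warns(UserWarning):
            assert len(read_bed(p, toy_layout, on_unknown="skip")) == 0
        with pytest.raises(ValueError, match="chrUn"):
            read_bed(p, toy_layout, on_unknown="error")

    def test_roundtrip(self, tmp_path, toy_layout):
        src = iv(("chr1", 5, 105, "+", "a", 7.0), ("chr2", 0, 50, "-", "b", None))
        p = tmp_path / "rt.bed"
        write_bed(src, p)
        back = read_bed(p, toy_layout)
        assert back.to_dataframe()[["chrom", "start", "end", "strand", "name"]].equals(
            src.to_dataframe()[["chrom", "start", "end", "strand", "name"]]
        )


def test_invalid_interval_construction():
    with pytest.raises(ValueError):
        StrandedInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        StrandedInterval("chr1", -5, 10)
    with pytest.raises(ValueError):
        StrandedInterval("chr1", 0, 10, strand="*")
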