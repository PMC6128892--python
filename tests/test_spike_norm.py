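import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromexpress.io_formats import FragmentRecord, FragmentSet, ValidationError
from chromexpress.spike_norm import (
    CoverageTrack,
    coverage,
    deduplicate,
    normalize_subtract,
    partition,
    scale,
    scale_factor,
)


def make_set(records):
    return FragmentSet.from_records([FragmentRecord(*r) for r in records])


class TestPartition:
    def test_all_target(self, space):
        frags = make_set([("chr1", 0, 50), ("chr1", 10, 60)])
        result = partition(frags, space)
        assert result.counts == (2, 0)

    def test_counts_conserved(self, space, rng):
        n_target, n_spike = 850, 150
        chroms = ["chr1"] * n_target + ["spike_chr1"] * n_spike
        starts = rng.integers(0, 4000, size=1000)
        frags = FragmentSet(
            np.array(chroms, dtype=object), starts, starts + 50,
            np.array(["+"] * 1000, dtype=object),
        )
        result = partition(frags, space)
        assert result.counts == (850, 150)
        assert sum(result.counts) == len(frags)

    def test_unknown_chromosome_is_error(self, space):
        frags = make_set([("chrUn", 0, 50)])
        with pytest.raises(ValidationError, match="chrUn"):
            partition(frags, space)


class TestDeduplicate:
    def test_identical_triplicate_keeps_one(self):
        frags = make_set([("chr1", 0, 50)] * 3)
        assert len(deduplicate(frags)) == 1

    def test_strand_is_part_of_the_key(self):
        frags = make_set([("chr1", 0, 50, "+"), ("chr1", 0, 50, "-")])
        assert len(deduplicate(frags)) == 2

    def test_first_occurrence_order_preserved(self):
        frags = make_set([("chr1", 100, 150), ("chr1", 0, 50), ("chr1", 100, 150)])
        out = deduplicate(frags)
        assert list(out.starts) == [100, 0]

    def test_survivors_equal_distinct_tuples_on_simulated_duplicates(self, small_config):
        from dataclasses import replace

        from chromexpress.simulate import make_genomes, make_truth, simulate_chip_sample

        config = replace(small_config, duplication_rate=0.2, n_fragments=10_000)
        space, genes = make_genomes(config)
        truth = make_truth(config, genes)
        frags = simulate_chip_sample(config, genes, truth, "H3K4me3", "control")
        assert len(frags) == 12_000
        distinct = {
            (c, int(s), int(e), t)
            for c, s, e, t in zip(frags.chroms, frags.starts, frags.ends, frags.strands)
        }
        assert len(deduplicate(frags)) == len(distinct)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "spike_chr1"]),
                st.integers(0, 400),
                st.integers(1, 60),
                st.sampled_from(["+", "-"]),
            ),
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, raw):
        frags = make_set([(c, s, s + l, t) for c, s, l, t in raw])
        once = deduplicate(frags)
        twice = deduplicate(once)
        assert list(once.starts) == list(twice.starts)
        assert list(once.chroms) == list(twice.chroms)


class TestScaleFactor:
    @pytest.mark.parametrize(
        "count,expected", [(1_000_000, 1.0), (150_000, 1e6 / 150_000)]
    )
    def test_alpha_arithmetic(self, count, expected):
        assert scale_factor(count).alpha == pytest.approx(expected)

    def test_zero_spike_count_is_hard_error(self):
        with pytest.raises(ValidationError, match="spike-in"):
            scale_factor(0)

    def test_equal_counts_give_equal_alpha(self):
        assert scale_factor(123_456).alpha == scale_factor(123_456).alpha


class TestCoverage:
    def test_single_fragment_spans_twenty_bins(self, space):
        frags = make_set([("chr1", 100, 300)])
        track = coverage(frags, space, bin_size=10)
        assert track.values["chr1"][10:30].sum() == 20
        assert track.values["chr1"].sum() == 20

    def test_empty_set_all_zero(self, space):
        track = coverage(FragmentSet.empty(), space)
        assert track.values["chr1"].sum() == 0

    def test_matches_bruteforce_overlap_oracle(self, space, rng):
        starts = rng.integers(0, 9_900, size=1000)
        lengths = rng.integers(1, 120, size=1000)
        ends = np.minimum(starts + lengths, 10_000)
        frags = FragmentSet(
            np.array(["chr1"] * 1000, dtype=object), starts, ends,
            np.array(["+"] * 1000, dtype=object),
        )
        track = coverage(frags, space, bin_size=10)
        oracle = np.zeros(1000)
        for s, e in zip(starts, ends):  # O(n * bins) scan
            for b in range(1000):
                if s < (b + 1) * 10 and e > b * 10:
                    oracle[b] += 1
        np.testing.assert_array_equal(track.values["chr1"], oracle)


class TestNormalizeSubtract:
    def test_self_subtraction_is_exactly_zero(self, space, rng):
        starts = rng.integers(0, 9_000, size=500)
        frags = FragmentSet(
            np.array(["chr1"] * 500, dtype=object), starts, starts + 100,
            np.array(["+"] * 500, dtype=object),
        )
        track = coverage(frags, space)
        sf = scale_factor(200_000)
        out = normalize_subtract(track, track, sf, sf)
        assert out.state == "subtracted"
        for vals in out.values.values():
            assert np.all(vals == 0.0)

    def test_bin_arithmetic(self, space):
        chip = CoverageTrack.zeros(space, bin_size=10)
        inp = CoverageTrack.zeros(space, bin_size=10)
        chip.values["chr1"][0] = 8.0
        inp.values["chr1"][0] = 3.0
        out = normalize_subtract(chip, inp, scale_factor(500_000), scale_factor(1_000_000))
        assert out.values["chr1"][0] == pytest.approx(2 * 8 - 1 * 3)

    def test_negative_values_kept_unless_clipped(self, space):
        chip = CoverageTrack.zeros(space, bin_size=10)
        inp = CoverageTrack.zeros(space, bin_size=10)
        inp.values["chr1"][5] = 4.0
        sf = scale_factor(1_000_000)
        kept = normalize_subtract(chip, inp, sf, sf)
        clipped = normalize_subtract(chip, inp, sf, sf, clip_negative=True)
        assert kept.values["chr1"][5] == -4.0
        assert clipped.values["chr1"][5] == 0.0

    def test_linear_in_each_track(self, space, rng):
        chip = CoverageTrack.zeros(space, bin_size=10)
        inp = CoverageTrack.zeros(space, bin_size=10)
        chip.values["chr1"][:] = rng.random(1000)
        inp.values["chr1"][:] = rng.random(1000)
        sf = scale_factor(1_000_000)
        base = normalize_subtract(chip, inp, sf, sf)
        chip2 = chip.copy()
        chip2.values["chr1"] *= 3.0
        scaled = normalize_subtract(chip2, inp, sf, sf)
        np.testing.assert_allclose(
            scaled.values["chr1"], 3 * chip.values["chr1"] - inp.values["chr1"]
        )
        assert base.values["chr1"] == pytest.approx(
            chip.values["chr1"] - inp.values["chr1"]
        )

    def test_shape_mismatch_is_error(self, space):
        chip = CoverageTrack.zeros(space, bin_size=10)
        inp = CoverageTrack.zeros(space, bin_size=20)
        sf = scale_factor(1_000_000)
        with pytest.raises(ValueError, match="binning|chromosomes"):
            normalize_subtract(chip, inp, sf, sf)

    def test_state_transitions_enforced(self, space):
        track = CoverageTrack.zeros(space, bin_size=10)
        sf = scale_factor(1_000_000)
        scaled = scale(track, sf)
        with pytest.raises(ValueError, match="raw"):
            scale(scaled, sf)
        with pytest.raises(ValueError, match="raw"):
            normalize_subtract(scaled, track, sf, sf)
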