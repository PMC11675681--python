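import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrasleep.errors import InsufficientDataError
from hrasleep.hra_features import (
    RunsDistribution,
    classify_deltas,
    runs_entropy,
    runs_partition,
    threshold_counts,
    variance_decomposition,
)
from hrasleep.hrv_time import pnn30, sd1, sd2, sdnn

# values on a 0.5-ms dyadic grid so grid shifts are exact in binary floating point
rr_lists = st.lists(
    st.integers(min_value=600, max_value=4000).map(lambda k: k * 0.5),
    min_size=4,
    max_size=80,
)
shifts = st.integers(min_value=-200, max_value=200).map(lambda k: k * 0.5)
# a narrow integer range produces ties, exercising neutral runs
rr_int_lists = st.lists(st.integers(min_value=700, max_value=710), min_size=4, max_size=80)


class TestClassifyDeltas:
    def test_hand_example(self):
        out = classify_deltas([800.0, 810.0, 810.0, 790.0])
        assert list(out) == [1, 0, -1]

    def test_monotone_series(self):
        assert (classify_deltas(np.arange(800.0, 900.0, 10.0)) == 1).all()

    def test_reversal_swaps_signs(self, rng):
        x = 900 + rng.normal(0, 40, 100)
        np.testing.assert_array_equal(classify_deltas(x[::-1]), -classify_deltas(x)[::-1])


class TestVarianceDecomposition:
    def test_constant_series(self):
        vd = variance_decomposition(np.full(20, 800.0))
        assert all(v == 0 for v in vars(vd).values())

    def test_alternating_series_perfect_symmetry(self):
        x = np.tile([800.0, 820.0], 51)[:101]  # 50 up moves, 50 down moves
        vd = variance_decomposition(x)
        assert vd.sd1d**2 == pytest.approx(vd.sd1a**2)
        assert vd.sd1d**2 == pytest.approx(sd1(x) ** 2 / 2)

    @pytest.mark.parametrize("integer", [False, True])
    def test_partition_identities(self, rng, integer):
        for _ in range(20):
            x = 900 + rng.normal(0, 50, 300)
            if integer:
                x = np.round(x / 10) * 10  # introduce ties
            vd = variance_decomposition(x)
            assert vd.sd1d**2 + vd.sd1a**2 == pytest.approx(sd1(x) ** 2, rel=1e-9)
            assert vd.sd2d**2 + vd.sd2a**2 == pytest.approx(sd2(x) ** 2, rel=1e-9)
            plot_var = (sd1(x) ** 2 + sd2(x) ** 2) / 2
            assert vd.sdnnd**2 + vd.sdnna**2 == pytest.approx(plot_var, rel=1e-9)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            variance_decomposition([800.0, 810.0])


class TestRunsPartition:
    def test_hand_trace(self):
        dist = runs_partition([800.0, 810.0, 820.0, 800.0, 790.0, 790.0])
        assert dist.dr_counts == {2: 1}
        assert dist.ar_counts == {2: 1}
        assert dist.neutral_counts == {1: 1}
        assert dist.dr_max == 2 and dist.ar_max == 2

    def test_strictly_increasing(self):
        n = 17
        dist = runs_partition(np.linspace(800, 900, n))
        assert dist.dr_counts == {n - 1: 1}
        assert dist.ar_counts == {} and dist.ar_max == 0

    def test_length_conservation(self, rng):
        for _ in range(20):
            x = np.round(900 + rng.normal(0, 30, 250))
            dist = runs_partition(x)
            covered = sum(
                i * c
                for counts in (dist.dr_counts, dist.ar_counts, dist.neutral_counts)
                for i, c in counts.items()
            )
            assert covered == len(x) - 1


class TestRunsEntropy:
    def test_single_run_zero_entropy(self):
        ent = runs_entropy(RunsDistribution({1: 1}, {}, {}))
        assert ent.hdr == 0.0 and ent.har == 0.0

    def test_two_equal_bins_one_bit(self):
        ent = runs_entropy(RunsDistribution({1: 1}, {1: 1}, {}))
        assert ent.hdr == pytest.approx(0.5)
        assert ent.har == pytest.approx(0.5)
        assert ent.h_total == pytest.approx(1.0)

    def test_merging_bins_never_raises_component(self):
        split = RunsDistribution({1: 3, 2: 2}, {1: 4}, {})
        merged = RunsDistribution({1: 5}, {1: 4}, {})
        assert runs_entropy(merged).hdr <= runs_entropy(split).hdr

    def test_neutral_runs_enter_total_only(self):
        dist = RunsDistribution({1: 2}, {1: 2}, {1: 4})
        ent = runs_entropy(dist)
        assert ent.h_total > ent.hdr + ent.har
        ent_x = runs_entropy(dist, include_neutral=False)
        assert ent_x.h_total == pytest.approx(ent_x.hdr + ent_x.har)

    def test_empty_distribution(self):
        with pytest.raises(InsufficientDataError):
            runs_entropy(RunsDistribution({}, {}, {}))


class TestThresholdCounts:
    @pytest.mark.parametrize(
        "series, dec, acc",
        [
            ([800.0, 840.0, 800.0], 50.0, 50.0),
            ([800.0, 831.0, 800.0], 50.0, 50.0),
            ([800.0, 830.0, 800.0], 0.0, 0.0),  # 30 is not > 30
        ],
    )
    def test_hand_counts(self, series, dec, acc):
        tc = threshold_counts(series)
        assert (tc.pnn30dec, tc.pnn30acc) == (dec, acc)

    def test_partition_of_pnn30_is_exact(self, rng):
        for _ in range(50):
            x = 900 + rng.normal(0, 40, rng.integers(5, 200))
            tc = threshold_counts(x)
            assert tc.pnn30dec + tc.pnn30acc == pnn30(x)


@settings(derandomize=True, max_examples=60)
@given(st.one_of(rr_lists, rr_int_lists.map(lambda v: [float(x) for x in v])))
def test_time_reversal_swaps_all_asymmetry_quantities(xs):
    x = np.asarray(xs, dtype=float)
    fwd, rev = variance_decomposition(x), variance_decomposition(x[::-1])
    assert fwd.sd1d == pytest.approx(rev.sd1a, rel=1e-12, abs=1e-12)
    assert fwd.sd1a == pytest.approx(rev.sd1d, rel=1e-12, abs=1e-12)
    assert fwd.sd2d == pytest.approx(rev.sd2a, rel=1e-12, abs=1e-12)
    assert fwd.sdnnd == pytest.approx(rev.sdnna, rel=1e-12, abs=1e-12)
    df, dr = runs_partition(x), runs_partition(x[::-1])
    assert df.dr_counts == dr.ar_counts and df.ar_counts == dr.dr_counts
    assert df.dr_max == dr.ar_max and df.ar_max == dr.dr_max
    ef, er = runs_entropy(df), runs_entropy(dr)
    assert ef.hdr == pytest.approx(er.har) and ef.har == pytest.approx(er.hdr)
    tf, tr = threshold_counts(x), threshold_counts(x[::-1])
    assert tf.pnn30dec == tr.pnn30acc and tf.pnn30acc == tr.pnn30dec


@settings(derandomize=True, max_examples=40)
@given(rr_lists, shifts)
def test_shift_invariance_of_asymmetry_features(xs, shift):
    x = np.asarray(xs)
    a, b = variance_decomposition(x), variance_decomposition(x + shift)
    assert a.sd1d == pytest.approx(b.sd1d, rel=1e-9, abs=1e-9)
    assert a.sd2a == pytest.approx(b.sd2a, rel=1e-6, abs=1e-6)
    assert runs_partition(x).dr_counts == runs_partition(x + shift).dr_counts
    ta, tb = threshold_counts(x), threshold_counts(x + shift)
    assert ta == tb
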