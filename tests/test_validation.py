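"""Tests for the paired-difference device-validation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsalert.validation import (
    BhsGrades,
    ComparisonPair,
    Cuff,
    DifferenceStats,
    EmptyStratumError,
    Measurement,
    MeasurementSequence,
    Source,
    bhs_grade,
    build_comparison_pairs,
    difference_stats,
    iso_assess,
    run_validation,
)
from vsalert.synth import PairedStudySpec, generate_paired_study

from oracles import cumulative_within, two_pass_mean_sd


def seq_from_sbp(values, subject="s", arm=30.0):
    """Alternating sequence R,D,R,... from a list of systolic values; the
    diastolic track mirrors the systolic one 40 mm Hg lower."""
    measurements = tuple(
        Measurement(Source.REFERENCE if i % 2 == 0 else Source.DEVICE, v, v - 40.0)
        for i, v in enumerate(values)
    )
    return MeasurementSequence(subject_id=subject, arm_circumference=arm,
                               measurements=measurements, cuff=Cuff.WIDE_RANGE)


def pairs_from_diffs(diffs, arm=30.0):
    return [
        ComparisonPair(device_sbp=100.0 + d, device_dbp=60.0 + d,
                       reference_sbp=100.0, reference_dbp=60.0,
                       subject_id="s", arm_circumference=arm)
        for d in diffs
    ]


class TestPairing:
    def test_flanking_mean_on_trend_sequence_gives_zero_diffs(self):
        seq = seq_from_sbp([100, 102, 104, 106, 108, 110, 112])
        pairs = build_comparison_pairs(seq, "flanking_mean")
        assert len(pairs) == 3
        assert [p.reference_sbp for p in pairs] == [102, 106, 110]
        assert [p.diff_sbp for p in pairs] == [0, 0, 0]

    def test_same_index_on_trend_sequence(self):
        seq = seq_from_sbp([100, 102, 104, 106, 108, 110, 112])
        pairs = build_comparison_pairs(seq, "same_index")
        assert [p.diff_sbp for p in pairs] == [2, 2, 2]

    def test_sequence_ending_on_device_is_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            seq_from_sbp([100, 102, 104, 106, 108, 110])

    def test_non_alternating_sequence_is_rejected(self):
        measurements = tuple(
            Measurement(Source.REFERENCE, 100.0, 60.0) for _ in range(7)
        )
        with pytest.raises(ValueError, match="alternate"):
            MeasurementSequence("s", 30.0, measurements)

    def test_unknown_scheme_rejected(self):
        seq = seq_from_sbp([100, 100, 100])
        with pytest.raises(ValueError, match="scheme"):
            build_comparison_pairs(seq, "bland_altman")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(80, 180), min_size=4, max_size=4))
    def test_flanking_equals_same_index_on_constant_reference(self, device_vals):
        values = [100.0] * 9
        for i, v in enumerate(device_vals):
            values[2 * i + 1] = v
        seq = seq_from_sbp(values)
        flank = build_comparison_pairs(seq, "flanking_mean")
        same = build_comparison_pairs(seq, "same_index")
        assert [p.diff_sbp for p in flank] == [p.diff_sbp for p in same]


class TestDifferenceStats:
    def test_zero_diffs(self):
        s = difference_stats(pairs_from_diffs([0, 0, 0]))
        assert s.mean_sbp == 0 and s.sd_sbp == 0

    def test_hand_computed(self):
        s = difference_stats(pairs_from_diffs([2, 4, 6]))
        assert s.mean_sbp == pytest.approx(4.0)
        assert s.sd_sbp == pytest.approx(2.0)

    def test_simulated_study_mean_within_two_se_of_design(self):
        # 255 differences ~ Normal(2.2, 6.1^2); SE = 6.1/sqrt(255) = 0.382
        rng = np.random.default_rng(20240601)
        diffs = rng.normal(2.2, 6.1, size=255)
        s = difference_stats(pairs_from_diffs(diffs))
        assert s.mean_sbp == pytest.approx(2.2, abs=2 * 6.1 / np.sqrt(255))

    def test_empty_stratum_is_an_explicit_signal(self):
        pairs = pairs_from_diffs([1, 2, 3], arm=30.0)
        with pytest.raises(EmptyStratumError):
            difference_stats(pairs, stratum=(33.0, 42.0))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            difference_stats(pairs_from_diffs([1.0]))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=40))
    def test_matches_two_pass_oracle(self, diffs):
        s = difference_stats(pairs_from_diffs(diffs))
        mean, sd = two_pass_mean_sd(diffs)
        assert s.mean_sbp == pytest.approx(mean, abs=1e-9)
        assert s.sd_sbp == pytest.approx(sd, abs=1e-9)


class TestIsoAssess:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(2.2, 6.1, True), (5.0, 8.0, True), (5.1, 7.0, False),
         (-5.0, 8.0, True), (-5.2, 3.0, False), (0.0, 8.1, False)],
    )
    def test_bounds_inclusive_and_sign_symmetric(self, mean, sd, expected):
        stats = DifferenceStats(10, mean, sd, mean, sd)
        assert iso_assess(stats).overall_pass is expected

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 12), st.floats(0, 3), st.floats(0, 3))
    def test_monotone_in_mean_and_sd(self, mean, sd, dmean, dsd):
        base = iso_assess(DifferenceStats(10, mean, sd, 0.0, 0.0))
        worse = iso_assess(DifferenceStats(10, mean + dmean, sd + dsd, 0.0, 0.0))
        if worse.sbp_pass:
            assert base.sbp_pass


class TestBhsGrade:
    def test_perfect_device_grades_a(self):
        g = bhs_grade(pairs_from_diffs([0.0] * 10))
        assert (g.grade_sbp, g.grade_dbp) == ("A", "A")
        assert g.pct_sbp == (100.0, 100.0, 100.0)

    def test_hopeless_device_grades_d(self):
        g = bhs_grade(pairs_from_diffs([20.0] * 10))
        assert (g.grade_sbp, g.grade_dbp) == ("D", "D")
        assert g.pct_sbp == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "n5,n10,n15,n_out,expected",
        [
            (60, 25, 10, 5, "A"),   # cumulative 60/85/95
            (50, 25, 15, 10, "B"),  # cumulative 50/75/90
            (40, 25, 20, 15, "C"),  # cumulative 40/65/85
            (30, 25, 20, 25, "D"),  # cumulative 30/55/75
        ],
    )
    def test_constructed_grade_fixtures(self, n5, n10, n15, n_out, expected):
        diffs = [0.0] * n5 + [8.0] * n10 + [13.0] * n15 + [20.0] * n_out
        assert len(diffs) == 100
        g = bhs_grade(pairs_from_diffs(diffs))
        assert g.grade_sbp == expected
        # cumulative percentages agree with a hand count
        assert g.pct_sbp == cumulative_within([abs(d) for d in diffs])

    def test_cumulative_percentages_non_decreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = bhs_grade(pairs_from_diffs(rng.normal(0, 8, size=30)))
            assert g.pct_sbp[0] <= g.pct_sbp[1] <= g.pct_sbp[2]

    def test_adding_zero_difference_pair_never_worsens_grade(self):
        rng = np.random.default_rng(11)
        order = "ABCD"
        for _ in range(20):
            pairs = pairs_from_diffs(rng.normal(2, 9, size=25))
            before = bhs_grade(pairs).grade_sbp
            after = bhs_grade(pairs + pairs_from_diffs([0.0])).grade_sbp
            assert order.index(after) <= order.index(before)

    def test_malformed_grade_table_rejected(self):
        with pytest.raises(ValueError):
            bhs_grade(pairs_from_diffs([0.0] * 5), {"A": (95.0, 85.0, 60.0)})
        with pytest.raises(ValueError):
            bhs_grade(pairs_from_diffs([0.0] * 5), {"A": (60.0, 85.0)})

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            bhs_grade([])


class TestRunValidation:
    def test_zero_difference_dataset_passes_everything(self):
        seqs = [seq_from_sbp([100.0] * 7, subject=f"s{i}", arm=arm)
                for i, arm in enumerate([25.0, 28.0, 35.0, 40.0])]
        report = run_validation(seqs)
        assert report.overall.iso.overall_pass
        assert report.overall.bhs.grade_sbp == "A"
        assert len(report.strata) == 2

    def test_large_arm_bias_shows_in_its_stratum_only(self):
        small = [seq_from_sbp([100.0] * 7, subject=f"a{i}", arm=28.0)
                 for i in range(3)]
        big_vals = [100.0, 115.0] * 3 + [100.0]  # device +15 throughout
        big = [seq_from_sbp(big_vals, subject=f"b{i}", arm=38.0) for i in range(3)]
        report = run_validation(small + big)
        by_stratum = {r.stratum: r for r in report.strata}
        assert by_stratum[(22.0, 32.0)].stats.mean_sbp == pytest.approx(0.0)
        assert by_stratum[(33.0, 42.0)].stats.mean_sbp == pytest.approx(15.0)
        assert not by_stratum[(33.0, 42.0)].iso.overall_pass

    def test_synthetic_wide_range_cuff_study_fails_only_on_large_arms(self):
        # default generator: +10 mm Hg device bias on arms >= 33 cm
        seqs = generate_paired_study(PairedStudySpec(seed=42))
        report = run_validation(seqs)
        by_stratum = {r.stratum: r for r in report.strata}
        assert by_stratum[(22.0, 32.0)].iso.overall_pass
        assert not by_stratum[(33.0, 42.0)].iso.overall_pass
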