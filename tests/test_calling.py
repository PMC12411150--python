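import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aneuscan.calling import (
    CIN_NEGATIVE,
    CIN_POSITIVE,
    GAIN,
    LOSS,
    NEUTRAL,
    QC_FAILED,
    CallThresholds,
    CINCaller,
    annotate_genes,
    call_cin,
    call_segments,
    summarize_arms,
)
from aneuscan.genome import GeneLocus
from aneuscan.normalize import QCReport
from aneuscan.segmentation import Segment


def make_segment(chrom, start_bin, end_bin, mean, grid=None):
    """Segment over fully-usable bins; grid indices equal usable indices."""
    offset = 0
    if grid is not None and chrom != grid.genome.names[0]:
        offset = grid.chrom_slices()[chrom].start
    return Segment(
        chrom=chrom,
        start_bin=start_bin,
        end_bin=end_bin,
        seg_mean=mean,
        p_value=0.001,
        start=start_bin * 200_000,
        end=end_bin * 200_000,
        grid_start=offset + start_bin,
        grid_end=offset + end_bin,
    )


def passing_qc(sid="s"):
    return QCReport(sample_id=sid, statistic=0.1, passed=True)


class TestCallSegments:
    @pytest.mark.parametrize(
        "mean,n_bins,expected",
        [
            (5.0, 60, GAIN),
            (-4.0, 10, NEUTRAL),  # too short at min_event_bins=50
            (0.0, 60, NEUTRAL),
            (-3.5, 60, LOSS),
            (2.9, 60, NEUTRAL),  # below z_gain
        ],
    )
    def test_rule(self, mean, n_bins, expected):
        seg = make_segment("chrA", 0, n_bins, mean)
        [(_, call)] = call_segments([seg], CallThresholds())
        assert call == expected

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.floats(-8, 8),
        st.integers(10, 120),
        st.floats(3.0, 6.0),
        st.floats(0.5, 3.0),
    )
    def test_gains_monotone_in_threshold(self, mean, n_bins, z_gain, bump):
        seg = make_segment("chrA", 0, n_bins, mean)
        low = CallThresholds(z_gain=z_gain)
        high = CallThresholds(z_gain=z_gain + bump)
        [(_, call_low)] = call_segments([seg], low)
        [(_, call_high)] = call_segments([seg], high)
        if call_high == GAIN:  # raising z_gain never creates a gain
            assert call_low == GAIN


class TestCallCIN:
    def test_no_calls_negative(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        segs = [make_segment("chrA", 0, 200, 0.1, small_grid)]
        result = call_cin(segs, CallThresholds(), passing_qc(), small_grid, usable)
        assert result.status == CIN_NEGATIVE
        assert result.aberrant_fraction == 0.0
        assert result.aberrant_arms == []

    def test_whole_arm_gain_positive_with_arm_listed(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        segs = [
            make_segment("chrA", 0, 100, 0.0, small_grid),
            make_segment("chrA", 100, 200, 5.0, small_grid),  # whole q arm
            make_segment("chrB", 0, 200, 0.0, small_grid),
        ]
        result = call_cin(segs, CallThresholds(), passing_qc(), small_grid, usable)
        assert result.status == CIN_POSITIVE
        assert result.aberrant_arms == [("chrAq", GAIN)]
        assert result.aberrant_fraction == pytest.approx(100 / 400)

    def test_qc_failed_carries_no_calls(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        qc = QCReport(sample_id="bad", statistic=0.9, passed=False)
        segs = [make_segment("chrA", 100, 200, 5.0, small_grid)]
        result = call_cin(segs, CallThresholds(), qc, small_grid, usable)
        assert result.status == QC_FAILED
        assert result.called_segments == []
        assert result.aberrant_fraction == 0.0

    def test_half_arm_event_not_attributed_to_arm(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        segs = [make_segment("chrA", 100, 150, 5.0, small_grid)]  # 50% of q arm
        result = call_cin(segs, CallThresholds(), passing_qc(), small_grid, usable)
        assert result.status == CIN_POSITIVE  # still a called event
        assert result.aberrant_arms == []  # but > 50% coverage required

    def test_min_aberrant_fraction_gate(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        segs = [make_segment("chrA", 100, 200, 5.0, small_grid)]
        thresholds = CallThresholds(cin_min_aberrant_fraction=0.5)
        result = call_cin(segs, thresholds, passing_qc(), small_grid, usable)
        assert result.status == CIN_NEGATIVE  # 25% aberrant < 50% floor


class TestSummarizeArms:
    def test_frequencies(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        results = []
        for k in range(4):
            segs = (
                [make_segment("chrA", 100, 200, 5.0, small_grid)] if k < 3 else []
            )
            results.append(
                call_cin(segs, CallThresholds(), passing_qc(f"s{k}"), small_grid, usable)
            )
        freq = summarize_arms(results, small_grid)
        assert freq.loc["chrAq", "gain_frequency"] == pytest.approx(0.75)
        assert freq.loc["chrAq", "loss_frequency"] == 0.0
        assert freq.loc["chrBp", "gain_frequency"] == 0.0
        assert ((freq >= 0) & (freq <= 1)).all().all()

    def test_no_calls_all_zero(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        results = [
            call_cin([], CallThresholds(), passing_qc("s0"), small_grid, usable)
        ]
        assert (summarize_arms(results, small_grid) == 0).all().all()

    def test_empty_cohort_rejected(self, small_grid):
        with pytest.raises(ValueError):
            summarize_arms([], small_grid)


class TestAnnotateGenes:
    def test_gene_inside_gain_amplified(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        called = [(make_segment("chrA", 100, 200, 5.0, small_grid), GAIN)]
        locus = GeneLocus("EGFR", "chrA", 30_000_000, 30_100_000)  # bin 150
        calls = annotate_genes(called, [locus], small_grid, usable)
        assert calls == {"EGFR": "amplified"}

    def test_larger_neutral_overlap_wins(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        called = [
            (make_segment("chrA", 0, 101, 5.0, small_grid), GAIN),
            (make_segment("chrA", 101, 200, 0.0, small_grid), NEUTRAL),
        ]
        # gene spans bins 100-103: 1 bin in the gain, 3 in the neutral segment
        locus = GeneLocus("G", "chrA", 20_000_000, 20_800_000)
        assert annotate_genes(called, [locus], small_grid, usable) == {"G": "neutral"}

    def test_conflicting_tie_is_neutral(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        called = [
            (make_segment("chrA", 0, 100, 5.0, small_grid), GAIN),
            (make_segment("chrA", 100, 200, -5.0, small_grid), LOSS),
        ]
        # two bins on each side of the boundary
        locus = GeneLocus("G", "chrA", 19_600_000, 20_400_000)
        assert annotate_genes(called, [locus], small_grid, usable) == {"G": "neutral"}

    def test_gene_on_unusable_bins_not_evaluable(self, small_grid):
        usable = np.ones(small_grid.n_bins, bool)
        usable[150] = False
        called = [(make_segment("chrA", 0, 200, 0.0, small_grid), NEUTRAL)]
        locus = GeneLocus("G", "chrA", 30_000_000, 30_100_000)
        assert annotate_genes(called, [locus], small_grid, usable) == {
            "G": "not-evaluable"
        }


class TestThresholdValidation:
    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            CallThresholds(z_gain=-1.0)
        with pytest.raises(ValueError):
            CallThresholds(min_event_bins=0)

    def test_chrx_excluded_by_default(self):
        caller = CINCaller()
        assert "chrX" in caller.exclude_chroms
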