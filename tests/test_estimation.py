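"""Binning, deduplication, Tukey fences and the Hodges–Lehmann estimator."""
import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleotherm import (
    EstimatorConfig,
    ThermalRange,
    assign_bin,
    dedupe_intervals,
    estimate_bin,
    estimate_stage,
    hodges_lehmann,
    midpoint,
    quartiles,
    stage_series,
    tukey_filter,
)

CFG = EstimatorConfig()


def walsh_median(values):
    """Independent brute-force pseudo-median: enumerate all Walsh averages
    (x_i + x_j)/2 over pairs i <= j and take their median."""
    averages = [
        (a + b) / 2
        for a, b in itertools.combinations_with_replacement(sorted(values), 2)
    ]
    return statistics.median(averages)


@pytest.mark.parametrize(
    "lo,hi,expected", [(18, 25, 21.5), (20, 20, 20.0), (0, 4, 2.0)]
)
def test_midpoint(lo, hi, expected):
    assert midpoint(ThermalRange(lo, hi)) == expected


@pytest.mark.parametrize(
    "lat,label",
    [
        (23.4, 20.0),
        (25.0, 30.0),  # exact boundary goes to the higher-labelled bin
        (-12.0, -10.0),
        (-25.0, -20.0),
        (0.0, 0.0),
        (4.9, 0.0),
        (90.0, 90.0),
    ],
)
def test_assign_bin(lat, label):
    assert assign_bin(lat, CFG) == label


def test_assign_bin_respects_width():
    assert assign_bin(8.0, EstimatorConfig(bin_width=5.0)) == 10.0


class TestDedupe:
    def make(self, ranges, make_record):
        return [make_record(t_min=lo, t_max=hi, taxon=f"T{i}")
                for i, (lo, hi) in enumerate(ranges)]

    def test_grouping_with_multiplicity(self, make_record):
        records = self.make([(10, 14), (10, 14), (12, 16)], make_record)
        out = dedupe_intervals(records)
        assert out == [(ThermalRange(10, 14), 2), (ThermalRange(12, 16), 1)]

    def test_all_identical_collapse_to_one(self, make_record):
        records = self.make([(18, 21)] * 5, make_record)
        out = dedupe_intervals(records)
        assert out == [(ThermalRange(18, 21), 5)]

    def test_rounding_to_centidegrees_merges_parse_noise(self, make_record):
        records = self.make([(10.001, 14.0), (9.999, 14.0)], make_record)
        assert len(dedupe_intervals(records)) == 1

    def test_multiplicities_sum_to_n(self, make_record):
        records = self.make([(10, 12), (11, 13), (10, 12), (9, 14)], make_record)
        assert sum(m for _, m in dedupe_intervals(records)) == len(records)


class TestQuartiles:
    @pytest.mark.parametrize(
        "values,q1,q3",
        [
            ([1, 2, 3, 4, 5], 2.0, 4.0),
            ([5, 5, 5], 5.0, 5.0),
            ([1, 2, 3, 4, 100], 2.0, 4.0),  # interpolation positions 1.0, 3.0
        ],
    )
    def test_interp_orderstat(self, values, q1, q3):
        assert quartiles(values, CFG) == (q1, q3)

    def test_inclusive_hinges(self):
        cfg = EstimatorConfig(quartile_method="inclusive")
        # halves {1,2,3} and {3,4,5}, median in both
        assert quartiles([1, 2, 3, 4, 5], cfg) == (2.0, 4.0)
        assert quartiles([1, 2, 3, 4], cfg) == (1.5, 3.5)

    def test_exclusive_convention_differs(self):
        cfg = EstimatorConfig(quartile_method="exclusive")
        q1, q3 = quartiles([1, 2, 3, 4, 5], cfg)
        assert (q1, q3) == (1.5, 4.5)  # positions p*(m+1) = 1.5 and 4.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quartiles([], CFG)


class TestTukeyFilter:
    def test_no_outliers_all_retained(self):
        retained, removed = tukey_filter([1, 2, 3, 4, 5], CFG)
        assert retained == [1, 2, 3, 4, 5] and removed == []

    def test_outlier_beyond_upper_fence_removed(self):
        # Q1=2, Q3=4, IQR=2 → upper fence 4 + 1.5·2 = 7
        retained, removed = tukey_filter([1, 2, 3, 4, 100], CFG)
        assert retained == [1, 2, 3, 4] and removed == [100]

    def test_constant_data_survives_zero_iqr(self):
        retained, removed = tukey_filter([5, 5, 5], CFG)
        assert retained == [5, 5, 5] and removed == []

    def test_input_order_preserved(self):
        retained, _ = tukey_filter([3, 1, 100, 4, 2], CFG)
        assert retained == [3, 1, 4, 2]

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
    def test_conservation_property(self, values):
        retained, removed = tukey_filter(values, CFG)
        assert sorted(retained + removed) == sorted(values)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=60))
    def test_identity_on_data_inside_its_fences(self, values):
        """Clipping a sample into its own fences leaves (for these sizes)
        quartiles untouched, so the filter must then be the identity."""
        q1, q3 = np.quantile(values, [0.25, 0.75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        clipped = [min(max(v, lo), hi) for v in values]
        nq1, nq3 = quartiles(clipped, CFG)
        if not (nq1 - 1.5 * (nq3 - nq1) <= min(clipped)
                and max(clipped) <= nq3 + 1.5 * (nq3 - nq1)):
            return  # precondition (inside own fences) not met after clipping
        retained, removed = tukey_filter(clipped, CFG)
        assert retained == clipped and removed == []


class TestHodgesLehmann:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2], 2.0),
            ([1, 2, 3], 2.0),
            ([0, 1, 2, 10], 1.75),  # median of the 10 Walsh averages
        ],
    )
    def test_worked_examples(self, values, expected):
        assert hodges_lehmann(values) == expected

    def test_matches_brute_force_on_small_grids(self):
        grid = [-2.0, 0.0, 1.5, 7.0]
        for size in range(1, 6):
            for combo in itertools.combinations_with_replacement(grid, size):
                assert hodges_lehmann(combo) == pytest.approx(
                    walsh_median(combo), abs=1e-12
                )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hodges_lehmann([])

    @given(
        st.lists(st.floats(-30, 30), min_size=1, max_size=25),
        st.floats(-10, 10),
        st.floats(0.1, 5),
    )
    def test_affine_equivariance_and_boundedness(self, values, c, a):
        h = hodges_lehmann(values)
        assert min(values) - 1e-9 <= h <= max(values) + 1e-9
        assert hodges_lehmann([v + c for v in values]) == pytest.approx(h + c)
        assert hodges_lehmann([a * v for v in values]) == pytest.approx(a * h)


class TestEstimateBin:
    def records_with_midpoints(self, mids, make_record, **kwargs):
        return [
            make_record(t_min=m - 1, t_max=m + 1, taxon=f"T{i}", **kwargs)
            for i, m in enumerate(mids)
        ]

    def test_symmetric_midpoints(self, make_record):
        est = estimate_bin(self.records_with_midpoints([10, 12, 14], make_record))
        assert est.hlm == 12.0
        assert est.n == 3 and est.n_int == 3
        assert est.n_outliers_removed == 0
        assert est.low_confidence  # n < default min_bin_n of 5

    def test_outlier_removed_before_pseudomedian(self, make_record):
        records = self.records_with_midpoints([1, 2, 3, 4, 100], make_record)
        est = estimate_bin(records)
        assert est.n_outliers_removed == 1
        assert est.hlm == hodges_lehmann([1, 2, 3, 4]) == 2.5
        # quartiles reported from the pre-Tukey values that defined the fences
        assert (est.q1, est.q3) == (2.0, 4.0)

    def test_duplicate_records_change_n_but_not_statistics(self, make_record):
        base = self.records_with_midpoints([10, 12, 14, 30], make_record)
        dup = base + [
            make_record(t_min=9, t_max=11, taxon="T0"),
            make_record(t_min=9, t_max=11, taxon="T0"),
        ]
        e1, e2 = estimate_bin(base), estimate_bin(dup)
        assert e2.n == e1.n + 2
        assert e2.n_int == e1.n_int
        assert (e2.hlm, e2.q1, e2.q3) == (e1.hlm, e1.q1, e1.q3)

    def test_weighted_mode_counts_multiplicity(self, make_record):
        records = self.records_with_midpoints([10, 20], make_record)
        records += [make_record(t_min=19, t_max=21, taxon="T1")] * 3
        cfg = EstimatorConfig(dedupe_mode="weighted")
        est_w = estimate_bin(records, cfg)
        est_u = estimate_bin(records)
        assert est_w.hlm == 20.0  # four records at 20 dominate
        assert est_u.hlm == 15.0  # unique intervals weigh equally
        assert est_w.n_int == est_u.n_int == 2

    def test_record_order_invariance(self, make_record):
        records = self.records_with_midpoints([14, 9, 22, 17, 11, 30], make_record)
        forward = estimate_bin(records)
        backward = estimate_bin(list(reversed(records)))
        assert forward == backward

    def test_n_int_never_exceeds_n(self, make_record):
        records = self.records_with_midpoints([10, 10, 12], make_record)
        records[1] = make_record(t_min=9, t_max=11, taxon="T0")
        est = estimate_bin(records)
        assert est.n_int <= est.n


class TestStageLevel:
    def test_one_estimate_per_occupied_bin(self, make_record):
        records = []
        for lat in (8, 12, 18, 22, 28, 33):
            records.append(make_record(paleolat=lat, t_min=15, t_max=18,
                                       taxon=f"T{lat}"))
        trend = estimate_stage(records, "Pragian")
        assert [e.bin_label for e in trend.estimates] == [10.0, 20.0, 30.0]
        assert len(trend.trend_points) == 3

    def test_unknown_stage_gives_empty_trend(self, make_record):
        trend = estimate_stage([make_record()], "Visean")
        assert trend.estimates == []

    def test_single_bin_trend(self, make_record):
        trend = estimate_stage([make_record(paleolat=41.0)], "Pragian")
        assert len(trend.trend_points) == 1

    def test_series_recovers_known_bin_means(self, make_record):
        # one stage, two bins with constant midpoints 12 and 14 → mean 13
        records = [
            make_record(paleolat=10, t_min=11, t_max=13, taxon="A"),
            make_record(paleolat=20, t_min=13, t_max=15, taxon="B"),
        ]
        series = stage_series(records)
        assert len(series) == 1
        row = series.rows[0]
        assert row.mean_hlm == 13.0
        assert (row.t_min, row.t_max) == (12.0, 14.0)
        assert row.n_records == 2

    def test_series_ordered_by_stage_age(self, make_record):
        records = [
            make_record(stage="Visean", paleolat=10),
            make_record(stage="Pragian", paleolat=10),
            make_record(stage="Norian", paleolat=10),
        ]
        series = stage_series(records)
        assert [r.stage for r in series] == ["Pragian", "Visean", "Norian"]
        for row in series:
            assert row.t_min <= row.mean_hlm <= row.t_max
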