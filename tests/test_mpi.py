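import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpindex import (
    FilterConfig,
    GenomicInterval,
    PreMirnaLocus,
    apply_filters,
    compute_records,
    delta_mpi,
    mpi_condition,
    mpi_sample,
    records_to_frame,
)
from conftest import constant_locus_coverage, make_coverage

nonneg = st.floats(min_value=0, max_value=1e9, allow_nan=False)


class TestMpiSample:
    @pytest.mark.parametrize(
        "h, f, expected",
        [(0, 0, 0.0), (3, 15, 2.0), (15, 3, -2.0), (7.5, 7.5, 0.0)],
    )
    def test_worked_values(self, h, f, expected):
        assert mpi_sample(h, f) == pytest.approx(expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            mpi_sample(-1, 5)
        with pytest.raises(ValueError):
            mpi_sample(5, float("nan"))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(h=nonneg, f=nonneg)
    def test_antisymmetry(self, h, f):
        assert mpi_sample(h, f) == pytest.approx(-mpi_sample(f, h), abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(h=st.floats(min_value=0, max_value=1e6), delta=st.floats(min_value=1e-3, max_value=1e3))
    def test_strictly_decreasing_in_hairpin_increasing_in_flank(self, h, delta):
        f = 50.0
        assert mpi_sample(h + delta, f) < mpi_sample(h, f)
        assert mpi_sample(h, f + delta) > mpi_sample(h, f)

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(42)
        h = rng.uniform(0, 1e4, 1000)
        f = rng.uniform(0, 1e4, 1000)
        oracle = -np.log2((h + 1) / (f + 1))  # independent direct evaluation
        got = np.array([mpi_sample(a, b) for a, b in zip(h, f)])
        assert np.max(np.abs(got - oracle)) < 1e-12


class TestConditionAndDelta:
    def test_condition_mean(self):
        assert mpi_condition([2.0, 2.2]) == pytest.approx(2.1)
        assert mpi_condition([0.0]) == 0.0
        assert mpi_condition([1.0, -1.0]) == 0.0

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            mpi_condition([])

    def test_delta(self):
        assert delta_mpi(1.1, 2.1) == pytest.approx(-1.0)
        assert delta_mpi(2.5, 1.0) == pytest.approx(1.5)
        assert delta_mpi(0.7, 0.7) == 0.0

    def test_delta_invariant_under_common_shift(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=4)
        mut = rng.normal(size=4)
        d0 = delta_mpi(mpi_condition(mut), mpi_condition(ref))
        c = 1.73
        d1 = delta_mpi(mpi_condition(mut + c), mpi_condition(ref + c))
        assert d1 == pytest.approx(d0)


def _two_condition_records():
    """1 locus, constant coverage: reference (hairpin 3, flanks 15),
    mutant (hairpin 15, flanks 15)."""
    locus = PreMirnaLocus("m1", GenomicInterval("chr1", 1000, 1085, "+"))
    ref_cov = make_coverage("WT_rep1")
    constant_locus_coverage(ref_cov, locus, 3, 15, 15)
    mut_cov = make_coverage("KO_rep1")
    constant_locus_coverage(mut_cov, locus, 15, 15, 15)
    coverages = {"WT_rep1": ref_cov, "KO_rep1": mut_cov}
    conditions = {"WT_rep1": "WT", "KO_rep1": "KO"}
    return locus, coverages, conditions


class TestComputeRecords:
    def test_two_condition_worked_example(self):
        locus, coverages, conditions = _two_condition_records()
        records, failures = compute_records([locus], coverages, conditions, "WT")
        assert failures == []
        (rec,) = records
        assert rec.per_condition_mpi["WT"] == pytest.approx(2.0)
        assert rec.per_condition_mpi["KO"] == pytest.approx(0.0)
        assert rec.delta_mpi["KO"] == pytest.approx(-2.0)

    def test_all_zero_coverage_gives_zero_mpi(self):
        locus = PreMirnaLocus("m1", GenomicInterval("chr1", 1000, 1085, "+"))
        coverages = {"WT_rep1": make_coverage(), "KO_rep1": make_coverage()}
        conditions = {"WT_rep1": "WT", "KO_rep1": "KO"}
        ((rec,), _) = compute_records([locus], coverages, conditions, "WT")
        assert rec.per_condition_mpi["WT"] == 0.0
        assert rec.delta_mpi["KO"] == 0.0

    def test_duplicate_reference_sample_leaves_condition_mpi_unchanged(self):
        locus, coverages, conditions = _two_condition_records()
        ((before,), _) = compute_records([locus], coverages, conditions, "WT")
        coverages["WT_rep2"] = coverages["WT_rep1"]
        conditions["WT_rep2"] = "WT"
        ((after,), _) = compute_records([locus], coverages, conditions, "WT")
        assert after.per_condition_mpi["WT"] == pytest.approx(
            before.per_condition_mpi["WT"]
        )

    def test_underivable_locus_reported_not_dropped(self):
        good = PreMirnaLocus("good", GenomicInterval("chr1", 1000, 1085, "+"))
        edge = PreMirnaLocus("edge", GenomicInterval("chr1", 10, 95, "+"))
        cov = make_coverage("WT_rep1")
        constant_locus_coverage(cov, good, 3, 15, 15)
        records, failures = compute_records(
            [good, edge], {"WT_rep1": cov}, {"WT_rep1": "WT"}, "WT"
        )
        assert [r.locus_id for r in records] == ["good"]
        assert failures and failures[0][0] == "edge"

    def test_strand_symmetry(self):
        """A minus-strand locus with mirrored coverage gives the identical MPI."""
        plus = PreMirnaLocus("p", GenomicInterval("chr1", 1000, 1085, "+"))
        minus = PreMirnaLocus("m", GenomicInterval("chr1", 1000, 1085, "-"))
        cov = make_coverage("s1")
        # asymmetric flanks (within the ratio filter) on the plus strand
        constant_locus_coverage(cov, plus, 4, 10, 20)
        # spatial mirror of the same profile on the minus strand
        hp = minus.hairpin
        cov.add_interval("chr1", "-", hp.start - 100, hp.start, 20)
        cov.add_interval("chr1", "-", hp.start, hp.end, 4)
        cov.add_interval("chr1", "-", hp.end, hp.end + 100, 10)
        records, _ = compute_records(
            [plus, minus], {"s1": cov}, {"s1": "WT"}, "WT"
        )
        by_id = {r.locus_id: r for r in records}
        assert by_id["m"].per_sample["s1"].mpi == pytest.approx(
            by_id["p"].per_sample["s1"].mpi, abs=1e-12
        )

    def test_unknown_reference_rejected(self):
        locus, coverages, conditions = _two_condition_records()
        with pytest.raises(ValueError, match="reference"):
            compute_records([locus], coverages, conditions, "HET")


class TestFilters:
    def test_five_locus_audit(self, filter_fixture):
        records, _ = compute_records(
            filter_fixture["loci"],
            filter_fixture["coverages"],
            filter_fixture["sample_conditions"],
            "WT",
        )
        survivors, audit = apply_filters(
            records,
            filter_fixture["loci"],
            filter_fixture["detected"],
            filter_fixture["mirtrons"],
            FilterConfig(),
            "WT",
            filter_fixture["sample_conditions"],
        )
        assert [r.locus_id for r in survivors] == ["E"]
        first = dict(zip(audit["locus_id"], audit["first_failing_filter"]))
        assert first == {
            "A": "mirtron",
            "B": "ref_flank_depth",
            "C": "flank_ratio",
            "D": "detected",
        }
        index = dict(zip(audit["locus_id"], audit["first_failing_index"]))
        assert index == {"A": 1, "B": 3, "C": 4, "D": 2}
        # audit is exhaustive and no survivor fails anything
        assert len(survivors) + audit["locus_id"].nunique() == len(records)
        assert all(not r.failing_filters() for r in survivors)

    def test_flank_ratio_uses_pseudocounts(self, filter_fixture):
        # C: means 20 and 110 -> (110+1)/(20+1) = 111/21 > 4
        assert (110 + 1) / (20 + 1) > 4

    def test_boundary_flank_depth_two_passes(self):
        locus = PreMirnaLocus("b", GenomicInterval("chr1", 1000, 1085, "+"))
        cov = make_coverage("WT_rep1")
        constant_locus_coverage(cov, locus, 1, 2.0, 2.0)
        records, _ = compute_records([locus], {"WT_rep1": cov}, {"WT_rep1": "WT"}, "WT")
        survivors, audit = apply_filters(
            records, [locus], {"b"}, set(), FilterConfig(), "WT", {"WT_rep1": "WT"}
        )
        assert [r.locus_id for r in survivors] == ["b"]

    def test_empty_detected_set_fails_all(self, filter_fixture):
        records, _ = compute_records(
            filter_fixture["loci"],
            filter_fixture["coverages"],
            filter_fixture["sample_conditions"],
            "WT",
        )
        survivors, audit = apply_filters(
            records, filter_fixture["loci"], set(), set(),
            FilterConfig(), "WT", filter_fixture["sample_conditions"],
        )
        assert survivors == []
        assert set(audit["locus_id"]) == {"A", "B", "C", "D", "E"}

    def test_require_detected_false_skips_filter_two(self, filter_fixture):
        records, _ = compute_records(
            filter_fixture["loci"],
            filter_fixture["coverages"],
            filter_fixture["sample_conditions"],
            "WT",
        )
        survivors, _ = apply_filters(
            records, filter_fixture["loci"], set(), filter_fixture["mirtrons"],
            FilterConfig(require_detected=False), "WT",
            filter_fixture["sample_conditions"],
        )
        assert {r.locus_id for r in survivors} == {"D", "E"}

    def test_processed_in_ref_flag_uses_min_over_reference_samples(self):
        locus = PreMirnaLocus("x", GenomicInterval("chr1", 1000, 1085, "+"))
        cov_hi = make_coverage("WT_rep1")
        constant_locus_coverage(cov_hi, locus, 3, 15, 15)  # MPI = 2
        cov_lo = make_coverage("WT_rep2")
        constant_locus_coverage(cov_lo, locus, 13, 15, 15)  # MPI ~ 0.19
        records, _ = compute_records(
            [locus], {"WT_rep1": cov_hi, "WT_rep2": cov_lo},
            {"WT_rep1": "WT", "WT_rep2": "WT"}, "WT",
        )
        survivors, _ = apply_filters(
            records, [locus], {"x"}, set(), FilterConfig(), "WT",
            {"WT_rep1": "WT", "WT_rep2": "WT"},
        )
        # condition mean MPI > 0.3 but the weakest replicate is below it
        assert records[0].per_condition_mpi["WT"] > 0.3
        assert records[0].processed_in_ref is False


def test_records_to_frame_is_sorted_and_complete(filter_fixture):
    records, _ = compute_records(
        filter_fixture["loci"],
        filter_fixture["coverages"],
        filter_fixture["sample_conditions"],
        "WT",
    )
    frame = records_to_frame(records)
    assert list(frame["locus_id"]) == sorted(frame["locus_id"])
    assert {"WT_rep1.mpi", "mpi.WT"} <= set(frame.columns)
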