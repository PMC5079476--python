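"""Region-universe construction, binarization and compendium building."""

import math

import numpy as np
import pytest
from oracles import binarize_all_pairs, coverage_per_base, merge_intervals_quadratic

from seqcorr import (
    DataError,
    ExpressionSample,
    GenomicInterval,
    MetadataRecord,
    PeakSample,
    RegionUniverse,
    Transform,
    binarize_peaks,
    build_cage_compendium,
    build_expression_compendium,
    build_peak_compendium,
    build_region_universe,
    subset_compendium,
)
from conftest import random_intervals

SMALL_GENOME = {"chrA": 10_000, "chrB": 10_000, "chrC": 10_000}


def _tuples(universe):
    return [(iv.chrom, iv.start, iv.end) for iv in universe.regions]


class TestRegionUniverse:
    def test_overlap_merge(self):
        u = build_region_universe(
            [
                PeakSample("a", [GenomicInterval("chr1", 100, 200)]),
                PeakSample("b", [GenomicInterval("chr1", 150, 250)]),
            ]
        )
        assert _tuples(u) == [("chr1", 100, 250)]

    def test_bookended_intervals_merge(self):
        u = build_region_universe(
            [PeakSample("a", [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300)])]
        )
        assert _tuples(u) == [("chr1", 100, 300)]

    def test_disjoint_chromosomes(self):
        u = build_region_universe(
            [
                PeakSample("a", [GenomicInterval("chr1", 100, 200)]),
                PeakSample("b", [GenomicInterval("chr2", 100, 200)]),
            ]
        )
        assert _tuples(u) == [("chr1", 100, 200), ("chr2", 100, 200)]

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            build_region_universe([PeakSample("a", [])])

    def test_matches_quadratic_merge_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            samples = [
                PeakSample(f"s{i}", random_intervals(rng, int(rng.integers(1, 15)), SMALL_GENOME, 2000))
                for i in range(int(rng.integers(1, 5)))
            ]
            u = build_region_universe(samples)
            oracle = merge_intervals_quadratic(
                [(iv.chrom, iv.start, iv.end) for s in samples for iv in s.intervals]
            )
            assert _tuples(u) == oracle

    def test_coverage_identical_to_per_base_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            samples = [
                PeakSample(f"s{i}", random_intervals(rng, 10, SMALL_GENOME, 2000)) for i in range(3)
            ]
            u = build_region_universe(samples)
            cov_in = coverage_per_base(
                [(iv.chrom, iv.start, iv.end) for s in samples for iv in s.intervals], 10_000
            )
            cov_out = coverage_per_base(_tuples(u), 10_000)
            assert set(cov_in) == set(cov_out)
            for chrom in cov_in:
                assert np.array_equal(cov_in[chrom], cov_out[chrom])

    def test_each_input_interval_inside_exactly_one_region(self):
        rng = np.random.default_rng(2)
        samples = [PeakSample(f"s{i}", random_intervals(rng, 20, SMALL_GENOME, 1500)) for i in range(4)]
        u = build_region_universe(samples)
        for s in samples:
            for iv in s.intervals:
                containing = [
                    r for r in u.regions if r.chrom == iv.chrom and r.start <= iv.start and iv.end <= r.end
                ]
                assert len(containing) == 1

    def test_unsorted_or_overlapping_universe_rejected(self):
        with pytest.raises(DataError):
            RegionUniverse([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 300)])


class TestBinarize:
    def test_containment(self):
        u = RegionUniverse([GenomicInterval("chr1", 100, 200)])
        vec = binarize_peaks(PeakSample("s", [GenomicInterval("chr1", 150, 160)]), u)
        assert vec.tolist() == [1.0]

    def test_bookended_half_open_no_overlap(self):
        u = RegionUniverse([GenomicInterval("chr1", 100, 200)])
        vec = binarize_peaks(PeakSample("s", [GenomicInterval("chr1", 200, 300)]), u)
        assert vec.tolist() == [0.0]

    def test_empty_sample_gives_zero_vector(self):
        u = RegionUniverse([GenomicInterval("chr1", 100, 200)])
        assert binarize_peaks(PeakSample("s", []), u).tolist() == [0.0]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            universe = build_region_universe(
                [PeakSample("u", random_intervals(rng, 25, SMALL_GENOME, 1500))]
            )
            sample = PeakSample("s", random_intervals(rng, int(rng.integers(0, 20)), SMALL_GENOME, 1500))
            got = binarize_peaks(sample, universe)
            want = binarize_all_pairs(
                [(iv.chrom, iv.start, iv.end) for iv in sample.intervals], _tuples(universe)
            )
            assert np.array_equal(got, want)


class TestPeakCompendium:
    def test_identical_samples_give_all_ones(self):
        ivs = [GenomicInterval("chr1", 10, 50), GenomicInterval("chr2", 5, 25)]
        samples = [PeakSample("a", list(ivs)), PeakSample("b", list(ivs))]
        meta = [MetadataRecord("a", {"f": "x"}), MetadataRecord("b", {"f": "x"})]
        comp = build_peak_compendium(samples, meta)
        assert np.array_equal(comp.matrix, np.ones((2, 2)))

    def test_disjoint_samples_block_diagonal(self):
        samples = [
            PeakSample("a", [GenomicInterval("chr1", 10, 50), GenomicInterval("chr1", 100, 150)]),
            PeakSample("b", [GenomicInterval("chr2", 10, 50)]),
        ]
        meta = [MetadataRecord("a", {"f": "x"}), MetadataRecord("b", {"f": "x"})]
        comp = build_peak_compendium(samples, meta)
        assert comp.matrix.tolist() == [[1, 0], [1, 0], [0, 1]]
        assert comp.matrix[:, 0].sum() == 2 and comp.matrix[:, 1].sum() == 1

    def test_own_peaks_always_represented(self, small_synth_peaks):
        _, samples, _, _, comp = small_synth_peaks
        assert (comp.matrix.sum(axis=0) >= 1).all()

    def test_zero_samples_rejected(self):
        with pytest.raises(DataError):
            build_peak_compendium([], [])

    def test_metadata_mismatch_rejected(self, toy_peak_compendium):
        samples, meta, _ = toy_peak_compendium
        with pytest.raises(DataError, match="mismatch"):
            build_peak_compendium(samples, meta[:-1])


class TestExpressionCompendium:
    def test_log2_values_hand_checked(self):
        meta = [MetadataRecord("e", {"a": "1"})]
        comp = build_expression_compendium([ExpressionSample("e", {"g1": 0.0})], meta)
        assert comp.matrix.tolist() == [[0.0]]  # log2(0+1)
        comp = build_expression_compendium([ExpressionSample("e", {"g1": 3.0})], meta)
        assert comp.matrix.tolist() == [[2.0]]  # log2(3+1)

    def test_union_features_and_absent_fill(self):
        samples = [
            ExpressionSample("e1", {"g1": 1.0, "g2": 3.0}),
            ExpressionSample("e2", {"g2": 7.0, "g3": 15.0}),
        ]
        meta = [MetadataRecord("e1", {"a": "1"}), MetadataRecord("e2", {"a": "1"})]
        comp = build_expression_compendium(samples, meta)
        assert comp.features == ["g1", "g2", "g3"]
        # absent entries = log2(0 + 1) = 0
        assert comp.matrix.tolist() == [[1.0, 0.0], [2.0, 3.0], [0.0, 4.0]]

    def test_log_base_options(self):
        meta = [MetadataRecord("e", {"a": "1"})]
        sample = ExpressionSample("e", {"g1": 9.0})
        c10 = build_expression_compendium([sample], meta, log_base=10)
        assert c10.matrix[0, 0] == pytest.approx(1.0)
        ce = build_expression_compendium([sample], meta, log_base="e")
        assert ce.matrix[0, 0] == pytest.approx(math.log(10.0))

    def test_log_transform_is_monotone_within_column(self, small_synth_expression):
        _, samples, _, _, comp = small_synth_expression
        raw = np.array([samples[0].values[g] for g in comp.features])
        col = comp.matrix[:, 0]
        order_raw = np.argsort(raw, kind="stable")
        assert (np.diff(col[order_raw]) >= 0).all()

    def test_pseudocount_below_one_rejected(self):
        with pytest.raises(DataError):
            Transform(kind="log", pseudocount=0.5)


class TestCageCompendium:
    def _meta(self, names):
        return [MetadataRecord(n, {"a": "1"}) for n in names]

    def test_single_interval_log2(self):
        s = PeakSample("c1", [GenomicInterval("chr1", 10, 20, 3.0)], scored=True)
        comp = build_cage_compendium([s], self._meta(["c1"]))
        assert comp.matrix.tolist() == [[2.0]]  # log2(3+1)

    def test_sum_then_log_within_region(self):
        s = PeakSample(
            "c1",
            [GenomicInterval("chr1", 10, 20, 1.0), GenomicInterval("chr1", 15, 30, 2.0)],
            scored=True,
        )
        comp = build_cage_compendium([s], self._meta(["c1"]))
        assert comp.matrix.tolist() == [[2.0]]  # log2(1+2+1)

    def test_region_without_overlap_gets_log_pseudocount(self):
        s1 = PeakSample("c1", [GenomicInterval("chr1", 10, 20, 3.0)], scored=True)
        s2 = PeakSample("c2", [GenomicInterval("chr2", 10, 20, 3.0)], scored=True)
        comp = build_cage_compendium([s1, s2], self._meta(["c1", "c2"]))
        assert comp.matrix[1, 0] == 0.0 and comp.matrix[0, 1] == 0.0

    def test_unscored_sample_rejected(self):
        s = PeakSample("c1", [GenomicInterval("chr1", 10, 20)], scored=False)
        with pytest.raises(DataError, match="unscored"):
            build_cage_compendium([s], self._meta(["c1"]))


class TestSubset:
    def test_filter_selects_matching_columns(self, toy_expression_compendium):
        _, _, comp = toy_expression_compendium
        sub = subset_compendium(comp, {"cell_type": "A"})
        assert sub.experiment_ids == ["e1", "e2"]
        assert np.array_equal(sub.matrix, comp.matrix[:, :2])
        assert sub.features == comp.features  # no feature rebuild

    def test_filter_matching_all_is_identity(self, toy_expression_compendium):
        _, _, comp = toy_expression_compendium
        sub = subset_compendium(comp, {"cell_type": lambda v: True})
        assert sub.experiment_ids == comp.experiment_ids
        assert np.array_equal(sub.matrix, comp.matrix)

    def test_unknown_key_lists_valid_keys(self, toy_expression_compendium):
        _, _, comp = toy_expression_compendium
        with pytest.raises(DataError, match="cell_type"):
            subset_compendium(comp, {"tissue": "brain"})

    def test_zero_matches_rejected(self, toy_expression_compendium):
        _, _, comp = toy_expression_compendium
        with pytest.raises(DataError, match="no experiments match"):
            subset_compendium(comp, {"cell_type": "Z"})

    def test_multi_key_and_collection_values(self, toy_expression_compendium):
        _, _, comp = toy_expression_compendium
        sub = subset_compendium(comp, {"cell_type": ["A", "B"], "factor": "X"})
        assert sub.experiment_ids == ["e1", "e3"]
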