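"""Autozygosity-length law, thresholds, and perfect-homozygosity scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohbench.gmap import uniform_map
from rohbench.popsim import DiploidPopulation, self_offspring
from rohbench.truthmap import (GenerationThreshold, capture_threshold,
                               cm_to_kb, expected_segment_length,
                               map_autozygous_segments)


class TestLengthLaw:
    def test_mean_segment_length_is_half_g_reciprocal(self):
        assert expected_segment_length(2) == pytest.approx(0.25)   # 25 cM
        assert expected_segment_length(50) == pytest.approx(0.01)  # 1 cM
        assert expected_segment_length(1) == pytest.approx(0.5)

    def test_invalid_generation_depth_fails(self):
        with pytest.raises(ValueError):
            expected_segment_length(0)

    def test_80pct_capture_thresholds(self):
        assert capture_threshold(20, 0.8) == 0.55
        assert capture_threshold(50, 0.8) == 0.22

    def test_capture_approaching_one_gives_zero_threshold(self):
        assert capture_threshold(20, 1 - 1e-12) == 0.0

    def test_threshold_decreases_with_generation_depth(self):
        thresholds = [capture_threshold(g, 0.8) for g in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_cm_to_kb_at_the_map_average_rate(self):
        assert cm_to_kb(0.55, 1.3) == 423
        assert cm_to_kb(0.22, 1.3) == 169
        assert cm_to_kb(1.3, 1.3) == 1000

    def test_generation_threshold_bundles_both_units(self):
        thr = GenerationThreshold(20)
        assert (thr.min_len_cm, thr.min_len_kb) == (0.55, 423)


def _population_with_hets(het_lists, positions, region=10_000, rate=1000.0):
    """Individuals homozygous everywhere except the listed variant indices."""
    positions = np.asarray(positions, dtype=np.int64)
    m = positions.size
    haps = []
    for hets in het_lists:
        h1 = np.zeros(m, dtype=np.uint8)
        h2 = np.zeros(m, dtype=np.uint8)
        h2[list(hets)] = 1
        haps.extend([h1, h2])
    return DiploidPopulation(positions, np.asarray(haps),
                             uniform_map(region, rate))


def _brute_force_runs(het_bp, region):
    """Maximal het-free intervals, by direct construction."""
    runs = []
    prev = 0
    for hb in sorted(het_bp):
        if hb > prev:
            runs.append((prev, hb))
        prev = hb + 1
    if prev < region:
        runs.append((prev, region))
    return runs


class TestScan:
    def test_fully_homozygous_individual_spans_the_region(self):
        pop = _population_with_hets([()], np.array([100, 500, 900]),
                                    region=1000)
        truth = map_autozygous_segments(pop, 1e-6)
        np.testing.assert_array_equal(truth.segments[0], [[0, 1000]])
        assert truth.base_rate == pytest.approx(1.0)
        assert truth.mask.all()

    def test_toy_with_two_hets_matches_brute_force(self):
        positions = np.arange(10) * 1000 + 500
        pop = _population_with_hets([(3, 7)], positions, region=10_000)
        truth = map_autozygous_segments(pop, 1e-6)
        expected = _brute_force_runs(positions[[3, 7]], 10_000)
        np.testing.assert_array_equal(truth.segments[0], expected)
        assert not truth.mask[0, 3] and not truth.mask[0, 7]

    def test_threshold_beyond_region_length_gives_no_segments(self):
        pop = _population_with_hets([()], np.array([100, 900]), region=1000,
                                    rate=1.3)
        truth = map_autozygous_segments(pop, 10.0)
        assert len(truth.segments[0]) == 0
        assert truth.base_rate == 0.0

    def test_empty_variant_table_fails(self):
        pop = DiploidPopulation(np.array([], dtype=np.int64),
                                np.zeros((2, 0), dtype=np.uint8),
                                uniform_map(1000))
        with pytest.raises(ValueError):
            map_autozygous_segments(pop, 0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.sets(st.integers(min_value=0, max_value=49), max_size=12),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_toys_match_brute_force_enumeration(self, hets, seed):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(100_000, size=50, replace=False))
        pop = _population_with_hets([hets], positions, region=100_000)
        truth = map_autozygous_segments(pop, 1e-9)
        expected = _brute_force_runs(positions[sorted(hets)], 100_000)
        np.testing.assert_array_equal(truth.segments[0], expected)

    def test_raising_the_threshold_never_adds_coverage(self, small_pop):
        coverages = []
        for thr in (0.05, 0.22, 0.55, 1.5):
            truth = map_autozygous_segments(small_pop, thr)
            coverages.append(truth.base_rate)
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))

    def test_segment_cm_lengths_respect_the_threshold(self, small_pop):
        truth = map_autozygous_segments(small_pop, GenerationThreshold(50))
        for cms in truth.segment_cm:
            assert np.all(cms >= truth.min_len_cm)

    def test_selfed_offspring_carry_more_autozygosity(self, small_pop):
        selfed = self_offspring(small_pop, seed=13, recomb_intensity=66.7)
        base = map_autozygous_segments(small_pop, 0.22).base_rate
        inbred = map_autozygous_segments(selfed, 0.22).base_rate
        assert inbred > base

    def test_mask_at_panel_positions_agrees_with_segments(self, small_pop):
        truth = map_autozygous_segments(small_pop, 0.22)
        probe = np.linspace(0, small_pop.region_length - 1, 200).astype(np.int64)
        mask = truth.mask_at(probe)
        for i in (0, small_pop.n_individuals - 1):
            segs = truth.segments[i]
            expect = np.zeros(probe.size, dtype=bool)
            for s, e in segs:
                expect |= (probe >= s) & (probe < e)
            np.testing.assert_array_equal(mask[i], expect)
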