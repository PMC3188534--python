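"""Sliding-window and block ROH callers against direct enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohbench.panel import MISSING, GenotypePanel
from rohbench.rohcall import (BlockParams, SlidingWindowParams, block_roh,
                              expected_window_snps, plink_grid_params,
                              sliding_window_roh)


def _row_panel(genotypes, spacing=4000):
    g = np.asarray(genotypes, dtype=np.int8)[None, :]
    positions = np.arange(g.shape[1], dtype=np.int64) * spacing
    return GenotypePanel(genotypes=g, positions=positions,
                         cm=positions * 1.3e-6)


def _hom_runs(genotypes, min_len):
    """Maximal runs without het or missing, as (first, last) pairs."""
    runs, start = [], None
    for i, g in enumerate(genotypes):
        if g in (0, 2):
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(genotypes) - start >= min_len:
        runs.append((start, len(genotypes) - 1))
    return runs


class TestSlidingWindow:
    def test_long_clean_run_is_called_in_full(self):
        panel = _row_panel(np.zeros(200))
        p = SlidingWindowParams(window_snps=50, het_allowance=0,
                                missing_allowance=0, min_roh_snps=100)
        calls = sliding_window_roh(panel, p)
        assert len(calls) == 1
        row = calls.calls.iloc[0]
        assert (row.first_snp, row.last_snp, row.n_snps) == (0, 199, 200)

    def test_single_het_blocks_or_passes_with_the_allowance(self):
        g = np.zeros(199)
        g[99] = 1  # 99 hom + 1 het + 99 hom
        p0 = SlidingWindowParams(window_snps=50, het_allowance=0,
                                 missing_allowance=0, min_roh_snps=100)
        assert len(sliding_window_roh(_row_panel(g), p0)) == 0
        p1 = SlidingWindowParams(window_snps=50, het_allowance=1,
                                 missing_allowance=0, min_roh_snps=100)
        calls = sliding_window_roh(_row_panel(g), p1)
        assert len(calls) == 1
        assert calls.calls.iloc[0].n_snps == 199

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_zero_het_allowance_never_calls_a_heterozygous_snp(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.choice([0, 1, 2], size=300, p=[0.45, 0.10, 0.45])
        p = SlidingWindowParams(window_snps=20, het_allowance=0,
                                missing_allowance=0, min_roh_snps=25)
        mask = sliding_window_roh(_row_panel(g), p).mask()[0]
        assert not np.any(mask & (g == 1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=5, max_value=40))
    def test_equivalence_with_run_length_oracle(self, seed, k):
        """window = min SNPs, allowances 0, any-clean-window rule: calls are
        exactly the maximal homozygous runs of length >= k."""
        rng = np.random.default_rng(seed)
        g = rng.choice([0, 1, 2], size=200, p=[0.42, 0.16, 0.42])
        p = SlidingWindowParams(window_snps=k, het_allowance=0,
                                missing_allowance=0, hit_proportion=1e-9,
                                min_roh_snps=k)
        calls = sliding_window_roh(_row_panel(g), p)
        got = list(zip(calls.calls.first_snp, calls.calls.last_snp))
        assert got == _hom_runs(g, k)

    def test_raising_min_roh_snps_never_adds_called_bp(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0, 1, 2], size=500, p=[0.46, 0.08, 0.46])
        panel = _row_panel(g)
        total = [sliding_window_roh(panel, plink_grid_params(t, 0))
                 .total_called_bp() for t in (10, 20, 40, 80)]
        assert all(a >= b for a, b in zip(total, total[1:]))

    def test_window_longer_than_panel_warns_and_calls_nothing(self):
        panel = _row_panel(np.zeros(10))
        p = SlidingWindowParams(window_snps=50, min_roh_snps=50)
        with pytest.warns(UserWarning):
            calls = sliding_window_roh(panel, p)
        assert len(calls) == 0

    def test_missing_allowance_governs_missing_genotypes(self):
        g = np.zeros(120)
        g[60] = MISSING
        strict = SlidingWindowParams(window_snps=40, het_allowance=0,
                                     missing_allowance=0, min_roh_snps=100)
        lax = SlidingWindowParams(window_snps=40, het_allowance=0,
                                  missing_allowance=1, min_roh_snps=100)
        assert len(sliding_window_roh(_row_panel(g), strict)) == 0
        assert len(sliding_window_roh(_row_panel(g), lax)) == 1


class TestGridParams:
    def test_expected_snps_per_cm_window(self):
        assert expected_window_snps(30110, 156, 1) == 193
        assert expected_window_snps(1370, 156, 1) == 9
        assert expected_window_snps(500, 12.5, 12.5) == 500

    def test_invalid_sizes_fail(self):
        with pytest.raises(ValueError):
            expected_window_snps(0, 156, 1)

    def test_window_is_capped_at_fifty_snps(self):
        p = plink_grid_params(200, 1)
        assert (p.window_snps, p.min_roh_snps, p.het_allowance) == (50, 200, 1)
        assert p.missing_allowance == 3  # ceil(5% of 50)


class TestBlock:
    def test_fully_homozygous_row_gives_one_window_aligned_call(self):
        g = np.zeros(600)
        panel = _row_panel(g)  # 600 SNPs * 4 kb = 2.4 Mb ~ 3.1 cM
        p = BlockParams(min_len_cm=1.0, window_snps=9)
        calls = block_roh(panel, p)
        assert len(calls) == 1
        row = calls.calls.iloc[0]
        assert row.first_snp == 0
        assert row.last_snp == (600 // 9) * 9 - 1  # trailing partial ignored

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_window_tagging_matches_a_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.choice([0, 1, 2], size=240, p=[0.44, 0.12, 0.44])
        w = 8
        p = BlockParams(min_len_cm=1e-9, window_snps=w, het_allowance=0)
        calls = block_roh(_row_panel(g), p)
        tags = [not np.any(g[i * w:(i + 1) * w] == 1)
                for i in range(len(g) // w)]
        expected = []
        i = 0
        while i < len(tags):
            if tags[i]:
                j = i
                while j + 1 < len(tags) and tags[j + 1]:
                    j += 1
                expected.append((i * w, (j + 1) * w - 1))
                i = j + 1
            else:
                i += 1
        got = list(zip(calls.calls.first_snp, calls.calls.last_snp))
        assert got == expected

    def test_run_shorter_than_the_cm_threshold_is_not_called(self):
        g = np.ones(300)
        g[100:200] = 0  # tagged stretch ~0.51 cM at 1.3 cM/Mb, 4 kb spacing
        panel = _row_panel(g)
        p = BlockParams(min_len_cm=1.0, window_snps=10)
        assert len(block_roh(panel, p)) == 0
        lax = BlockParams(min_len_cm=0.3, window_snps=10)
        assert len(block_roh(panel, lax)) == 1

    def test_missing_counts_as_het_only_in_strict_mode(self):
        g = np.zeros(100)
        g[25] = MISSING
        panel = _row_panel(g)
        lax = BlockParams(min_len_cm=1e-9, window_snps=10, het_allowance=0)
        strict = BlockParams(min_len_cm=1e-9, window_snps=10, het_allowance=0,
                             missing_is_het=True)
        assert len(block_roh(panel, lax)) == 1
        assert len(block_roh(panel, strict)) == 2

    def test_calls_snap_to_window_boundaries(self):
        rng = np.random.default_rng(8)
        g = rng.choice([0, 1, 2], size=400, p=[0.45, 0.1, 0.45])
        w = 10
        calls = block_roh(_row_panel(g), BlockParams(min_len_cm=1e-9,
                                                     window_snps=w))
        assert np.all(calls.calls.first_snp % w == 0)
        assert np.all((calls.calls.last_snp + 1) % w == 0)
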