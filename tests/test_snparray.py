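"""Array extraction, genotyping-error injection, missingness, and GWAS QC."""

import numpy as np
import pytest
from scipy import stats

from rohbench.gmap import uniform_map
from rohbench.panel import MISSING, GenotypePanel
from rohbench.popsim import DiploidPopulation
from rohbench.snparray import (ArrayDesign, ErrorModel, QCThresholds,
                               hwe_chi2, inject_errors, inject_missing,
                               qc_filter, sample_snps)

from conftest import random_hwe_panel


def _pool_population(m=10_000, n=200, region=40_000_000, seed=0):
    """Synthetic variant pool with uniform allele frequencies, no LD."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.02, 0.5, size=m)
    haps = (rng.random((2 * n, m)) < freqs).astype(np.uint8)
    positions = np.sort(rng.choice(region, size=m, replace=False))
    return DiploidPopulation(positions, haps, uniform_map(region))


class TestSampleSnps:
    def test_design_requesting_everything_returns_all_eligible(self):
        pop = _pool_population(m=500, n=100, region=1_000_000, seed=1)
        design = ArrayDesign(snps_per_window=10_000, seed=2)
        panel = sample_snps(pop, design)
        eligible = np.flatnonzero(pop.maf > design.min_maf)
        np.testing.assert_array_equal(panel.positions,
                                      pop.positions[eligible])

    def test_zero_density_gives_an_empty_panel(self):
        pop = _pool_population(m=200, n=50, region=1_000_000, seed=3)
        panel = sample_snps(pop, ArrayDesign(snps_per_window=0.0, seed=0))
        assert panel.n_snps == 0

    def test_realized_maf_bins_match_a_uniform_target(self):
        """Chi-square goodness of fit of drawn bin counts vs the design."""
        pop = _pool_population(m=10_000, n=400, seed=4)
        edges = (0.05, 0.14, 0.23, 0.32, 0.41, 0.5)
        design = ArrayDesign(maf_bin_edges=edges,
                             maf_bin_props=(0.2,) * 5,
                             snps_per_window=10, window_kb=400,  # 1000 draws
                             seed=5)
        panel = sample_snps(pop, design)
        assert panel.n_snps == pytest.approx(1000, abs=30)
        bins = np.clip(np.searchsorted(edges, panel.maf, side="right") - 1,
                       0, 4)
        counts = np.bincount(bins, minlength=5)
        expected = np.full(5, counts.sum() / 5)
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.001

    def test_snp_positions_inherit_sequence_coordinates(self, small_pop):
        panel = sample_snps(small_pop, ArrayDesign(snps_per_window=20, seed=6))
        assert np.all(np.isin(panel.positions, small_pop.positions))
        assert np.all(np.diff(panel.positions) > 0)
        np.testing.assert_allclose(
            panel.cm, np.asarray(small_pop.gmap.cm_at(panel.positions)))


class TestErrors:
    def test_zero_rate_leaves_the_panel_unchanged(self, hwe_panel):
        out = inject_errors(hwe_panel, ErrorModel(overall_rate=0.0, seed=1))
        np.testing.assert_array_equal(out.genotypes, hwe_panel.genotypes)

    def test_realized_rates_and_het_hom_asymmetry(self):
        panel = random_hwe_panel(1000, 1000, seed=21)
        model = ErrorModel(overall_rate=0.01, het_to_hom_ratio=3.0, seed=22)
        out = inject_errors(panel, model)
        g0, g1 = panel.genotypes, out.genotypes
        changed = g0 != g1
        n = g0.size
        se = np.sqrt(0.01 * 0.99 / n)
        assert changed.mean() == pytest.approx(0.01, abs=3 * se)
        e_het = changed[g0 == 1].mean()
        e_hom = changed[g0 != 1].mean()
        assert e_het / e_hom == pytest.approx(3.0, rel=0.1)

    def test_miscalled_homozygotes_always_become_heterozygous(self):
        panel = random_hwe_panel(400, 400, seed=23)
        out = inject_errors(panel, ErrorModel(overall_rate=0.05, seed=24))
        g0, g1 = panel.genotypes, out.genotypes
        hom_err = (g0 == 0) & (g0 != g1)
        assert hom_err.any()
        assert np.all(g1[hom_err] == 1)  # never hom-ref -> hom-alt
        het_err = (g0 == 1) & (g0 != g1)
        assert set(np.unique(g1[het_err])) <= {0, 2}

    def test_positions_and_alleles_are_untouched(self, hwe_panel):
        out = inject_errors(hwe_panel, ErrorModel(overall_rate=0.05, seed=3))
        np.testing.assert_array_equal(out.positions, hwe_panel.positions)
        np.testing.assert_array_equal(out.ref, hwe_panel.ref)

    def test_panel_with_missing_codes_is_rejected(self, hwe_panel):
        broken = hwe_panel.copy()
        broken.genotypes[0, 0] = MISSING
        with pytest.raises(ValueError):
            inject_errors(broken, ErrorModel(overall_rate=0.01))


class TestMissing:
    def test_zero_rate_is_identity(self, hwe_panel):
        out = inject_missing(hwe_panel, 0.0, seed=1)
        np.testing.assert_array_equal(out.genotypes, hwe_panel.genotypes)

    def test_realized_missingness_matches_the_nominal_rate(self):
        panel = random_hwe_panel(1000, 1000, seed=31)
        out = inject_missing(panel, 0.008, seed=32)
        realized = (out.genotypes == MISSING).mean()
        se = np.sqrt(0.008 * 0.992 / panel.genotypes.size)
        assert realized == pytest.approx(0.008, abs=3 * se)

    def test_near_total_missingness_leaves_nothing_after_qc(self):
        panel = random_hwe_panel(100, 50, seed=33)
        out = inject_missing(panel, 0.95, seed=34)
        cleaned, report = qc_filter(out)
        assert cleaned.n_snps == 0 or cleaned.n_individuals == 0


class TestQC:
    def _panel_from_counts(self, n0, n1, n2):
        g = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2)])
        return GenotypePanel(genotypes=g[:, None].astype(np.int8),
                             positions=np.array([10]), cm=np.array([0.0]))

    def test_hardy_weinberg_proportions_are_kept(self):
        panel = self._panel_from_counts(25, 50, 25)
        chi2, p = hwe_chi2([25], [50], [25])
        assert chi2[0] == pytest.approx(0.0)
        cleaned, _ = qc_filter(panel)
        assert cleaned.n_snps == 1

    def test_total_heterozygote_deficit_is_dropped(self):
        panel = self._panel_from_counts(50, 0, 50)
        chi2, p = hwe_chi2([50], [0], [50])
        assert chi2[0] == pytest.approx(100.0)
        assert p[0] == pytest.approx(1.5e-23, rel=0.1)
        cleaned, report = qc_filter(panel)
        assert cleaned.n_snps == 0
        assert report.set_index("step").loc["hwe", "n_dropped"] == 1

    def test_rare_variant_is_dropped_by_the_maf_floor(self):
        g = np.zeros((1000, 1), dtype=np.int8)
        g[0, 0] = 1  # one minor allele among 2,000
        panel = GenotypePanel(genotypes=g, positions=np.array([5]),
                              cm=np.array([0.0]))
        assert panel.maf[0] == pytest.approx(0.0005)
        cleaned, report = qc_filter(panel)
        assert cleaned.n_snps == 0
        assert report.set_index("step").loc["maf", "n_dropped"] == 1

    def test_step_accounting_conserves_the_snp_total(self):
        panel = random_hwe_panel(300, 400, seed=41, maf_low=0.001)
        noisy = inject_missing(panel, 0.03, seed=42)
        cleaned, report = qc_filter(noisy)
        snp_drops = report.set_index("step")["n_dropped"]
        assert (snp_drops[["snp_missingness", "maf", "hwe"]].sum()
                + cleaned.n_snps == panel.n_snps)

    def test_qc_order_individuals_before_snps(self):
        # one individual missing half its genotypes must go first,
        # rescuing SNPs that would otherwise fail the missingness step
        rng = np.random.default_rng(43)
        g = rng.binomial(2, 0.3, size=(60, 40)).astype(np.int8)
        g[0, ::2] = MISSING
        panel = GenotypePanel(genotypes=g,
                              positions=np.arange(40) * 100,
                              cm=np.arange(40) * 1e-4)
        cleaned, report = qc_filter(panel)
        assert report.set_index("step").loc["individual_missingness",
                                            "n_dropped"] == 1
        assert cleaned.n_snps == 40
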