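"""SNP-array extraction from sequence data, error injection, and GWAS QC.

Sequence-level variant data carries every polymorphism; a genotyping array
measures only a common-SNP subset with a characteristic minor-allele-
frequency spectrum and spatial density.  :func:`sample_snps` performs
stratified sampling (per density window, apportioned across MAF bins) to
mimic an Affymetrix-6.0-like panel; :func:`inject_errors` adds genotyping
error with the empirically observed ~3x excess of het->hom over hom->het
miscalls; :func:`inject_missing` adds missingness; and :func:`qc_filter`
applies the standard GWAS cleaning cascade (individual missingness, SNP
missingness, MAF, Hardy-Weinberg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel
from .popsim import DiploidPopulation

__all__ = [
    "ArrayDesign",
    "ErrorModel",
    "QCThresholds",
    "default_design",
    "sample_snps",
    "inject_errors",
    "inject_missing",
    "qc_filter",
    "hwe_chi2",
]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ArrayDesign:
    """Target MAF spectrum and spatial density of the extracted panel.

    ``maf_bin_edges`` / ``maf_bin_props`` define the target MAF histogram
    (proportions sum to 1, bins within (0, 0.5]); ``snps_per_window`` SNPs
    are drawn in every ``window_kb`` window, apportioned across the bins by
    largest remainder.
    """

    maf_bin_edges: tuple = (0.01, 0.05, 0.14, 0.23, 0.32, 0.41, 0.5)
    maf_bin_props: tuple = (0.15, 0.17, 0.17, 0.17, 0.17, 0.17)
    snps_per_window: float = 25.0
    window_kb: float = 100.0
    min_maf: float = 0.01
    seed: int = 0

    def __post_init__(self):
        edges = np.asarray(self.maf_bin_edges, dtype=float)
        props = np.asarray(self.maf_bin_props, dtype=float)
        if edges.size != props.size + 1:
            raise ValueError("need one more bin edge than proportion")
        if np.any(np.diff(edges) <= 0) or edges[0] <= 0 or edges[-1] > 0.5:
            raise ValueError("MAF bins must be increasing within (0, 0.5]")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("histogram proportions must sum to 1")


def default_design(**overrides) -> ArrayDesign:
    """The shipped array design: 25 SNPs per 100 kb, a 15% mass tail in
    [0.01, 0.05) and the rest spread uniformly over [0.05, 0.5]."""
    return ArrayDesign(**overrides)


@dataclass(frozen=True)
class ErrorModel:
    """Genotyping-error model with asymmetric het/hom miscall rates.

    ``overall_rate`` is the marginal per-genotype miscall probability;
    heterozygous genotypes are miscalled (to a random homozygote) at
    ``het_to_hom_ratio`` times the rate at which homozygous genotypes are
    miscalled to heterozygotes.
    """

    overall_rate: float = 0.002
    het_to_hom_ratio: float = 3.0
    missing_rate: float = 0.008
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overall_rate < 1.0:
            raise ValueError("overall_rate must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.het_to_hom_ratio <= 0:
            raise ValueError("het_to_hom_ratio must be positive")


@dataclass(frozen=True)
class QCThresholds:
    max_ind_missing: float = 0.05
    max_snp_missing: float = 0.02
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-4


# ----------------------------------------------------------------------
def panel_from_population(pop: DiploidPopulation, snp_idx: np.ndarray,
                          rng: np.random.Generator | None = None) -> GenotypePanel:
    """Materialize a genotype panel from selected sequence variants."""
    snp_idx = np.asarray(snp_idx, dtype=np.int64)
    rng = rng if rng is not None else np.random.default_rng(0)
    m = snp_idx.size
    ref = _ALLELES[rng.integers(4, size=m)]
    alt_off = rng.integers(1, 4, size=m)
    alt = _ALLELES[(np.searchsorted(_ALLELES, ref) + alt_off) % 4]
    # keep letter pair sorted so PED round trips are unambiguous; the
    # labels are cosmetic, code 0 always means homozygous-ancestral
    swap = ref > alt
    ref2 = np.where(swap, alt, ref)
    alt2 = np.where(swap, ref, alt)
    return GenotypePanel(
        genotypes=pop.dosages()[:, snp_idx],
        positions=pop.positions[snp_idx],
        cm=np.asarray(pop.gmap.cm_at(pop.positions[snp_idx])),
        ref=ref2, alt=alt2,
        region_length=pop.region_length,
    )


def sample_snps(pop: DiploidPopulation, design: ArrayDesign) -> GenotypePanel:
    """Stratified draw of an array-like SNP subset from sequence variants.

    Within each density window the target SNP count is apportioned across
    MAF bins by largest remainder; when a bin lacks variants the shortfall
    moves to the nearest bin (with a warning, never silently).
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    maf = pop.maf
    eligible = maf > design.min_maf
    edges = np.asarray(design.maf_bin_edges)
    n_bins = edges.size - 1
    window_bp = int(design.window_kb * 1000)
    L = pop.region_length
    n_windows = max(1, int(np.ceil(L / window_bp)))
    chosen: list[np.ndarray] = []
    fallback_warned = False
    for w in range(n_windows):
        lo_bp, hi_bp = w * window_bp, min((w + 1) * window_bp, L)
        lo, hi = np.searchsorted(pop.positions, [lo_bp, hi_bp])
        idx = np.arange(lo, hi)[eligible[lo:hi]]
        if not idx.size:
            continue
        target = int(round(design.snps_per_window * (hi_bp - lo_bp) / window_bp))
        if target <= 0:
            continue
        if target >= idx.size:
            chosen.append(idx)  # design asks for everything available
            continue
        bins = np.clip(np.searchsorted(edges, maf[idx], side="right") - 1,
                       0, n_bins - 1)
        want = _largest_remainder(np.asarray(design.maf_bin_props) * target)
        got: list[np.ndarray] = []
        short = 0
        # first pass: draw what each bin can supply
        avail = [idx[bins == b] for b in range(n_bins)]
        for b in range(n_bins):
            take = min(want[b], avail[b].size)
            if take:
                got.append(rng.choice(avail[b], size=take, replace=False))
            short += want[b] - take
            avail[b] = np.setdiff1d(avail[b], got[-1] if take else [])
        # shortfall: move to nearest bins with remaining variants
        while short > 0:
            remaining = np.concatenate([a for a in avail if a.size]) \
                if any(a.size for a in avail) else np.empty(0, dtype=np.int64)
            if not remaining.size:
                break
            if not fallback_warned:
                warnings.warn("MAF bin shortfall: reallocating draws to "
                              "nearest available bins", stacklevel=2)
                fallback_warned = True
            take = min(short, remaining.size)
            extra = rng.choice(remaining, size=take, replace=False)
            got.append(extra)
            avail = [np.setdiff1d(a, extra) for a in avail]
            short -= take
        if got:
            chosen.append(np.concatenate(got))
    if not chosen:
        snp_idx = np.empty(0, dtype=np.int64)
    else:
        snp_idx = np.sort(np.concatenate(chosen))
    return panel_from_population(pop, snp_idx, rng)


def _largest_remainder(quota: np.ndarray) -> np.ndarray:
    """Integer apportionment preserving the total (largest-remainder rule)."""
    base = np.floor(quota).astype(int)
    short = int(round(quota.sum())) - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


# ----------------------------------------------------------------------
def inject_errors(panel: GenotypePanel, model: ErrorModel) -> GenotypePanel:
    """Apply asymmetric genotype miscalls; returns a new panel.

    The per-het miscall rate ``e_het`` is solved from the marginal rate:
    ``overall = f_het * e_het + (1 - f_het) * e_het / ratio`` with ``f_het``
    the realized het fraction.  Erring hets become one of the two homozygous
    codes equiprobably; erring homozygotes always become het.
    """
    if panel.missing_mask.any():
        raise ValueError("inject_errors expects a panel without missing codes")
    if model.overall_rate == 0.0:
        return panel.copy()
    g = panel.genotypes
    f_het = float(np.mean(g == 1))
    e_het = model.overall_rate / (f_het + (1.0 - f_het) / model.het_to_hom_ratio)
    e_hom = e_het / model.het_to_hom_ratio
    if e_het >= 1.0:
        raise ValueError("solved het error rate >= 1; lower overall_rate")
    rng = np.random.default_rng(model.seed)
    u = rng.random(g.shape)
    coin = rng.integers(2, size=g.shape).astype(np.int8)
    out = g.copy()
    het_err = (g == 1) & (u < e_het)
    out[het_err] = 2 * coin[het_err]          # 0 or 2 equiprobably
    hom_err = (g != 1) & (u < e_hom)
    out[hom_err] = 1
    new = panel.copy()
    new.genotypes = out
    return new


def inject_missing(panel: GenotypePanel, rate: float,
                   seed: int | None = None) -> GenotypePanel:
    """Set each genotype to missing independently with the given rate."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    new = panel.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        new.genotypes[rng.random(new.genotypes.shape) < rate] = MISSING
    return new


# ----------------------------------------------------------------------
def hwe_chi2(n_hom_ref: np.ndarray, n_het: np.ndarray,
             n_hom_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain 1-df Hardy-Weinberg chi-square from genotype counts.

    Expected counts come from the allele frequencies of the non-missing
    genotypes; no continuity correction.
    """
    n0 = np.asarray(n_hom_ref, dtype=float)
    n1 = np.asarray(n_het, dtype=float)
    n2 = np.asarray(n_hom_alt, dtype=float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n0 + n1) / (2 * n)
        q = 1.0 - p
        e = np.stack([n * p**2, 2 * n * p * q, n * q**2])
        o = np.stack([n0, n1, n2])
        terms = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    chi2 = np.where(n > 0, chi2, 0.0)
    pval = stats.chi2.sf(chi2, df=1)
    return chi2, pval


def qc_filter(panel: GenotypePanel,
              thr: QCThresholds = QCThresholds()) -> tuple[GenotypePanel, pd.DataFrame]:
    """Standard GWAS cleaning cascade; returns the panel and a step report.

    Order: (1) individuals with missing fraction > ``max_ind_missing``;
    (2) SNPs with missing fraction > ``max_snp_missing``; (3) SNPs with
    MAF < ``min_maf``; (4) SNPs with HWE chi-square p < ``hwe_p_floor``.
    """
    report_rows = []
    n0, m0 = panel.n_individuals, panel.n_snps

    miss_ind = panel.missing_mask.mean(axis=1) if panel.n_snps else \
        np.zeros(panel.n_individuals)
    keep_ind = np.flatnonzero(miss_ind <= thr.max_ind_missing)
    report_rows.append(("individual_missingness", n0 - keep_ind.size, keep_ind.size, m0))
    panel = panel.subset(individuals=keep_ind)

    miss_snp = panel.missing_mask.mean(axis=0) if panel.n_individuals else \
        np.ones(panel.n_snps)
    keep = np.flatnonzero(miss_snp <= thr.max_snp_missing)
    report_rows.append(("snp_missingness", panel.n_snps - keep.size,
                        panel.n_individuals, keep.size))
    panel = panel.subset(snps=keep)

    keep = np.flatnonzero(panel.maf >= thr.min_maf)
    report_rows.append(("maf", panel.n_snps - keep.size,
                        panel.n_individuals, keep.size))
    panel = panel.subset(snps=keep)

    g = panel.genotypes
    counts = [np.sum(g == c, axis=0) for c in (0, 1, 2)]
    _, pvals = hwe_chi2(*counts)
    keep = np.flatnonzero(pvals >= thr.hwe_p_floor)
    report_rows.append(("hwe", panel.n_snps - keep.size,
                        panel.n_individuals, keep.size))
    panel = panel.subset(snps=keep)

    report = pd.DataFrame(report_rows, columns=["step", "n_dropped",
                                                "n_individuals", "n_snps"])
    return panel, report
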