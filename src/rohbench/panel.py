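"""The SNP genotype panel container shared across the pipeline.

Genotypes are coded ``0`` (homozygous reference), ``1`` (heterozygous),
``2`` (homozygous alternate) and ``-1`` (missing) in an
``(individuals, SNPs)`` int8 matrix, with per-SNP bp and cM positions and
allele labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenotypePanel", "MISSING"]

MISSING: int = -1


@dataclass
class GenotypePanel:
    genotypes: np.ndarray              # (n, m) int8 in {0, 1, 2, -1}
    positions: np.ndarray              # (m,) bp, strictly increasing
    cm: np.ndarray                     # (m,) genetic positions
    ref: np.ndarray = None             # (m,) reference allele letters
    alt: np.ndarray = None             # (m,) alternate allele letters
    snp_ids: np.ndarray = None
    sample_ids: np.ndarray = None
    region_length: int | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        n, m = self.genotypes.shape
        if self.positions.size != m or self.cm.size != m:
            raise ValueError("per-SNP arrays do not match the genotype matrix")
        if m > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes restricted to {0, 1, 2, -1}")
        if self.ref is None:
            self.ref = np.full(m, "A", dtype="U1")
        if self.alt is None:
            self.alt = np.full(m, "G", dtype="U1")
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{p}" for p in self.positions])
        if self.sample_ids is None:
            self.sample_ids = np.array([f"ind{i}" for i in range(n)])
        self.snp_ids = np.asarray(self.snp_ids)
        self.sample_ids = np.asarray(self.sample_ids)

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, missing genotypes excluded."""
        g = self.genotypes
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt_count = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_called > 0, alt_count / (2.0 * n_called), 0.0)
        return np.minimum(f, 1.0 - f)

    def dosages_imputed(self) -> np.ndarray:
        """Float dosage matrix with per-SNP mean imputation of missing."""
        g = self.genotypes.astype(np.float64)
        miss = self.genotypes == MISSING
        if miss.any():
            g[miss] = np.nan
            col_mean = np.nanmean(np.where(miss, np.nan, g), axis=0)
            col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
            g = np.where(miss, col_mean[np.newaxis, :], g)
        return g

    def subset(self, individuals=None, snps=None) -> "GenotypePanel":
        ind = np.arange(self.n_individuals) if individuals is None \
            else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypePanel(
            genotypes=self.genotypes[np.ix_(ind, snp)],
            positions=self.positions[snp],
            cm=self.cm[snp],
            ref=self.ref[snp],
            alt=self.alt[snp],
            snp_ids=self.snp_ids[snp],
            sample_ids=self.sample_ids[ind],
            region_length=self.region_length,
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.genotypes.copy(), self.positions.copy(),
                             self.cm.copy(), self.ref.copy(), self.alt.copy(),
                             self.snp_ids.copy(), self.sample_ids.copy(),
                             self.region_length)
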