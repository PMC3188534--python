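"""End-to-end desk-scale benchmarking pipeline.

Chains the stages: forward simulation -> truth autozygosity maps ->
SNP-array extraction with genotyping error and missingness -> GWAS QC ->
LD pruning at several strengths -> sliding-window and block ROH calling
over a threshold grid -> per-SNP error rates and d' -> burden-regression
power.  The output is one table shaped like a caller-comparison report:
one row per (caller, threshold, het allowance, pruning level, error level,
generation depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .evalmetrics import confusion
from .gmap import build_genetic_map
from .ldprune import PruneParams, vif_prune
from .panel import GenotypePanel
from .popsim import SimConfig, simulate_population
from .powersim import PowerConfig, simulate_power
from .rohcall import (BlockParams, block_roh, expected_window_snps,
                      plink_grid_params, sliding_window_roh)
from .snparray import (ArrayDesign, ErrorModel, QCThresholds, inject_errors,
                       inject_missing, qc_filter, sample_snps)
from .truthmap import GenerationThreshold, map_autozygous_segments

logger = logging.getLogger(__name__)

__all__ = ["GridConfig", "run_grid", "evaluate_panel", "power_from_rates"]


@dataclass(frozen=True)
class GridConfig:
    """A scaled-down benchmarking sweep over callers and thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    design: ArrayDesign = field(default_factory=ArrayDesign)
    error_rates: tuple = (0.002, 0.01)
    missing_rate: float = 0.008
    generations: tuple = (20, 50)
    capture: float = 0.8
    prune_levels: tuple = ("none", "light", "moderate", "heavy")
    snp_thresholds: tuple = (15, 25, 50, 75, 100)
    het_allowances: tuple = (0, 1)
    block_min_cm: tuple = (0.25, 0.5, 1.0, 2.0)
    callers: tuple = ("sliding", "block")
    power_n_reps: int = 1000
    seed: int = 0


def power_from_rates(type1: float, detect_rate: float, g: int,
                     base_rate: float, *, capture: float = 0.8,
                     rate_cm_per_mb: float = 1.3, n_reps: int = 1000,
                     seed: int = 0) -> float:
    """Burden power for measured error rates on the g-generation segment grid."""
    thr = GenerationThreshold(g, capture, rate_cm_per_mb)
    cfg = PowerConfig(type1=type1, detect_rate=detect_rate,
                      base_rate=base_rate, segment_kb=thr.min_len_kb,
                      n_reps=n_reps, seed=seed)
    return simulate_power(cfg).power


def evaluate_panel(panel: GenotypePanel, truth, callset) -> dict:
    """Per-SNP confusion of a call set against a truth map on one panel."""
    truth_mask = truth.mask_at(panel.positions)
    rates = confusion(truth_mask, callset.mask())
    return {
        "type1": rates.type1,
        "type2": rates.type2,
        "d_prime": rates.d_prime() if rates.type1 is not None
        and rates.type2 is not None else np.nan,
        "tp": rates.tp, "fp": rates.fp, "tn": rates.tn, "fn": rates.fn,
    }


def run_grid(cfg: GridConfig) -> pd.DataFrame:
    """Run the full benchmarking sweep; returns the evaluation/power table."""
    seed = cfg.seed
    gmap = build_genetic_map(cfg.sim.region_length,
                             seed=io.stage_seed(seed, "map"))
    sim_cfg = _with_seed(cfg.sim, io.stage_seed(seed, "sim"))
    logger.info("simulating population (%d bp region)", cfg.sim.region_length)
    pop = simulate_population(sim_cfg, gmap)
    logger.info("population: %d individuals, %d variants",
                pop.n_individuals, pop.n_variants)

    truths = {g: map_autozygous_segments(
        pop, GenerationThreshold(g, cfg.capture)) for g in cfg.generations}
    for g, t in truths.items():
        logger.info("truth (%d generations): base rate %.4f%%",
                    g, 100 * t.base_rate)

    design = ArrayDesign(**{**_public_fields(cfg.design),
                            "seed": io.stage_seed(seed, "design")})
    base_panel = sample_snps(pop, design)
    logger.info("extracted panel: %d SNPs", base_panel.n_snps)

    rows = []
    for err_rate in cfg.error_rates:
        model = ErrorModel(overall_rate=err_rate,
                           missing_rate=cfg.missing_rate,
                           seed=io.stage_seed(seed, f"err{err_rate}"))
        noisy = inject_errors(base_panel, model)
        noisy = inject_missing(noisy, cfg.missing_rate,
                               seed=io.stage_seed(seed, f"miss{err_rate}"))
        clean, report = qc_filter(noisy, QCThresholds())
        logger.info("error level %s: %d SNPs after QC", err_rate, clean.n_snps)

        panels: dict[str, GenotypePanel] = {}
        for level in cfg.prune_levels:
            if level == "none":
                panels[level] = clean
            else:
                kept, _ = vif_prune(clean, PruneParams.level(level))
                panels[level] = clean.subset(snps=kept)
                logger.info("pruning %s: %d SNPs kept", level, kept.size)

        for level, panel in panels.items():
            total_cm = float(panel.cm[-1] - panel.cm[0]) if panel.n_snps else 0.0
            callsets = {}
            if "sliding" in cfg.callers:
                for thr in cfg.snp_thresholds:
                    for het in cfg.het_allowances:
                        p = plink_grid_params(thr, het)
                        callsets[("sliding", f"{thr} SNPs", het)] = \
                            sliding_window_roh(panel, p)
            if "block" in cfg.callers:
                for min_cm in cfg.block_min_cm:
                    w = expected_window_snps(panel.n_snps, total_cm, min_cm) \
                        if total_cm > 0 else 1
                    for het in cfg.het_allowances:
                        p = BlockParams(min_len_cm=min_cm, window_snps=w,
                                        het_allowance=het)
                        callsets[("block", f"{min_cm} cM", het)] = \
                            block_roh(panel, p)

            for (caller, thr_label, het), callset in callsets.items():
                for g in cfg.generations:
                    ev = evaluate_panel(panel, truths[g], callset)
                    if ev["type1"] is None or ev["type2"] is None:
                        continue
                    power = power_from_rates(
                        ev["type1"], 1.0 - ev["type2"], g,
                        truths[g].base_rate, capture=cfg.capture,
                        n_reps=cfg.power_n_reps,
                        seed=io.stage_seed(seed, f"pw{caller}{thr_label}"
                                           f"{het}{level}{err_rate}{g}"))
                    rows.append({
                        "caller": caller, "threshold": thr_label,
                        "het_allowance": het, "pruning": level,
                        "error_rate": err_rate, "generations": g,
                        "n_snps": panel.n_snps, "power": power,
                        "type1": ev["type1"], "type2": ev["type2"],
                        "d_prime": ev["d_prime"],
                        "n_calls": len(callset),
                        "mean_call_kb": (callset.calls["length_kb"].mean()
                                         if len(callset) else 0.0),
                    })
    return pd.DataFrame(rows)


def _with_seed(sim: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace
    return replace(sim, seed=seed)


def _public_fields(design: ArrayDesign) -> dict:
    return {k: getattr(design, k) for k in
            ("maf_bin_edges", "maf_bin_props", "snps_per_window",
             "window_kb", "min_maf")}
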