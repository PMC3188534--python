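"""Shared fixtures: simulated populations at two scales and toy panels."""

from __future__ import annotations

import numpy as np
import pytest

from rohbench.gmap import build_genetic_map, uniform_map
from rohbench.panel import GenotypePanel
from rohbench.popsim import DiploidPopulation, SimConfig, simulate_population

# The desk-scale benchmark conditions used by the end-to-end checks:
# 4 Mb chromosome, rescale factor 32 (N 10,000 -> 312), the European-style
# bottleneck (800 for 200 generations) and recovery, final reduction to
# 6,500, 50-generation mutational freeze, 200 sampled individuals.
DESK_SIM = SimConfig(
    region_length=4_000_000,
    effective_size_schedule=((60_000, 10_000), (200, 800),
                             (2_000, 10_000), (400, 6_500)),
    rescale_factor=32.0,
    freeze_generations=50,
    sample_size=200,
    seed=3,
)


@pytest.fixture(scope="session")
def desk_map():
    return build_genetic_map(DESK_SIM.region_length, seed=2)


@pytest.fixture(scope="session")
def desk_pop(desk_map) -> DiploidPopulation:
    """The desk-scale population (about a minute to simulate; shared)."""
    return simulate_population(DESK_SIM, desk_map)


@pytest.fixture(scope="session")
def small_pop() -> DiploidPopulation:
    """A cheap bottlenecked population for statistical checks (seconds)."""
    cfg = SimConfig(
        region_length=1_500_000,
        effective_size_schedule=((40_000, 10_000), (200, 800),
                                 (2_000, 10_000)),
        rescale_factor=66.7,
        freeze_generations=10,
        sample_size=100,
        seed=7,
    )
    gmap = build_genetic_map(cfg.region_length, seed=7)
    return simulate_population(cfg, gmap)


def random_hwe_panel(n: int, m: int, seed: int, *, spacing: int = 1000,
                     maf_low: float = 0.05, maf_high: float = 0.5) -> GenotypePanel:
    """Independent SNPs in Hardy-Weinberg proportions (no LD)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=m)
    genotypes = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    positions = np.arange(m, dtype=np.int64) * spacing
    gmap = uniform_map(int(positions[-1] + spacing))
    return GenotypePanel(genotypes=genotypes, positions=positions,
                         cm=np.asarray(gmap.cm_at(positions)),
                         region_length=gmap.region_length)


@pytest.fixture
def hwe_panel() -> GenotypePanel:
    return random_hwe_panel(500, 80, seed=11)
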