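"""Desk-scale forward-time Wright-Fisher diploid simulator.

The simulator evolves a monoecious diploid population over discrete,
non-overlapping generations: random mating with replacement, gametes formed
by crossover sampling from a hotspot recombination map, optional gene
conversion, and infinite-sites mutation at integer bp positions.  Population
size changes follow an explicit epoch schedule (e.g. a European-style
bottleneck followed by recovery), and new mutation can be switched off for
the final generations (a "mutational freeze") so that recently autozygous
tracts remain perfectly homozygous at the sequence level.

Everything is rescaled to desk scale by a factor ``lambda``: population
sizes and epoch durations are divided by ``lambda`` while mutation,
recombination and gene-conversion rates are multiplied by it, preserving the
population-scaled parameters theta = 4*N*mu and rho = 4*N*r.  Haplotypes are
stored sparsely as sorted integer arrays of carried derived-allele
positions.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .gmap import GeneticMap, build_genetic_map

__all__ = [
    "SimConfig",
    "DiploidPopulation",
    "ForwardSimulator",
    "simulate_population",
    "sample_individuals",
    "self_offspring",
    "desk_config",
    "nucleotide_diversity",
    "ld_r2_curve",
    "build_genetic_map",
    "GeneticMap",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration for a forward simulation, in *unrescaled* units.

    ``effective_size_schedule`` is a list of ``(generations, N)`` epochs in
    unrescaled generations and diploid individuals; the rescale factor
    ``rescale_factor`` (lambda) is applied inside the simulator.  The
    mutational-freeze window ``freeze_generations`` is counted in *simulated*
    (already rescaled) generations and is deliberately not rescaled: its job
    is to guarantee perfect sequence-level homozygosity of recently
    coalesced tracts, which live on the rescaled time scale.
    """

    region_length: int = 10_000_000
    effective_size_schedule: tuple = ((100_000, 10_000), (200, 800),
                                      (2_000, 10_000), (500, 6_500))
    mutation_rate: float = 2.3e-8
    gene_conversion_rate: float = 0.0  # off by default at desk scale
    gene_conversion_length: int = 500
    rescale_factor: float = 50.0
    freeze_generations: int = 50
    sample_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")
        for rate in (self.mutation_rate, self.gene_conversion_rate):
            if not np.isfinite(rate) or rate < 0:
                raise ValueError("rates must be finite and non-negative")
        if not self.effective_size_schedule:
            raise ValueError("empty size schedule")

    def rescaled_schedule(self) -> list[tuple[int, int]]:
        lam = self.rescale_factor
        out = []
        for gens, n in self.effective_size_schedule:
            n_scaled = max(2, int(round(n / lam)))
            g_scaled = max(1, int(round(gens / lam)))
            out.append((g_scaled, n_scaled))
        total = sum(g for g, _ in out)
        if self.freeze_generations >= total:
            raise ValueError("freeze_generations must be shorter than the run")
        return out


def desk_config(**overrides) -> SimConfig:
    """The shipped desk-scale default configuration.

    10 Mb region, lambda = 50: burn-in 2,000 generations at N = 200,
    bottleneck to 16 for 4 generations, recovery at 200 for 40 generations,
    then a final reduction to 130, with a 50-generation mutational freeze.
    """
    return SimConfig(**overrides)


class DiploidPopulation:
    """A sampled diploid population over a biallelic variant table.

    ``haplotypes`` is a dense ``(2 * n_individuals, n_variants)`` uint8
    matrix of derived-allele indicators; rows ``2i`` and ``2i + 1`` are the
    two haplotypes of individual ``i``.  Positions are 0-based bp,
    strictly increasing.
    """

    def __init__(self, positions: np.ndarray, haplotypes: np.ndarray,
                 gmap: GeneticMap,
                 origin_generation: np.ndarray | None = None):
        positions = np.asarray(positions, dtype=np.int64)
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2 or haplotypes.shape[1] != positions.size:
            raise ValueError("haplotype matrix does not match variant table")
        if haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be 2 per individual")
        if positions.size > 1 and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.positions = positions
        self.haplotypes = haplotypes
        self.gmap = gmap
        self.origin_generation = (np.asarray(origin_generation, dtype=np.int64)
                                  if origin_generation is not None else
                                  np.full(positions.size, -1, dtype=np.int64))

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.positions.size

    @property
    def region_length(self) -> int:
        return self.gmap.region_length

    @property
    def derived_freq(self) -> np.ndarray:
        if self.haplotypes.shape[0] == 0:
            return np.zeros(self.n_variants)
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.derived_freq
        return np.minimum(f, 1.0 - f)

    def dosages(self) -> np.ndarray:
        """(n_individuals, n_variants) int8 derived-allele dosage matrix."""
        return (self.haplotypes[0::2].astype(np.int8)
                + self.haplotypes[1::2].astype(np.int8))

    def het_mask(self) -> np.ndarray:
        """(n_individuals, n_variants) bool: heterozygous at sequence level."""
        return self.haplotypes[0::2] != self.haplotypes[1::2]

    @property
    def cm(self) -> np.ndarray:
        return np.asarray(self.gmap.cm_at(self.positions))


def nucleotide_diversity(pop: DiploidPopulation) -> float:
    """Mean pairwise difference per bp (unbiased estimator of theta)."""
    n = pop.haplotypes.shape[0]
    if n < 2:
        return 0.0
    f = pop.derived_freq
    pi = np.sum(2.0 * f * (1.0 - f)) * n / (n - 1)
    return float(pi / pop.region_length)


# ----------------------------------------------------------------------
class ForwardSimulator:
    """Mutable Wright-Fisher population state with per-generation stepping.

    Haplotypes are sorted int64 arrays of derived-mutation positions and are
    treated as immutable once created, so unrecombined gametes can share
    storage with the parent.
    """

    _PRUNE_EVERY = 25  # generations between fixed/lost-variant sweeps

    def __init__(self, config: SimConfig, gmap: GeneticMap,
                 rng: np.random.Generator | None = None):
        if gmap.region_length != config.region_length:
            raise ValueError("genetic map and config disagree on region length")
        self.config = config
        self.gmap = gmap
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        lam = config.rescale_factor
        self.mu_per_gamete = config.mutation_rate * lam * config.region_length
        self.gc_per_gamete = config.gene_conversion_rate * lam * config.region_length
        self.recomb_intensity = lam
        self.map_morgans = gmap.total_morgans * lam
        schedule = config.rescaled_schedule()
        self.schedule = schedule
        n0 = schedule[0][1]
        self.haps: list[np.ndarray] = [np.empty(0, dtype=np.int64)
                                       for _ in range(2 * n0)]
        self.generation = 0
        self.mutating = True
        self._origin: dict[int, int] = {}
        self._segregating: set[int] = set()

    # -- gamete formation ------------------------------------------------
    def _gamete(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        rng = self.rng
        k = rng.poisson(self.map_morgans)
        if k == 0:
            g = h1 if rng.integers(2) == 0 else h2
        else:
            cuts = self.gmap.sample_crossovers(rng, n=k)
            cuts.sort()
            g = _recombine(h1, h2, cuts, int(rng.integers(2)))
        if self.gc_per_gamete > 0.0:
            n_tracts = rng.poisson(self.gc_per_gamete)
            for _ in range(n_tracts):
                start = rng.integers(self.config.region_length)
                g = _convert_tract(g, h1 if rng.integers(2) else h2,
                                   int(start),
                                   int(start) + self.config.gene_conversion_length)
        if self.mutating and self.mu_per_gamete > 0.0:
            m = rng.poisson(self.mu_per_gamete)
            if m:
                g = self._mutate(g, m)
        return g

    def _mutate(self, g: np.ndarray, m: int) -> np.ndarray:
        rng = self.rng
        new = []
        gen = self.generation
        L = self.config.region_length
        while len(new) < m:
            pos = int(rng.integers(L))
            if pos in self._segregating:
                continue  # infinite sites: never reuse a live position
            self._segregating.add(pos)
            self._origin[pos] = gen
            new.append(pos)
        out = np.concatenate([g, np.asarray(new, dtype=np.int64)])
        out.sort()
        return out

    # -- population cycle ------------------------------------------------
    def step(self, n_next: int | None = None) -> None:
        """Advance one generation of random monoecious mating."""
        n_now = len(self.haps) // 2
        n_next = n_now if n_next is None else int(n_next)
        parents = self.rng.integers(n_now, size=(n_next, 2))
        new_haps: list[np.ndarray] = []
        for p1, p2 in parents:
            new_haps.append(self._gamete(self.haps[2 * p1], self.haps[2 * p1 + 1]))
            new_haps.append(self._gamete(self.haps[2 * p2], self.haps[2 * p2 + 1]))
        self.haps = new_haps
        self.generation += 1
        if self.generation % self._PRUNE_EVERY == 0:
            self._prune()

    def _prune(self) -> None:
        """Drop fixed and lost variants; refresh the live-position set."""
        if not self.haps:
            return
        nonempty = [h for h in self.haps if h.size]
        if not nonempty:
            self._segregating.clear()
            self._origin.clear()
            return
        uniq, counts = np.unique(np.concatenate(nonempty), return_counts=True)
        fixed = uniq[counts == len(self.haps)]
        if fixed.size:
            self.haps = [h[~np.isin(h, fixed, assume_unique=True)]
                         for h in self.haps]
        live = uniq[counts < len(self.haps)]
        self._segregating = set(live.tolist())
        self._origin = {p: g for p, g in self._origin.items()
                        if p in self._segregating}

    def run(self) -> None:
        """Run the full epoch schedule with the trailing mutational freeze."""
        total = sum(g for g, _ in self.schedule)
        freeze_start = total - self.config.freeze_generations
        done = 0
        for gens, n_epoch in self.schedule:
            for _ in range(gens):
                self.mutating = done < freeze_start
                self.step(n_next=n_epoch)
                done += 1
        self._prune()

    # -- export ----------------------------------------------------------
    def to_population(self, individuals: np.ndarray | None = None) -> DiploidPopulation:
        haps = self.haps
        if individuals is not None:
            rows = np.stack([2 * np.asarray(individuals),
                             2 * np.asarray(individuals) + 1], axis=1).ravel()
            haps = [haps[r] for r in rows]
        nonempty = [h for h in haps if h.size]
        positions = (np.unique(np.concatenate(nonempty)) if nonempty
                     else np.empty(0, dtype=np.int64))
        mat = np.zeros((len(haps), positions.size), dtype=np.uint8)
        for i, h in enumerate(haps):
            if h.size:
                mat[i, np.searchsorted(positions, h)] = 1
        origin = np.asarray([self._origin.get(int(p), -1) for p in positions],
                            dtype=np.int64)
        return DiploidPopulation(positions, mat, self.gmap, origin)


def _recombine(h1: np.ndarray, h2: np.ndarray, cuts: np.ndarray,
               start: int) -> np.ndarray:
    """Alternate sorted haplotype slices at the given breakpoints."""
    i1 = np.searchsorted(h1, cuts)
    i2 = np.searchsorted(h2, cuts)
    pieces = []
    src = start
    prev1 = prev2 = 0
    for j in range(len(cuts) + 1):
        end1 = i1[j] if j < len(cuts) else h1.size
        end2 = i2[j] if j < len(cuts) else h2.size
        pieces.append(h1[prev1:end1] if src == 0 else h2[prev2:end2])
        prev1, prev2 = end1, end2
        src ^= 1
    return np.concatenate(pieces)


def _convert_tract(g: np.ndarray, donor: np.ndarray, start: int,
                   end: int) -> np.ndarray:
    """Replace ``[start, end)`` of g with the homologous donor tract."""
    g_lo, g_hi = np.searchsorted(g, [start, end])
    d_lo, d_hi = np.searchsorted(donor, [start, end])
    return np.concatenate([g[:g_lo], donor[d_lo:d_hi], g[g_hi:]])


# ----------------------------------------------------------------------
def simulate_population(config: SimConfig, gmap: GeneticMap) -> DiploidPopulation:
    """Run the Wright-Fisher schedule and return the (sampled) population.

    Deterministic given ``config.seed``.  If ``config.sample_size`` is set,
    a uniform random subsample of that many individuals is returned.
    """
    sim = ForwardSimulator(config, gmap)
    sim.run()
    pop = sim.to_population()
    if config.sample_size is not None:
        if config.sample_size > pop.n_individuals:
            raise ValueError("sample_size exceeds the final population size")
        pop = sample_individuals(pop, config.sample_size,
                                 seed=int(sim.rng.integers(2**31)))
    return pop


def sample_individuals(pop: DiploidPopulation, n: int,
                       seed: int | None = None) -> DiploidPopulation:
    """Uniform subsample of ``n`` individuals without replacement.

    Individual order is preserved; the variant table is kept as-is (allele
    frequencies are recomputed lazily from the subsample).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > pop.n_individuals:
        raise ValueError("n exceeds population size")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pop.n_individuals, size=n, replace=False))
    rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
    return DiploidPopulation(pop.positions, pop.haplotypes[rows], pop.gmap,
                             pop.origin_generation)


def self_offspring(pop: DiploidPopulation, seed: int | None = None,
                   recomb_intensity: float = 1.0) -> DiploidPopulation:
    """One generation of self-mating: each individual is replaced by an
    offspring of selfing, with gametes recombined on the population's map.

    Used to create individuals with guaranteed recent autozygosity.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_individuals
    new = np.zeros_like(pop.haplotypes[: 2 * n])
    for i in range(n):
        h1, h2 = pop.haplotypes[2 * i], pop.haplotypes[2 * i + 1]
        for j in range(2):
            cuts = pop.gmap.sample_crossovers(rng, intensity=recomb_intensity)
            new[2 * i + j] = _dense_recombine(h1, h2, pop.positions, cuts,
                                              int(rng.integers(2)))
    return DiploidPopulation(pop.positions, new, pop.gmap,
                             pop.origin_generation)


def _dense_recombine(h1: np.ndarray, h2: np.ndarray, positions: np.ndarray,
                     cuts: np.ndarray, start: int) -> np.ndarray:
    idx = np.searchsorted(positions, cuts)
    out = np.empty_like(h1)
    bounds = np.concatenate([[0], idx, [positions.size]]).astype(np.int64)
    src = start
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        out[lo:hi] = (h1 if src == 0 else h2)[lo:hi]
        src ^= 1
    return out


# ----------------------------------------------------------------------
def ld_r2_curve(panel, max_dist: int = 50_000, n_pairs: int = 5000,
                maf_match_tol: float = 0.05, min_maf: float = 0.05,
                mode: str = "matched", seed: int | None = None,
                lowess_frac: float = 2.0 / 3.0):
    """LD decay diagnostic: r^2 of random SNP pairs vs physical distance.

    Samples ``n_pairs`` random SNP pairs no further apart than ``max_dist``
    in one of two modes: ``"matched"`` keeps pairs whose MAFs differ by at
    most ``maf_match_tol`` (removing the floor effect that MAF mismatch
    imposes on r^2), ``"minmaf"`` keeps pairs where both SNPs exceed
    ``min_maf``.  r^2 is the squared Pearson correlation of 0/1/2 dosages,
    with missing genotypes excluded pairwise.  Returns ``(pairs, smooth)``
    dataframes, the latter a locally weighted (lowess) mean-r^2 trend.

    Accepts a :class:`~rohbench.panel.GenotypePanel`; a
    :class:`DiploidPopulation` works too (its dosages are used directly).
    """
    import pandas as pd
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if mode not in ("matched", "minmaf"):
        raise ValueError("mode must be 'matched' or 'minmaf'")
    if hasattr(panel, "dosages"):
        dos = panel.dosages().astype(np.float64)
        positions = panel.positions
        f = panel.maf
        missing = np.zeros(dos.shape, dtype=bool)
    else:
        dos = panel.genotypes.astype(np.float64)
        positions = panel.positions
        f = panel.maf
        missing = panel.missing_mask
    m = positions.size
    if m < 2:
        raise ValueError("panel needs at least two SNPs")
    rng = np.random.default_rng(seed)

    if mode == "minmaf":
        eligible = np.flatnonzero(f > min_maf)
    else:
        eligible = np.arange(m)
    if eligible.size < 2:
        raise ValueError("no eligible SNP pairs under the MAF constraint")

    rows = []
    attempts = 0
    max_attempts = 200 * n_pairs
    while len(rows) < n_pairs and attempts < max_attempts:
        attempts += 1
        i = int(eligible[rng.integers(eligible.size)])
        lo = np.searchsorted(positions, positions[i] - max_dist)
        hi = np.searchsorted(positions, positions[i] + max_dist, side="right")
        cand = eligible[np.searchsorted(eligible, lo):
                        np.searchsorted(eligible, hi)]
        cand = cand[cand != i]
        if mode == "matched":
            cand = cand[np.abs(f[cand] - f[i]) <= maf_match_tol]
        if not cand.size:
            continue
        j = int(cand[rng.integers(cand.size)])
        ok = ~(missing[:, i] | missing[:, j])
        x, y = dos[ok, i], dos[ok, j]
        if ok.sum() < 3 or x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        rows.append((abs(int(positions[j]) - int(positions[i])), r * r))
    if not rows:
        raise ValueError("no eligible SNP pairs found")
    pairs = pd.DataFrame(rows, columns=["distance_bp", "r2"])
    sm = lowess(pairs["r2"], pairs["distance_bp"], frac=lowess_frac, it=1,
                return_sorted=True)
    smooth = pd.DataFrame(sm, columns=["distance_bp", "r2"]).drop_duplicates(
        subset="distance_bp")
    return pairs, smooth
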