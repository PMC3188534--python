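"""Power of a whole-genome autozygosity-burden regression.

The genome is split into equal-length potential autozygous segments; each
segment is independently autozygous with a small base rate.  A continuous
phenotype is constructed so that the true autozygous-segment count explains
a fixed share of its variance.  Detection is imperfect: truly autozygous
segments are called with probability ``detect_rate`` (one minus the type-2
rate) and non-autozygous segments are falsely called with probability
``type1``.  Regressing the phenotype on the called sum over many Monte
Carlo replicates gives the power -- the proportion of replicates with a
positive slope and p < 0.05 -- as a function of a caller's error rates.

A closed-form normal approximation of the same design is provided as an
independent check on the Monte Carlo estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerConfig", "PowerResult", "segments_for_genome",
           "simulate_power", "closed_form_power"]

logger = logging.getLogger(__name__)


def segments_for_genome(genome_mb: float, segment_kb: float) -> int:
    """Number of equal-length potential segments in a genome."""
    if genome_mb <= 0 or segment_kb <= 0:
        raise ValueError("genome and segment sizes must be positive")
    return int(round(genome_mb * 1000.0 / segment_kb))


@dataclass(frozen=True)
class PowerConfig:
    """Design of one burden-power experiment.

    ``segment_kb`` is the potential-segment length (423 kb and 169 kb for
    the 20- and 50-generation autozygosity maps at 1.3 cM/Mb);
    ``base_rate`` the per-segment autozygosity probability; ``type1`` and
    ``detect_rate`` come from a caller's measured per-SNP error rates.
    """

    type1: float
    detect_rate: float
    base_rate: float
    segment_kb: float
    n_individuals: int = 2000
    genome_mb: float = 3200.0
    var_explained: float = 0.01
    n_reps: int = 1000
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for p in (self.type1, self.detect_rate, self.base_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.var_explained < 1.0:
            raise ValueError("var_explained must lie in (0, 1)")

    @property
    def n_segments(self) -> int:
        return segments_for_genome(self.genome_mb, self.segment_kb)


@dataclass(frozen=True)
class PowerResult:
    power: float
    n_reps: int
    seed: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1.0 - self.power) / self.n_reps))


def simulate_power(cfg: PowerConfig) -> PowerResult:
    """Monte Carlo burden-regression power. Deterministic given cfg.seed.

    Per replicate: true per-individual autozygous counts are Binomial
    (``n_segments``, ``base_rate``); the phenotype standardizes the count
    against its theoretical binomial moments and adds Gaussian noise so the
    count explains ``var_explained`` of the variance; the called sum adds
    binomial thinning at ``detect_rate`` and false calls at ``type1``; a
    replicate succeeds when the OLS slope of phenotype on called sum is
    positive with two-sided p below ``alpha_level``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, S = cfg.n_individuals, cfg.n_segments
    mu_a = S * cfg.base_rate
    sd_a = np.sqrt(S * cfg.base_rate * (1.0 - cfg.base_rate))
    successes = 0
    degenerate = 0
    chunk = max(1, min(cfg.n_reps, int(2e7 // max(n, 1))))
    done = 0
    while done < cfg.n_reps:
        k = min(chunk, cfg.n_reps - done)
        a = rng.binomial(S, cfg.base_rate, size=(k, n))
        y = (np.sqrt(cfg.var_explained) * (a - mu_a) / sd_a
             + np.sqrt(1.0 - cfg.var_explained) * rng.standard_normal((k, n)))
        d = rng.binomial(a, cfg.detect_rate) + rng.binomial(S - a, cfg.type1)
        d = d.astype(np.float64)
        dc = d - d.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        var_d = np.sum(dc * dc, axis=1)
        ok = var_d > 0
        degenerate += int(np.sum(~ok))
        cov = np.sum(dc * yc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var_d * np.sum(yc * yc, axis=1))
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        successes += int(np.sum(ok & (cov > 0) & (p < cfg.alpha_level)))
        done += k
    if degenerate:
        logger.warning("%d replicates had zero variance in the called sum "
                       "and were counted as failures", degenerate)
    return PowerResult(power=successes / cfg.n_reps, n_reps=cfg.n_reps,
                       seed=cfg.seed)


def closed_form_power(cfg: PowerConfig) -> float:
    """Normal-approximation power of the same design.

    The phenotype-call correlation is assembled from the binomial moments
    of the true count A and the thinned-plus-false-called sum D, then power
    is approximated by ``Phi(|r| * sqrt(n) - z_{1 - alpha/2})``.
    """
    S, al, de = cfg.n_segments, cfg.type1, cfg.detect_rate
    var_a = S * cfg.base_rate * (1.0 - cfg.base_rate)
    mean_a = S * cfg.base_rate
    cov_ad = (de - al) * var_a
    var_d = (mean_a * de * (1.0 - de) + de**2 * var_a
             + (S - mean_a) * al * (1.0 - al) + al**2 * var_a
             - 2.0 * de * al * var_a)
    if var_d <= 0 or var_a <= 0:
        return cfg.alpha_level / 2.0
    r = np.sqrt(cfg.var_explained) * cov_ad / np.sqrt(var_a * var_d)
    z_crit = stats.norm.ppf(1.0 - cfg.alpha_level / 2.0)
    return float(stats.norm.cdf(abs(r) * np.sqrt(cfg.n_individuals) - z_crit))
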