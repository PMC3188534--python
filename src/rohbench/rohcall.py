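"""Window-based ROH callers: per-SNP sliding windows and non-overlapping blocks.

Two detection strategies are implemented over a genotype panel:

* :func:`sliding_window_roh` -- the sliding-window scan popularized by
  PLINK's ``--homozyg``: every window of ``window_snps`` consecutive SNPs is
  classified homozygous if it contains at most ``het_allowance``
  heterozygotes and ``missing_allowance`` missing calls; a SNP is eligible
  when at least ``hit_proportion`` of the windows containing it are
  homozygous; maximal eligible runs of at least ``min_roh_snps`` SNPs become
  calls.
* :func:`block_roh` -- the GERMLINE-style partition of the SNPs into
  non-overlapping windows; fully homozygous windows are tagged and runs of
  consecutive tagged windows spanning at least ``min_len_cm`` are called,
  with boundaries snapped to window edges (coarser start/end resolution).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

__all__ = [
    "SlidingWindowParams",
    "BlockParams",
    "ROHCallSet",
    "sliding_window_roh",
    "block_roh",
    "expected_window_snps",
    "plink_grid_params",
]


@dataclass(frozen=True)
class SlidingWindowParams:
    """Sliding-window caller parameters (PLINK ``--homozyg`` vocabulary)."""

    window_snps: int = 50
    het_allowance: int = 1
    missing_allowance: int = 5
    hit_proportion: float = 0.05
    min_roh_snps: int = 100

    def __post_init__(self):
        if self.window_snps < 1 or self.min_roh_snps < 1:
            raise ValueError("window and run thresholds must be >= 1")
        if not 0.0 <= self.hit_proportion <= 1.0:
            raise ValueError("hit_proportion must lie in [0, 1]")
        if self.het_allowance < 0 or self.missing_allowance < 0:
            raise ValueError("allowances must be >= 0")


@dataclass(frozen=True)
class BlockParams:
    """Non-overlapping-window caller parameters (GERMLINE vocabulary)."""

    min_len_cm: float = 1.0
    window_snps: int = 128
    het_allowance: int = 0
    missing_is_het: bool = False  # strict mode: count missing like a het

    def __post_init__(self):
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if self.min_len_cm <= 0:
            raise ValueError("min_len_cm must be positive")


def plink_grid_params(snp_threshold: int, het_allowance: int) -> SlidingWindowParams:
    """Parameter mapping used for the sliding-window threshold grid.

    Window size equals the SNP run threshold, capped at the conventional 50;
    the missing allowance is 5% of the window (rounded up); the hit
    proportion stays at its 0.05 default.
    """
    window = min(snp_threshold, 50)
    return SlidingWindowParams(
        window_snps=window,
        het_allowance=het_allowance,
        missing_allowance=math.ceil(0.05 * window),
        hit_proportion=0.05,
        min_roh_snps=snp_threshold,
    )


def expected_window_snps(n_snps: int, total_cm: float, min_len_cm: float) -> int:
    """Expected SNP count in ``min_len_cm`` at the panel's average density."""
    if n_snps <= 0 or total_cm <= 0 or min_len_cm <= 0:
        raise ValueError("all arguments must be positive")
    return max(1, int(round(n_snps / total_cm * min_len_cm)))


class ROHCallSet:
    """Per-individual ROH calls as a table of SNP-index and bp intervals."""

    COLUMNS = ["individual", "first_snp", "last_snp", "start_bp", "end_bp",
               "n_snps", "length_kb", "length_cm"]

    def __init__(self, calls: pd.DataFrame, n_individuals: int,
                 positions: np.ndarray):
        self.calls = calls.reset_index(drop=True)
        self.n_individuals = int(n_individuals)
        self.positions = np.asarray(positions)

    @classmethod
    def from_runs(cls, runs: list[tuple[int, int, int]],
                  panel: GenotypePanel) -> "ROHCallSet":
        """Build from (individual, first_snp, last_snp) inclusive runs."""
        pos, cm = panel.positions, panel.cm
        rows = []
        for ind, first, last in runs:
            rows.append((ind, first, last, int(pos[first]), int(pos[last]),
                         last - first + 1,
                         (pos[last] - pos[first]) / 1000.0,
                         float(cm[last] - cm[first])))
        calls = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(calls, panel.n_individuals, pos)

    def __len__(self) -> int:
        return len(self.calls)

    def mask(self) -> np.ndarray:
        """(n_individuals, n_snps) boolean per-SNP call mask."""
        out = np.zeros((self.n_individuals, self.positions.size), dtype=bool)
        for ind, first, last in zip(self.calls["individual"],
                                    self.calls["first_snp"],
                                    self.calls["last_snp"]):
            out[ind, first:last + 1] = True
        return out

    def total_called_bp(self) -> float:
        if not len(self.calls):
            return 0.0
        return float(np.sum(self.calls["end_bp"] - self.calls["start_bp"]))


# ----------------------------------------------------------------------
def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def sliding_window_eligible(genotypes: np.ndarray,
                            p: SlidingWindowParams) -> np.ndarray:
    """Per-SNP eligibility under the sliding-window hit-proportion rule.

    Only fully in-bounds windows enter the denominator, so SNPs near the
    chromosome ends are judged on the windows that actually exist.
    """
    m = genotypes.size
    w = p.window_snps
    if w > m:
        return np.zeros(m, dtype=bool)
    het = (genotypes == 1).astype(np.int32)
    miss = (genotypes == MISSING).astype(np.int32)
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(m - w + 1)
    hom_win = ((het_c[starts + w] - het_c[starts] <= p.het_allowance)
               & (miss_c[starts + w] - miss_c[starts] <= p.missing_allowance))
    # windows containing SNP i start in [i - w + 1, i] clipped to valid range
    win_c = np.concatenate([[0], np.cumsum(hom_win.astype(np.int32))])
    lo = np.clip(np.arange(m) - w + 1, 0, None)
    hi = np.minimum(np.arange(m), m - w)
    n_windows = hi - lo + 1
    n_hom = win_c[hi + 1] - win_c[lo]
    return n_hom >= p.hit_proportion * n_windows


def sliding_window_roh(panel: GenotypePanel,
                       p: SlidingWindowParams) -> ROHCallSet:
    """Sliding-window ROH calls for every individual in the panel."""
    if p.window_snps > panel.n_snps:
        warnings.warn("window longer than the panel: no calls possible",
                      stacklevel=2)
        return ROHCallSet.from_runs([], panel)
    runs = []
    for i in range(panel.n_individuals):
        eligible = sliding_window_eligible(panel.genotypes[i], p)
        for first, last in _runs_of(eligible):
            if last - first + 1 >= p.min_roh_snps:
                runs.append((i, first, last))
    return ROHCallSet.from_runs(runs, panel)


def block_tags(genotypes: np.ndarray, p: BlockParams) -> np.ndarray:
    """Tag non-overlapping windows that pass the het allowance.

    The partition starts at SNP 0; a trailing partial window is ignored.
    Missing genotypes count as homozygous-compatible unless
    ``missing_is_het``.
    """
    m = genotypes.size
    w = p.window_snps
    n_win = m // w
    if n_win == 0:
        return np.zeros(0, dtype=bool)
    g = genotypes[: n_win * w].reshape(n_win, w)
    bad = (g == 1)
    if p.missing_is_het:
        bad |= (g == MISSING)
    return bad.sum(axis=1) <= p.het_allowance


def block_roh(panel: GenotypePanel, p: BlockParams) -> ROHCallSet:
    """Non-overlapping-window ROH calls for every individual."""
    w = p.window_snps
    if w > panel.n_snps:
        warnings.warn("window longer than the panel: no calls possible",
                      stacklevel=2)
        return ROHCallSet.from_runs([], panel)
    cm = panel.cm
    runs = []
    for i in range(panel.n_individuals):
        tags = block_tags(panel.genotypes[i], p)
        for first_w, last_w in _runs_of(tags):
            first = first_w * w
            last = (last_w + 1) * w - 1
            if cm[last] - cm[first] >= p.min_len_cm:
                runs.append((i, first, last))
    return ROHCallSet.from_runs(runs, panel)
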