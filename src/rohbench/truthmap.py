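"""True autozygosity: segment-length thresholds and perfect-homozygosity runs.

An autozygous segment inherited from a common ancestor ``g`` generations
back has a length that is exponentially distributed with mean ``1 / (2 g)``
Morgans (recombination whittles the shared tract down over ``2 g`` meioses).
Fixing a capture proportion (default 80%) converts a generation depth into
a minimum genetic-length threshold; segments of the sequence-level diploid
data that are perfectly homozygous and at least that long are taken as the
truth against which ROH calls are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popsim import DiploidPopulation

__all__ = [
    "expected_segment_length",
    "capture_threshold",
    "cm_to_kb",
    "GenerationThreshold",
    "AutozygosityTruth",
    "map_autozygous_segments",
]


def expected_segment_length(g: int) -> float:
    """Mean autozygous-segment length, in Morgans, for generation depth g."""
    if g < 1:
        raise ValueError("g must be a positive number of generations")
    return 1.0 / (2.0 * g)


def capture_threshold(g: int, capture: float = 0.8) -> float:
    """Minimum segment length (cM, 2 dp) capturing the given proportion.

    Solves ``P(X >= L) = capture`` for ``X ~ Exponential(mean 1/(2g))``:
    ``L = -ln(capture) / (2 g)`` Morgans, reported in cM truncated to two
    decimals -- the quoting convention these thresholds follow (0.5579 cM
    at g = 20 is quoted as 0.55), which never overstates the captured
    proportion.
    """
    if not 0.0 < capture < 1.0:
        raise ValueError("capture must lie strictly in (0, 1)")
    morgans = -np.log(capture) / (2.0 * g)
    return float(np.floor(morgans * 100.0 * 100.0 + 1e-9) / 100.0)


def cm_to_kb(len_cm: float, rate_cm_per_mb: float = 1.3) -> int:
    """Convert a genetic length to kb at a given average rate.

    The cM value is rounded to 2 decimals *before* conversion, matching how
    such thresholds are quoted (e.g. 0.55 cM -> 423 kb at 1.3 cM/Mb).
    """
    if rate_cm_per_mb <= 0:
        raise ValueError("rate must be positive")
    return int(round(1000.0 * round(len_cm, 2) / rate_cm_per_mb))


@dataclass(frozen=True)
class GenerationThreshold:
    """A generation depth with its derived minimum-length threshold."""

    g: int
    capture: float = 0.8
    rate_cm_per_mb: float = 1.3

    @property
    def min_len_cm(self) -> float:
        return capture_threshold(self.g, self.capture)

    @property
    def min_len_kb(self) -> int:
        return cm_to_kb(self.min_len_cm, self.rate_cm_per_mb)


@dataclass
class AutozygosityTruth:
    """Per-individual true autozygous segments plus a per-variant mask.

    ``segments[i]`` is an ``(k_i, 2)`` int64 array of 0-based half-open
    ``[start, end)`` bp intervals; ``mask`` is ``(n_individuals,
    n_variants)`` boolean; ``base_rate`` is covered bp / total bp averaged
    over individuals.
    """

    segments: list[np.ndarray]
    segment_cm: list[np.ndarray]
    mask: np.ndarray
    base_rate: float
    min_len_cm: float
    positions: np.ndarray
    region_length: int

    @property
    def n_individuals(self) -> int:
        return len(self.segments)

    def mask_at(self, positions: np.ndarray) -> np.ndarray:
        """Truth labels for arbitrary SNP bp positions (e.g. a panel)."""
        positions = np.asarray(positions)
        out = np.zeros((self.n_individuals, positions.size), dtype=bool)
        for i, segs in enumerate(self.segments):
            if not len(segs):
                continue
            j = np.searchsorted(segs[:, 0], positions, side="right") - 1
            ok = j >= 0
            out[i, ok] = positions[ok] < segs[j[ok], 1]
        return out

    def variant_base_rate(self) -> float:
        """Alternative base rate measured over variants instead of bp."""
        return float(self.mask.mean())

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, (segs, cms) in enumerate(zip(self.segments, self.segment_cm)):
            for (s, e), c in zip(segs, cms):
                rows.append((i, int(s), int(e), int(e - s), float(c)))
        return pd.DataFrame(rows, columns=["individual", "start_bp", "end_bp",
                                           "length_bp", "length_cm"])


def map_autozygous_segments(pop: DiploidPopulation,
                            threshold: GenerationThreshold | float) -> AutozygosityTruth:
    """Find per-individual maximal perfectly-homozygous runs >= the threshold.

    A run extends from just after the previous heterozygous variant to just
    before the next one (the maximal interval consistent with the observed
    homozygosity), clipped to ``[0, region_length)``; runs whose genetic
    length reaches ``min_len_cm`` are emitted.
    """
    if pop.n_variants == 0:
        raise ValueError("empty variant table")
    min_len_cm = (threshold.min_len_cm
                  if isinstance(threshold, GenerationThreshold)
                  else float(threshold))
    gmap = pop.gmap
    L = pop.region_length
    het = pop.het_mask()
    positions = pop.positions
    n = pop.n_individuals

    segments: list[np.ndarray] = []
    segment_cm: list[np.ndarray] = []
    mask = np.zeros((n, pop.n_variants), dtype=bool)
    covered_bp = 0
    for i in range(n):
        het_bp = positions[het[i]]
        # candidate runs between consecutive het variants, clipped to region
        starts = np.concatenate([[0], het_bp + 1])
        ends = np.concatenate([het_bp, [L]])
        ok = starts < ends
        starts, ends = starts[ok], ends[ok]
        cm_len = np.asarray(gmap.cm_at(ends)) - np.asarray(gmap.cm_at(starts))
        keep = cm_len >= min_len_cm
        segs = np.column_stack([starts[keep], ends[keep]]).astype(np.int64)
        segments.append(segs)
        segment_cm.append(cm_len[keep])
        covered_bp += int(np.sum(segs[:, 1] - segs[:, 0])) if segs.size else 0
        for s, e in segs:
            lo, hi = np.searchsorted(positions, [s, e])
            mask[i, lo:hi] = True
    base_rate = covered_bp / (L * n)
    return AutozygosityTruth(segments=segments, segment_cm=segment_cm,
                             mask=mask, base_rate=base_rate,
                             min_len_cm=min_len_cm, positions=positions,
                             region_length=L)
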