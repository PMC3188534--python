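"""Piecewise-constant recombination maps with crossover hotspots.

A :class:`GeneticMap` describes recombination intensity along a single
simulated chromosome as a piecewise-constant rate (Morgans per bp) with two
levels: a low background rate and an elevated rate inside a set of short
hotspot intervals.  The default construction concentrates 80% of the total
map length into hotspots of ~2 kb that together span 20% of the sequence,
with an average rate of 1.3 cM/Mb -- the recombination regime typical of
human autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "build_genetic_map", "uniform_map", "map_from_table"]


@dataclass(frozen=True)
class GeneticMap:
    """Recombination map over ``[0, region_length)`` in bp.

    Parameters
    ----------
    region_length:
        Chromosome length in bp.
    hotspot_intervals:
        ``(k, 2)`` integer array of disjoint, sorted ``[start, end)`` bp
        intervals with elevated recombination.
    background_rate, hotspot_rate:
        Recombination intensities in Morgans per bp outside/inside hotspots.
    """

    region_length: int
    hotspot_intervals: np.ndarray
    background_rate: float
    hotspot_rate: float
    # derived piecewise representation, filled in __post_init__
    _bounds: np.ndarray = field(init=False, repr=False, compare=False)
    _rates: np.ndarray = field(init=False, repr=False, compare=False)
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        L = int(self.region_length)
        if L <= 0:
            raise ValueError("region_length must be positive")
        hs = np.asarray(self.hotspot_intervals, dtype=np.int64).reshape(-1, 2)
        if hs.size:
            if np.any(hs[:, 0] >= hs[:, 1]):
                raise ValueError("hotspot intervals must have start < end")
            if np.any(hs[:-1, 1] > hs[1:, 0]):
                raise ValueError("hotspot intervals must be sorted and disjoint")
            if hs[0, 0] < 0 or hs[-1, 1] > L:
                raise ValueError("hotspot intervals outside region")
        # alternate background/hotspot segments
        bounds = [0]
        rates = []
        pos = 0
        for start, end in hs:
            if start > pos:
                bounds.append(int(start))
                rates.append(self.background_rate)
                pos = int(start)
            bounds.append(int(end))
            rates.append(self.hotspot_rate)
            pos = int(end)
        if pos < L:
            bounds.append(L)
            rates.append(self.background_rate)
        b = np.asarray(bounds, dtype=np.float64)
        r = np.asarray(rates, dtype=np.float64)
        cum = np.concatenate([[0.0], np.cumsum(r * np.diff(b))])
        object.__setattr__(self, "hotspot_intervals", hs)
        object.__setattr__(self, "_bounds", b)
        object.__setattr__(self, "_rates", r)
        object.__setattr__(self, "_cum", cum)

    # ------------------------------------------------------------------
    @property
    def total_morgans(self) -> float:
        return float(self._cum[-1])

    @property
    def total_cm(self) -> float:
        return 100.0 * self.total_morgans

    @property
    def avg_rate_cm_per_mb(self) -> float:
        return self.total_cm / (self.region_length / 1e6)

    @property
    def hotspot_span_bp(self) -> int:
        hs = self.hotspot_intervals
        return int(np.sum(hs[:, 1] - hs[:, 0])) if hs.size else 0

    @property
    def hotspot_map_fraction(self) -> float:
        """Fraction of total map length (Morgans) inside hotspots."""
        return self.hotspot_rate * self.hotspot_span_bp / self.total_morgans

    # ------------------------------------------------------------------
    def morgans_at(self, bp) -> np.ndarray | float:
        """Cumulative genetic position (Morgans) at physical position bp."""
        bp_arr = np.asarray(bp, dtype=np.float64)
        seg = np.clip(np.searchsorted(self._bounds, bp_arr, side="right") - 1, 0,
                      len(self._rates) - 1)
        out = self._cum[seg] + (bp_arr - self._bounds[seg]) * self._rates[seg]
        return out if out.ndim else float(out)

    def cm_at(self, bp) -> np.ndarray | float:
        return 100.0 * self.morgans_at(bp)

    def bp_at_morgans(self, m) -> np.ndarray | float:
        """Inverse of :meth:`morgans_at` (piecewise linear)."""
        m_arr = np.asarray(m, dtype=np.float64)
        seg = np.clip(np.searchsorted(self._cum, m_arr, side="right") - 1, 0,
                      len(self._rates) - 1)
        out = self._bounds[seg] + (m_arr - self._cum[seg]) / self._rates[seg]
        return out if out.ndim else float(out)

    def cm_span(self, start_bp, end_bp) -> np.ndarray | float:
        return self.cm_at(end_bp) - self.cm_at(start_bp)

    def sample_crossovers(self, rng: np.random.Generator, *,
                          intensity: float = 1.0, n: int | None = None) -> np.ndarray:
        """Draw crossover positions (bp, float) for one meiosis.

        The number of crossovers is Poisson with mean ``total_morgans *
        intensity`` unless ``n`` is given; positions follow the map density
        via inverse-CDF sampling.
        """
        k = int(n) if n is not None else int(rng.poisson(self.total_morgans * intensity))
        if k == 0:
            return np.empty(0)
        u = rng.uniform(0.0, self.total_morgans, size=k)
        u.sort()
        return np.asarray(self.bp_at_morgans(u))

    def in_hotspot(self, bp) -> np.ndarray:
        """Boolean mask: does each position fall inside a hotspot interval."""
        bp_arr = np.atleast_1d(np.asarray(bp))
        hs = self.hotspot_intervals
        if not hs.size:
            return np.zeros(bp_arr.shape, dtype=bool)
        i = np.searchsorted(hs[:, 0], bp_arr, side="right") - 1
        ok = i >= 0
        out = np.zeros(bp_arr.shape, dtype=bool)
        out[ok] = bp_arr[ok] < hs[i[ok], 1]
        return out

    def to_dataframe(self):
        """PLINK-style map-rate table: chr, bp, rate cM/Mb, cumulative cM."""
        import pandas as pd

        starts = self._bounds[:-1].astype(np.int64)
        return pd.DataFrame({
            "chr": "1",
            "bp": starts,
            "rate_cm_per_mb": self._rates * 1e8,
            "cm": 100.0 * self._cum[:-1],
        })


def build_genetic_map(region_length: int,
                      avg_rate_cm_per_mb: float = 1.3,
                      hotspot_fraction_of_map: float = 0.8,
                      hotspot_span_fraction: float = 0.2,
                      hotspot_length: int = 2000,
                      seed: int | None = None) -> GeneticMap:
    """Place hotspots uniformly at random and solve the two-level rates.

    ``hotspot_fraction_of_map`` of the total genetic length is packed into
    hotspots that span ``hotspot_span_fraction`` of the physical sequence
    (to within one hotspot of rounding).  Deterministic given ``seed``.
    """
    L = int(region_length)
    if not (0.0 < hotspot_fraction_of_map < 1.0 and 0.0 < hotspot_span_fraction < 1.0):
        raise ValueError("fractions must lie strictly in (0, 1)")
    if hotspot_length <= 0 or hotspot_length >= L:
        raise ValueError("hotspot_length must be in (0, region_length)")
    n_hot = int(round(L * hotspot_span_fraction / hotspot_length))
    if n_hot < 1:
        raise ValueError("region too small to place any hotspot of the requested length")
    span = n_hot * hotspot_length
    if span >= L:
        raise ValueError("region too small for the requested hotspot span")
    rng = np.random.default_rng(seed)
    # uniform non-overlapping placement: sort gaps then shift by i*len
    slack = np.sort(rng.uniform(0.0, L - span, size=n_hot)).astype(np.int64)
    starts = slack + np.arange(n_hot, dtype=np.int64) * hotspot_length
    intervals = np.column_stack([starts, starts + hotspot_length])

    total_morgans = L * avg_rate_cm_per_mb * 1e-8  # cM/Mb -> Morgans/bp
    hot_rate = hotspot_fraction_of_map * total_morgans / span
    bg_rate = (1.0 - hotspot_fraction_of_map) * total_morgans / (L - span)
    return GeneticMap(region_length=L, hotspot_intervals=intervals,
                      background_rate=bg_rate, hotspot_rate=hot_rate)


def uniform_map(region_length: int, avg_rate_cm_per_mb: float = 1.3) -> GeneticMap:
    """A hotspot-free map with one constant rate (the degenerate case)."""
    rate = avg_rate_cm_per_mb * 1e-8
    return GeneticMap(region_length=int(region_length),
                      hotspot_intervals=np.empty((0, 2), dtype=np.int64),
                      background_rate=rate, hotspot_rate=rate)


def map_from_table(df, region_length: int) -> GeneticMap:
    """Rebuild a map from its PLINK-style rate table (see ``to_dataframe``).

    The table's alternating rates are re-read as background/hotspot levels;
    any segment whose rate exceeds the minimum is treated as a hotspot.
    """
    starts = np.asarray(df["bp"], dtype=np.int64)
    rates = np.asarray(df["rate_cm_per_mb"], dtype=float) * 1e-8
    bounds = np.concatenate([starts, [region_length]])
    lo = rates.min()
    hi = rates.max()
    hs = [(int(bounds[i]), int(bounds[i + 1]))
          for i in range(len(rates)) if rates[i] > lo + 1e-15]
    return GeneticMap(region_length=int(region_length),
                      hotspot_intervals=np.asarray(hs, dtype=np.int64).reshape(-1, 2),
                      background_rate=float(lo),
                      hotspot_rate=float(hi if hs else lo))
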