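"""Per-SNP scoring of ROH calls against true autozygosity, and d-prime.

Calls are scored per SNP, pooled over individuals: the type-1 error rate
(alpha) is the fraction of non-autozygous SNP genotypes called inside a
ROH, and the type-2 rate (beta) is the fraction of truly autozygous SNP
genotypes not covered by a call.  The signal-detection sensitivity index is
``d' = probit(1 - beta) - probit(alpha)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["ErrorRates", "confusion", "d_prime"]


@dataclass(frozen=True)
class ErrorRates:
    """Pooled per-SNP confusion counts and the derived error rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_autozygous(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_autozygous(self) -> int:
        return self.fp + self.tn

    @property
    def type1(self) -> float | None:
        """False calls / non-autozygous SNPs; None when undefined."""
        d = self.n_non_autozygous
        return self.fp / d if d else None

    @property
    def type2(self) -> float | None:
        """Missed calls / autozygous SNPs; None when undefined."""
        d = self.n_autozygous
        return self.fn / d if d else None

    @property
    def detect_rate(self) -> float | None:
        t2 = self.type2
        return None if t2 is None else 1.0 - t2

    def d_prime(self) -> float:
        """d' with degenerate rates clamped away from 0/1 by half a count."""
        if self.type1 is None or self.type2 is None:
            raise ValueError("d' undefined: no autozygous or no "
                             "non-autozygous SNPs")
        a = _clamp(self.type1, self.n_non_autozygous)
        b = _clamp(self.type2, self.n_autozygous)
        return d_prime(a, b)


def _clamp(rate: float, denom: int) -> float:
    lo = 1.0 / (2.0 * denom)
    if rate <= 0.0 or rate >= 1.0:
        warnings.warn("degenerate error rate clamped by half a count for d'",
                      stacklevel=3)
        return min(max(rate, lo), 1.0 - lo)
    return rate


def confusion(truth_mask: np.ndarray, call_mask: np.ndarray) -> ErrorRates:
    """Pooled per-SNP confusion of a call mask against a truth mask.

    Both masks are ``(individuals, SNPs)`` boolean arrays; counts are pooled
    over all cells.
    """
    t = np.asarray(truth_mask, dtype=bool)
    c = np.asarray(call_mask, dtype=bool)
    if t.shape != c.shape:
        raise ValueError("truth and call masks must have the same shape")
    tp = int(np.sum(t & c))
    fp = int(np.sum(~t & c))
    tn = int(np.sum(~t & ~c))
    fn = int(np.sum(t & ~c))
    return ErrorRates(tp=tp, fp=fp, tn=tn, fn=fn)


def d_prime(type1: float, type2: float, *, n_noise: int | None = None,
            n_signal: int | None = None) -> float:
    """Signal-detection sensitivity: probit(1 - type2) - probit(type1).

    The probit here is the standard-normal quantile function (a proportion
    converted to a Z score).  Rates of exactly 0 or 1 send d' to infinity;
    when the corresponding denominator (``n_noise`` for type1, ``n_signal``
    for type2) is supplied such rates are clamped by half a count with a
    warning, otherwise they raise.
    """
    if type1 <= 0.0 or type1 >= 1.0:
        if n_noise is None:
            raise ValueError("type1 rate of 0 or 1 needs n_noise to clamp")
        type1 = _clamp(type1, n_noise)
    if type2 <= 0.0 or type2 >= 1.0:
        if n_signal is None:
            raise ValueError("type2 rate of 0 or 1 needs n_signal to clamp")
        type2 = _clamp(type2, n_signal)
    return float(norm.ppf(1.0 - type2) - norm.ppf(type1))
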