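"""Sliding-window variance-inflation-factor (VIF) LD pruning.

A SNP's VIF within a window is ``1 / (1 - R^2)`` where ``R^2`` is the
multiple correlation of its dosage with all other SNPs in the window.
Pruning greedily removes the SNP with the largest VIF in each window until
no VIF exceeds the threshold, after first discarding SNPs below a MAF
floor.  Four conventional pruning strengths are provided: light (VIF > 10),
moderate (> 2), moderate-heavy (> 1.33) and heavy (> 1.1), corresponding to
window R^2 limits of 0.9, 0.5, 0.25 and 0.09.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel

__all__ = ["PruneParams", "PRUNE_LEVELS", "vif_to_r2", "vif_prune",
           "window_vifs"]

#: Named pruning strengths (threshold on VIF).
PRUNE_LEVELS: dict[str, float] = {
    "light": 10.0,
    "moderate": 2.0,
    "moderate-heavy": 1.33,
    "heavy": 1.1,
}

_R2_CAP = 1.0 - 1e-12
_DUP_TOL = 1e-9


@dataclass(frozen=True)
class PruneParams:
    min_maf: float = 0.05
    window_snps: int = 50
    window_step: int = 5
    vif_threshold: float = 2.0

    def __post_init__(self):
        if self.vif_threshold <= 1.0:
            raise ValueError("vif_threshold must exceed 1")
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")

    @classmethod
    def level(cls, name: str, **overrides) -> "PruneParams":
        return cls(vif_threshold=PRUNE_LEVELS[name], **overrides)


def vif_to_r2(vif: float) -> float:
    """Window R^2 implied by a VIF threshold (``1 - 1/VIF``, 2 dp)."""
    if vif <= 1.0:
        raise ValueError("VIF must exceed 1")
    return round(1.0 - 1.0 / vif, 2)


def window_vifs(z: np.ndarray) -> np.ndarray:
    """VIF of every column of a standardized dosage window.

    Uses the diagonal of the inverse correlation matrix; falls back to
    per-column least squares when the matrix is numerically singular.
    Zero-variance columns get VIF 1 (they carry no LD information).
    """
    n, m = z.shape
    if m == 1:
        return np.ones(1)
    sd = z.std(axis=0)
    live = sd > 0
    vifs = np.ones(m)
    if live.sum() < 2:
        return vifs
    zz = (z[:, live] - z[:, live].mean(axis=0)) / sd[live]
    corr = zz.T @ zz / n
    try:
        inv = np.linalg.inv(corr)
        diag = np.diag(inv)
        if np.all(np.isfinite(diag)) and np.all(diag > 1.0 - 1e-8):
            vifs[live] = np.maximum(diag, 1.0)
            return vifs
    except np.linalg.LinAlgError:
        pass
    # singular window (e.g. duplicate columns): per-column least squares
    out = np.empty(zz.shape[1])
    for j in range(zz.shape[1]):
        others = np.delete(zz, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, zz[:, j], rcond=None)
        resid = zz[:, j] - others @ beta
        r2 = min(1.0 - resid @ resid / n, _R2_CAP)
        out[j] = 1.0 / (1.0 - max(r2, 0.0))
    vifs[live] = out
    return vifs


def vif_prune(panel: GenotypePanel,
              params: PruneParams = PruneParams()) -> tuple[np.ndarray, np.ndarray]:
    """Greedy windowed VIF pruning; returns (kept, removed) SNP indices.

    SNPs with MAF below ``min_maf`` are removed first.  Windows of
    ``window_snps`` SNPs advance by ``window_step`` over the surviving
    list; within a window the SNP with the largest VIF above the threshold
    is removed (ties broken toward the higher bp position) until the window
    is clean; passes repeat until a full scan removes nothing, so the final
    set audits clean in every window.  Deterministic.
    """
    m = panel.n_snps
    keep = panel.maf >= params.min_maf
    z = panel.dosages_imputed()
    kept_idx = np.flatnonzero(keep)
    w, step = params.window_snps, params.window_step
    thr = params.vif_threshold
    changed = True
    while changed and kept_idx.size:
        changed = False
        start = 0
        while start < kept_idx.size:
            window = kept_idx[start:start + w]
            if window.size >= 2:
                removed_here = _clean_window(z, window, thr, panel.positions)
                if removed_here.size:
                    kept_idx = np.setdiff1d(kept_idx, removed_here,
                                            assume_unique=True)
                    changed = True
                    continue  # re-evaluate the same window start
            if start + w >= kept_idx.size:
                break
            start += step
    removed = np.setdiff1d(np.arange(m), kept_idx, assume_unique=True)
    return kept_idx, removed


def _clean_window(z: np.ndarray, window: np.ndarray, thr: float,
                  positions: np.ndarray) -> np.ndarray:
    """Remove-worst-VIF loop for one window; returns removed SNP indices."""
    active = list(window)
    removed = []
    while len(active) >= 2:
        vifs = window_vifs(z[:, active])
        worst = np.max(vifs)
        if worst <= thr:
            break
        cands = np.flatnonzero(vifs >= worst - 1e-12)
        # ties (e.g. duplicate columns) -> drop the higher bp position
        drop_local = cands[np.argmax(positions[np.asarray(active)[cands]])]
        removed.append(active.pop(drop_local))
    return np.asarray(removed, dtype=np.int64)
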