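"""Windowed pairwise-r² pruning of covered SNP sites (LD clumping).

Mirrors PLINK's ``--indep-pairwise <window> <step> <r2>`` behaviour in
site units: slide a window of ``window_size`` kept sites forward by
``step`` sites; within each window remove, for every pair whose squared
dosage correlation exceeds the threshold, the later site in genomic order;
repeat until stable. The removal preference differs from PLINK (which may
prefer the lower-MAF site) — determinism matters more here than byte
compatibility, and downstream results only need approximate independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np

from .panel_io import MISSING

logger = logging.getLogger("metareid")

T = TypeVar("T")


@dataclass(frozen=True)
class ClumpConfig:
    """Window (in sites), step (in sites) and r² threshold for pruning."""

    window_size: int = 100
    step: int = 30
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise ValueError("require window_size >= step >= 1")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("require 0 < r2_threshold <= 1")


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over shared calls.

    MISSING entries are pairwise-deleted; a monomorphic column (zero
    variance) yields r² = 0.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    denom = (xv @ xv) * (yv @ yv)
    if denom <= 0.0:
        return 0.0
    return float((xv @ yv) ** 2 / denom)


def _window_r2_matrix(cols: np.ndarray) -> np.ndarray:
    """Pairwise r² matrix for a window of dosage columns.

    Falls back to pairwise deletion when MISSING entries are present.
    """
    m = cols.shape[1]
    if (cols == MISSING).any():
        r2 = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                r2[a, b] = pairwise_r2(cols[:, a], cols[:, b])
        return r2
    x = cols.astype(float)
    x -= x.mean(axis=0)
    norms = np.sqrt((x**2).sum(axis=0))
    poly = norms > 0
    x[:, poly] /= norms[poly]
    x[:, ~poly] = 0.0  # monomorphic columns: define r² = 0 with every partner
    return np.triu((x.T @ x) ** 2, k=1)


def prune_sites(
    covered_sites: Sequence[T],
    reference_dosages: np.ndarray,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[T]:
    """Return the subset of ``covered_sites`` kept by windowed r² pruning.

    Parameters
    ----------
    covered_sites
        Sites (or site indices) in genomic order.
    reference_dosages
        LD reference dosage matrix, shape (n_individuals, n_sites), columns
        aligned with ``covered_sites``; MISSING entries allowed.
    """
    m = len(covered_sites)
    dosage = np.asarray(reference_dosages)
    if dosage.ndim != 2 or dosage.shape[1] != m:
        raise ValueError(
            f"reference dosage shape {dosage.shape} does not match {m} sites"
        )
    if dosage.shape[0] < 2:
        raise ValueError("LD reference needs at least 2 individuals")
    keep = np.ones(m, dtype=bool)
    changed = True
    while changed:
        changed = False
        kept_idx = np.flatnonzero(keep)
        start = 0
        while start < kept_idx.size:
            window = kept_idx[start : start + cfg.window_size]
            r2 = _window_r2_matrix(dosage[:, window])
            for a in range(window.size):
                i = window[a]
                if not keep[i]:
                    continue
                for b in range(a + 1, window.size):
                    j = window[b]
                    if keep[j] and r2[a, b] > cfg.r2_threshold:
                        keep[j] = False  # drop the later site of the pair
                        changed = True
            if start + cfg.window_size >= kept_idx.size:
                break
            start += cfg.step
    retained = [covered_sites[i] for i in np.flatnonzero(keep)]
    logger.debug("clumping kept %d of %d covered sites", len(retained), m)
    return retained
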