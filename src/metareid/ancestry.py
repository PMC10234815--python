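"""Ancestry prediction from ultra-low-coverage read evidence.

Each candidate population A contributes an expected likelihood score

    E(LS_A) = sum_i sum_g P(g | p_iA) * log L(g, n_i, k_i)

where P(g | p) are Hardy-Weinberg genotype frequencies at population A's
alt-allele frequency. The population maximizing E(LS_A) is the prediction;
no standardization is applied. Because only expectations over genotypes are
needed, this works at coverages far below what genotype calling requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .likelihood_core import ErrorModel, hwe_genotype_freqs, log_likelihood_by_genotype
from .panel_io import SitePanel
from .site_observe import ObservationSet

#: Relative score difference below which two populations are declared tied.
TIE_RELATIVE_TOLERANCE = 1e-9


@dataclass
class AncestryResult:
    """Per-population expected scores, the argmax prediction, and a tie flag."""

    scores: dict[str, float]
    predicted: str
    tie: bool
    n_sites: int
    n_bases: int


def expected_score_for_population(
    obs: ObservationSet, freqs_A: np.ndarray, em: ErrorModel
) -> float:
    """E(LS_A): expected likelihood score under population A's frequencies."""
    freqs_A = np.asarray(freqs_A, dtype=float)
    if freqs_A.shape != (len(obs),):
        raise ValueError("freqs must align with the observation set")
    table = log_likelihood_by_genotype(obs.n, obs.k, em)
    weights = hwe_genotype_freqs(freqs_A)
    return float((weights * table).sum())


def predict_ancestry(
    obs: ObservationSet,
    panel: SitePanel,
    populations: Sequence[str] | None = None,
    em: ErrorModel = ErrorModel(),
    tie_tolerance: float = TIE_RELATIVE_TOLERANCE,
) -> AncestryResult:
    """Score every population on a common site set and return the argmax.

    Sites lacking a frequency (NaN) in any population are dropped for all
    populations, so the scores stay comparable. Ties within ``tie_tolerance``
    (relative) are flagged and broken lexicographically.

    Raises
    ------
    ValueError
        If no site is usable or fewer than two populations are given.
    """
    pops = list(populations) if populations is not None else panel.populations
    if len(pops) < 2:
        raise ValueError("ancestry prediction needs at least two populations")
    freq_matrix = np.stack([panel_freqs_for(obs, panel, pop) for pop in pops])
    usable = np.isfinite(freq_matrix).all(axis=0)
    if not usable.any():
        raise ValueError("no usable sites: every site lacks a frequency somewhere")
    obs_use = obs.subset(np.flatnonzero(usable))
    scores = {
        pop: expected_score_for_population(obs_use, freq_matrix[i][usable], em)
        for i, pop in enumerate(pops)
    }
    ranked = sorted(scores, key=lambda pop: (-scores[pop], pop))
    best = ranked[0]
    tie = False
    if len(ranked) > 1:
        a, b = scores[best], scores[ranked[1]]
        scale = max(abs(a), abs(b), 1.0)
        tie = abs(a - b) <= tie_tolerance * scale
    return AncestryResult(
        scores=scores,
        predicted=best,
        tie=tie,
        n_sites=obs_use.n_sites,
        n_bases=obs_use.n_bases,
    )


def panel_freqs_for(obs: ObservationSet, panel: SitePanel, population: str) -> np.ndarray:
    """Population frequencies aligned to an observation set (NaN if absent)."""
    p = panel.frequencies(population)
    out = np.full(len(obs), np.nan)
    for i, site in enumerate(obs.sites):
        idx = panel.lookup(site.chrom, site.pos)
        if idx is not None and (panel.sites[idx].ref, panel.sites[idx].alt) == (site.ref, site.alt):
            out[i] = p[idx]
    return out
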