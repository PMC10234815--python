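"""The probability model behind the likelihood score.

At a biallelic SNP site covered by ``n`` read bases of which ``k`` match the
reference allele, the probability that a diploid individual carrying ``g``
alternative alleles (g = 0, 1, 2) produced those bases — assuming each base
is read independently and miscalled with probability ``epsilon`` — is

    L(g, n, k) = (1/2^n) * [(2-g)*eps + g*(1-eps)]^(n-k)
                         * [g*eps + (2-g)*(1-eps)]^k

The likelihood score of an individual is the sum of log L over the
(approximately independent, LD-pruned) covered sites. Its null distribution
— the score of a random member of the population — has closed-form moments
under Hardy-Weinberg genotype frequencies P(g | p) = ((1-p)^2, 2p(1-p), p^2),
which standardize the observed score into a z-score and a one-sided normal
P value. An empirical P value from simulated genotype vectors is available
as a cross-check.

All arithmetic is in natural-log space: with eps = 1e-6 the per-site
likelihoods span hundreds of orders of magnitude over a few hundred sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .panel_io import MISSING
from .site_observe import ObservationSet

DEFAULT_EPSILON = 1e-6
LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error probability (single global constant)."""

    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")


@dataclass
class ScoreResult:
    """Likelihood score of one candidate with its null moments and tests.

    ``z`` and the P values are NaN when the null variance is zero or no
    sites were usable.
    """

    ls: float
    e_null: float
    v_null: float
    z: float
    p_normal: float
    n_sites: int
    n_bases: int
    p_empirical: float | None = None


def log_likelihood_by_genotype(
    n: np.ndarray, k: np.ndarray, em: ErrorModel
) -> np.ndarray:
    """log L(g, n, k) for g = 0, 1, 2 at every site; shape (3, n_sites)."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    eps = em.epsilon
    out = np.empty((3,) + n.shape, dtype=float)
    for g in (0, 1, 2):
        alt_term = (2 - g) * eps + g * (1.0 - eps)  # per alternative-allele base
        ref_term = g * eps + (2 - g) * (1.0 - eps)  # per reference-allele base
        out[g] = -n * LN2 + (n - k) * np.log(alt_term) + k * np.log(ref_term)
    return out


def genotype_likelihood(g: int, n: int, k: int, em: ErrorModel) -> float:
    """Probability L(g, n, k) that genotype ``g`` produced the observed bases."""
    if g not in (0, 1, 2):
        raise ValueError(f"genotype dosage must be 0, 1 or 2, got {g}")
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"require n >= 1 and 0 <= k <= n, got n={n}, k={k}")
    table = log_likelihood_by_genotype(np.array([n]), np.array([k]), em)
    return float(np.exp(table[g, 0]))


def likelihood_score(
    obs: ObservationSet, dosages: np.ndarray, em: ErrorModel
) -> tuple[float, int, int]:
    """Summed log-likelihood of one individual's dosages over the observations.

    Sites with MISSING dosage are skipped and excluded from the returned
    site and base counts.

    Returns
    -------
    (ls, n_used_sites, n_used_bases); ``ls`` is NaN when no site is usable.
    """
    dosages = np.asarray(dosages)
    if dosages.shape != (len(obs),):
        raise ValueError("dosages must align with the observation set")
    mask = dosages != MISSING
    if not mask.any():
        return float("nan"), 0, 0
    table = log_likelihood_by_genotype(obs.n[mask], obs.k[mask], em)
    g = dosages[mask].astype(np.intp)
    ls = float(table[g, np.arange(g.size)].sum())
    return ls, int(mask.sum()), int(obs.n[mask].sum())


def hwe_genotype_freqs(p):
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2).

    Accepts a scalar or an array of allele frequencies; returns an array of
    shape (3,) or (3, n).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must be in [0, 1]")
    return np.stack([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


def null_moments(
    obs: ObservationSet,
    freqs: np.ndarray,
    em: ErrorModel,
    site_subset: Sequence[int] | np.ndarray | None = None,
) -> tuple[float, float]:
    """Expectation and variance of the likelihood score under the null.

    The null draws a genotype independently at each site from HWE frequencies
    with population alt-allele frequency ``freqs[i]``. ``site_subset`` (index
    array or boolean mask) restricts the moments to the sites actually used
    for an individual's score, so scores with different missingness remain
    comparable.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (len(obs),):
        raise ValueError("freqs must align with the observation set")
    n, k = obs.n, obs.k
    if site_subset is not None:
        idx = np.asarray(site_subset)
        n, k, freqs = n[idx], k[idx], freqs[idx]
    if n.size == 0:
        return float("nan"), float("nan")
    table = log_likelihood_by_genotype(n, k, em)  # (3, m)
    weights = hwe_genotype_freqs(freqs)  # (3, m)
    e_site = (weights * table).sum(axis=0)
    v_site = (weights * (table - e_site) ** 2).sum(axis=0)
    return float(e_site.sum()), float(v_site.sum())


def standardize_and_test(ls: float, e_null: float, v_null: float) -> tuple[float, float]:
    """Standardized score z = (LS - E)/sqrt(V) and its one-sided normal P.

    The alternative is that the candidate matches the sample, which inflates
    the score, so the P value is the upper tail. Returns (NaN, NaN) when the
    null variance is zero or any input is undefined.
    """
    if v_null < 0:
        raise ValueError(f"null variance must be >= 0, got {v_null}")
    if v_null == 0 or not np.isfinite(ls) or not np.isfinite(e_null) or not np.isfinite(v_null):
        return float("nan"), float("nan")
    z = (ls - e_null) / np.sqrt(v_null)
    return float(z), float(stats.norm.sf(z))


def empirical_pvalue(
    ls: float,
    obs: ObservationSet,
    freqs: np.ndarray,
    em: ErrorModel,
    n_draws: int = 99_999,
    seed: int | None = None,
    site_subset: Sequence[int] | np.ndarray | None = None,
    chunk: int = 4096,
) -> float:
    """Rank-based P value against simulated population genotype vectors.

    Draws ``n_draws`` genotype vectors (per-site independent HWE sampling
    from ``freqs``), scores each, and returns
    (1 + #{LS_sim > ls}) / (n_draws + 1); ties count toward the null.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (len(obs),):
        raise ValueError("freqs must align with the observation set")
    n, k = obs.n, obs.k
    if site_subset is not None:
        idx = np.asarray(site_subset)
        n, k, freqs = n[idx], k[idx], freqs[idx]
    table = log_likelihood_by_genotype(n, k, em)  # (3, m)
    cum0 = (1.0 - freqs) ** 2
    cum1 = cum0 + 2.0 * freqs * (1.0 - freqs)
    rng = np.random.default_rng(seed)
    higher = 0
    remaining = n_draws
    while remaining > 0:
        c = min(chunk, remaining)
        remaining -= c
        u = rng.random((c, freqs.size))
        g = (u >= cum0).astype(np.intp) + (u >= cum1).astype(np.intp)
        ls_sim = table[g, np.arange(freqs.size)].sum(axis=1)
        higher += int((ls_sim > ls).sum())
    return (1 + higher) / (n_draws + 1)
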