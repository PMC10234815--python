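"""Synthetic inputs with the statistical structure the methods assume.

Everything the pipeline consumes can be generated here: allele-frequency
panels with Balding-Nichols population structure, Hardy-Weinberg genotypes,
Mendelian offspring, ultra-low-coverage read-base observations with
sequencing error and optional non-host contamination, and per-chromosome
read-count profiles for sex inference.

Coverage is modelled at site level: the number of bases covering a SNP site
is Poisson with mean ``lam``, and ``lam`` is numerically the genome coverage
(at coverages well below 1 this is statistically equivalent to thinning
reads, without carrying a reference genome). A "whole-genome" experiment is
emulated by drawing depths over a large implicit site catalogue and
instantiating only the covered sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel_io import MISSING, GenotypeSet, SiteKey, SitePanel
from .site_observe import ObservationSet

#: GRCh37 chromosome lengths (bp), full sequence.
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

MafSpec = tuple  # ("uniform", lo, hi) or ("one_over_p", lo, hi)
DEFAULT_MAF: MafSpec = ("uniform", 0.01, 0.5)

_FREQ_FLOOR = 1e-9  # keep Balding-Nichols draws strictly inside (0, 1)


@dataclass
class SimConfig:
    """Scenario description for the simulator and the ``simulate`` command."""

    n_sites: int = 10_000
    maf: MafSpec = DEFAULT_MAF
    populations: Sequence[str] = ("POP",)
    fst: float = 0.0
    n_individuals: int = 100
    families: Sequence[tuple[str, str, str]] = ()  # (parent1, parent2, child)
    depth: float = 0.01  # mean bases per site ~ coverage proxy
    eps_sim: float = 1e-3
    contamination_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("require 0 <= F < 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.eps_sim < 0.5):
            raise ValueError("eps_sim must be in [0, 0.5)")
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination fraction must be in [0, 1]")


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_maf(spec: MafSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    kind, lo, hi = spec
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError(f"degenerate MAF spec {spec}; need 0 < lo < hi <= 0.5")
    if kind == "uniform":
        return rng.uniform(lo, hi, size)
    if kind == "one_over_p":
        # density proportional to 1/p on [lo, hi]: inverse-CDF sampling
        u = rng.random(size)
        return lo * (hi / lo) ** u
    raise ValueError(f"unknown MAF spectrum {kind!r}")


def _synthetic_sites(
    positions: np.ndarray, rng: np.random.Generator, chrom: str = "1"
) -> list[SiteKey]:
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, positions.size)
    alt_i = (ref_i + rng.integers(1, 4, positions.size)) % 4
    return [
        SiteKey(chrom, int(pos), str(bases[r]), str(bases[a]))
        for pos, r, a in zip(positions, ref_i, alt_i)
    ]


def simulate_panel(
    cfg: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[SitePanel, np.ndarray]:
    """Generate a site panel with per-population Balding-Nichols frequencies.

    Ancestral frequencies follow ``cfg.maf``; each population's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p when F > 0, and
    exactly ancestral when F = 0.

    Returns (panel, ancestral frequencies).
    """
    rng = _rng(cfg.seed if seed is None else seed)
    ancestral = _draw_maf(cfg.maf, cfg.n_sites, rng)
    positions = np.arange(1, cfg.n_sites + 1) * 1000
    sites = _synthetic_sites(positions, rng)
    freq: dict[str, np.ndarray] = {}
    for pop in cfg.populations:
        if cfg.fst == 0.0:
            freq[pop] = ancestral.copy()
        else:
            a = ancestral * (1.0 - cfg.fst) / cfg.fst
            b = (1.0 - ancestral) * (1.0 - cfg.fst) / cfg.fst
            freq[pop] = np.clip(rng.beta(a, b), _FREQ_FLOOR, 1.0 - _FREQ_FLOOR)
    return SitePanel(sites=sites, freq=freq), ancestral


def simulate_genotypes(
    panel: SitePanel,
    population: str,
    n_individuals: int,
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "I",
) -> GenotypeSet:
    """Draw HWE genotypes: per site, dosage ~ Binomial(2, p), independently."""
    rng = _rng(seed)
    p = panel.frequencies(population)
    dosage = rng.binomial(2, p, size=(n_individuals, len(panel))).astype(np.int16)
    ids = [f"{id_prefix}{i:04d}" for i in range(n_individuals)]
    return GenotypeSet(individuals=ids, dosage=dosage)


def simulate_offspring(
    parent1: np.ndarray,
    parent2: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Mendelian offspring: one allele transmitted uniformly from each parent.

    A heterozygous parent transmits the alternative allele with probability
    1/2. MISSING in either parent propagates to the offspring.
    """
    rng = _rng(seed)
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError("parent dosage vectors must be aligned")
    t1 = rng.binomial(1, np.clip(p1, 0, 2) / 2.0)
    t2 = rng.binomial(1, np.clip(p2, 0, 2) / 2.0)
    child = (t1 + t2).astype(np.int16)
    child[(p1 == MISSING) | (p2 == MISSING)] = MISSING
    return child


def _prob_ref_base(dosages: np.ndarray, eps: float) -> np.ndarray:
    """P(read base = ref) per site given the genotype and base error rate."""
    # g=0 -> 1-eps; g=1 -> 1/2 (error cancels); g=2 -> eps
    g = np.asarray(dosages, dtype=float)
    return (1.0 - g / 2.0) * (1.0 - eps) + (g / 2.0) * eps


def simulate_observations(
    dosages: np.ndarray,
    panel: SitePanel,
    lam: float,
    eps_sim: float,
    seed: int | np.random.Generator | None = None,
) -> ObservationSet:
    """Site-level read simulation for one individual.

    Depth per site is Poisson(``lam``); each base's true allele is drawn from
    the genotype (heterozygote: reference with probability 1/2) and flipped
    to the other allele with probability ``eps_sim``. Sites with zero depth
    or MISSING dosage are omitted.
    """
    rng = _rng(seed)
    dosages = np.asarray(dosages)
    if dosages.shape != (len(panel),):
        raise ValueError("dosages must align with the panel")
    n = rng.poisson(lam, len(panel))
    keep = (n > 0) & (dosages != MISSING)
    idx = np.flatnonzero(keep)
    k = rng.binomial(n[idx], _prob_ref_base(dosages[idx], eps_sim))
    return ObservationSet(
        sites=[panel.sites[i] for i in idx], n=n[idx], k=k
    )


def mix_contamination(
    host_dosages: np.ndarray,
    contaminant_dosages: np.ndarray,
    panel: SitePanel,
    lam: float,
    eps_sim: float,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> ObservationSet:
    """Simulate observations where each base comes from the contaminant
    genotype with probability ``fraction`` and from the host otherwise."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = _rng(seed)
    host = np.asarray(host_dosages)
    cont = np.asarray(contaminant_dosages)
    if host.shape != cont.shape or host.shape != (len(panel),):
        raise ValueError("host and contaminant dosages must align with the panel")
    n = rng.poisson(lam, len(panel))
    keep = (n > 0) & (host != MISSING) & (cont != MISSING)
    idx = np.flatnonzero(keep)
    p_ref = (1.0 - fraction) * _prob_ref_base(host[idx], eps_sim) + fraction * _prob_ref_base(cont[idx], eps_sim)
    k = rng.binomial(n[idx], p_ref)
    return ObservationSet(sites=[panel.sites[i] for i in idx], n=n[idx], k=k)


def simulate_sparse_cohort(
    genome_sites: int,
    coverage: float,
    n_candidates: int,
    maf: MafSpec = DEFAULT_MAF,
    eps_sim: float = 1e-3,
    seed: int | np.random.Generator | None = None,
    population: str = "POP",
    contaminant_fraction: float = 0.0,
    include_offspring: bool = False,
) -> tuple[SitePanel, ObservationSet, GenotypeSet, str]:
    """One re-identification replicate over an implicit genome-wide catalogue.

    Depths are drawn over ``genome_sites`` potential SNP sites at mean
    ``coverage``; only the covered sites are instantiated (panel frequencies,
    the truth individual's genotype, and ``n_candidates`` total candidate
    genotypes including the truth). Sites are independent, so restricting to
    the covered subset loses nothing.

    When ``include_offspring`` is true, candidate ``child`` is a Mendelian
    offspring of the truth and a random mate. ``contaminant_fraction`` mixes
    bases from an unrelated individual into the observations.

    Returns (panel of covered sites, observations, candidates, truth id).
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = _rng(seed)
    depth = rng.poisson(coverage, genome_sites)
    idx = np.flatnonzero(depth > 0)
    n = depth[idx].astype(np.int64)
    p = _draw_maf(maf, idx.size, rng)
    sites = _synthetic_sites(idx + 1, rng)
    panel = SitePanel(sites=sites, freq={population: p})

    dosage = rng.binomial(2, p, size=(n_candidates, idx.size)).astype(np.int16)
    ids = [f"I{i:04d}" for i in range(n_candidates)]
    truth_id = ids[0]
    if include_offspring and n_candidates >= 2:
        mate = rng.binomial(2, p, size=idx.size).astype(np.int16)
        dosage[1] = simulate_offspring(dosage[0], mate, rng)
        ids[1] = "child"
    candidates = GenotypeSet(individuals=ids, dosage=dosage)

    p_ref = _prob_ref_base(dosage[0], eps_sim)
    if contaminant_fraction > 0.0:
        contaminant = rng.binomial(2, p, size=idx.size).astype(np.int16)
        p_ref = (1.0 - contaminant_fraction) * p_ref + contaminant_fraction * _prob_ref_base(contaminant, eps_sim)
    k = rng.binomial(n, p_ref)
    obs = ObservationSet(sites=sites, n=n, k=k)
    return panel, obs, candidates, truth_id


def expected_coverage(
    total_sequenced_bases: float,
    human_read_fraction: float,
    genome_size: float = 3.1e9,
) -> float:
    """Expected human-genome coverage contributed by host reads.

    E.g. a 10 Gbp gut-metagenome library with 1% human reads yields
    0.1 Gbp of human sequence, ~0.03x of a 3.1 Gbp genome.
    """
    if total_sequenced_bases < 0 or not (0.0 <= human_read_fraction <= 1.0):
        raise ValueError("need total bases >= 0 and fraction in [0, 1]")
    return total_sequenced_bases * human_read_fraction / genome_size


def simulate_depth_profiles(
    sex: str,
    n_reads: int,
    chrom_lengths: Mapping[str, int],
    female_y_noise: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> dict[str, int]:
    """Multinomial per-chromosome read counts for one individual.

    Reads are allocated proportionally to copy number x chromosome length:
    autosomes carry two copies; males carry one X and one Y; females carry
    two X and a Y weight of ``female_y_noise`` x the two-copy autosomal
    per-base weight (mismapping noise floor).
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = _rng(seed)
    chroms = list(chrom_lengths)
    weights = []
    for chrom in chroms:
        length = chrom_lengths[chrom]
        if chrom == "X":
            copies = 2.0 if sex == "female" else 1.0
        elif chrom == "Y":
            copies = 2.0 * female_y_noise if sex == "female" else 1.0
        else:
            copies = 2.0
        weights.append(copies * length)
    w = np.asarray(weights, dtype=float)
    counts = rng.multinomial(n_reads, w / w.sum())
    return dict(zip(chroms, (int(c) for c in counts)))
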