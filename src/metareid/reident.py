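"""Re-identification of metagenome samples against a genotype database.

For every query (a set of per-site read-base counts) the covered panel sites
are LD-pruned, every candidate genotype record is scored, the score is
standardized against its population null, and two decision rules are
applied: (1) the candidate with the highest likelihood score, and (2) any
candidate whose one-sided P value clears a Bonferroni-corrected threshold
alpha / (n_queries x n_candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clumping import ClumpConfig, prune_sites
from .likelihood_core import (
    ErrorModel,
    empirical_pvalue,
    likelihood_score,
    null_moments,
    standardize_and_test,
)
from .panel_io import MISSING, GenotypeSet, SitePanel
from .site_observe import ObservationSet

logger = logging.getLogger("metareid")

#: Columns of the match-result table, in output order.
MATCH_COLUMNS = [
    "query", "candidate", "n_sites", "n_bases", "LS", "E", "V", "z",
    "p_normal", "p_empirical", "top_score", "significant",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class MatchRunConfig:
    """Knobs for a re-identification run."""

    alpha: float = 0.05
    n_tests: int | None = None  # default: n_queries x n_candidates
    em: ErrorModel = field(default_factory=ErrorModel)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    compute_empirical: bool = False
    n_empirical_draws: int = 99_999
    maf_range: tuple[float, float] | None = None  # (lo, hi]: restrict by panel MAF
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests is not None and self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


def _nan_row(query: str, candidate: str) -> dict:
    return {
        "query": query, "candidate": candidate, "n_sites": 0, "n_bases": 0,
        "LS": np.nan, "E": np.nan, "V": np.nan, "z": np.nan,
        "p_normal": np.nan, "p_empirical": np.nan,
        "top_score": False, "significant": False,
    }


def run_match(
    obs_by_query: Mapping[str, ObservationSet],
    genotypes: GenotypeSet,
    panel: SitePanel,
    population: str,
    cfg: MatchRunConfig = MatchRunConfig(),
    ld_reference: GenotypeSet | None = None,
) -> pd.DataFrame:
    """Score every query x candidate pair and apply both decision rules.

    ``ld_reference`` supplies the dosage matrix for clumping (aligned to the
    panel); the candidate set itself is used when absent. Queries with zero
    usable sites yield NA rows.
    """
    freqs_all = panel.frequencies(population)
    ld = ld_reference if ld_reference is not None else genotypes
    if ld.n_sites != len(panel) or genotypes.n_sites != len(panel):
        raise ValueError("genotypes and LD reference must be aligned to the panel")
    threshold = bonferroni_threshold(
        cfg.alpha,
        cfg.n_tests if cfg.n_tests is not None else len(obs_by_query) * len(genotypes),
    )
    rng = np.random.default_rng(cfg.seed)

    rows: list[dict] = []
    for query, obs in obs_by_query.items():
        panel_idx = np.array(
            [panel.lookup(s.chrom, s.pos) for s in obs.sites], dtype=object
        )
        usable = np.array([i is not None for i in panel_idx], dtype=bool)
        if cfg.maf_range is not None:
            lo, hi = cfg.maf_range
            maf = panel.maf(population)
            for j in np.flatnonzero(usable):
                m = maf[panel_idx[j]]
                if not (lo < m <= hi):
                    usable[j] = False
        obs_idx = np.flatnonzero(usable)
        if obs_idx.size == 0:
            logger.warning("query %s: no usable sites", query)
            rows.extend(_nan_row(query, c) for c in genotypes.individuals)
            continue
        pidx = panel_idx[obs_idx].astype(np.intp)
        retained_local = prune_sites(
            list(range(obs_idx.size)), ld.dosage[:, pidx], cfg.clump
        )
        sel = obs_idx[retained_local]
        obs_sel = obs.subset(sel)
        pidx_sel = pidx[retained_local]
        freqs = freqs_all[pidx_sel]

        best_ls = -np.inf
        best_i = None
        for ci, candidate in enumerate(genotypes.individuals):
            dos = genotypes.dosage[ci, pidx_sel]
            ls, n_sites, n_bases = likelihood_score(obs_sel, dos, cfg.em)
            if n_sites == 0:
                rows.append(_nan_row(query, candidate))
                continue
            subset = dos != MISSING
            e_null, v_null = null_moments(obs_sel, freqs, cfg.em, subset)
            z, p_norm = standardize_and_test(ls, e_null, v_null)
            p_emp = np.nan
            if cfg.compute_empirical:
                p_emp = empirical_pvalue(
                    ls, obs_sel, freqs, cfg.em,
                    n_draws=cfg.n_empirical_draws,
                    seed=rng.integers(2**31 - 1),
                    site_subset=subset,
                )
            rows.append({
                "query": query, "candidate": candidate,
                "n_sites": n_sites, "n_bases": n_bases,
                "LS": ls, "E": e_null, "V": v_null, "z": z,
                "p_normal": p_norm, "p_empirical": p_emp,
                "top_score": False,
                "significant": bool(np.isfinite(p_norm) and p_norm < threshold),
            })
            if np.isfinite(z) and ls > best_ls:
                best_ls, best_i = ls, len(rows) - 1
        if best_i is not None:
            rows[best_i]["top_score"] = True

    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def evaluate_decisions(
    matches: pd.DataFrame, truth: Mapping[str, str | None]
) -> dict[str, float]:
    """Confusion-matrix summary of a match table against known truth.

    ``truth`` maps each query to its true candidate id (or None when the
    donor is absent from the database). Sensitivity counts true pairs called
    significant; specificity counts non-pairs not called; top-score accuracy
    counts queries whose highest-scoring candidate is the truth, among
    queries whose truth is present in the candidate set.
    """
    candidates = set(matches["candidate"])
    true_pairs = n_true_called = 0
    non_pairs = n_non_called = 0
    n_with_truth = n_top_correct = 0
    for (query,), group in matches.groupby(["query"]):
        true_candidate = truth.get(query)
        if true_candidate not in candidates:
            true_candidate = None
        for _, row in group.iterrows():
            is_true = true_candidate is not None and row["candidate"] == true_candidate
            if is_true:
                true_pairs += 1
                n_true_called += bool(row["significant"])
            else:
                non_pairs += 1
                n_non_called += bool(row["significant"])
        if true_candidate is not None:
            n_with_truth += 1
            top = group.loc[group["top_score"], "candidate"]
            n_top_correct += bool(len(top) and top.iloc[0] == true_candidate)
    return {
        "sensitivity": n_true_called / true_pairs if true_pairs else float("nan"),
        "specificity": 1.0 - (n_non_called / non_pairs) if non_pairs else float("nan"),
        "top_score_accuracy": (
            n_top_correct / n_with_truth if n_with_truth else float("nan")
        ),
    }
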