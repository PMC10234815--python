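"""Per-site read-base evidence: pileup decoding and contamination metrics.

Turns samtools-style pileup text into per-site counts of reference and
alternative bases (after base-quality filtering), the raw material for the
likelihood score. Also computes the mitochondrial non-major-allele fraction
used as a crude non-host-contamination metric: a clean single-donor sample
should show one haplotype at essentially every mtDNA position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .panel_io import SiteKey, SitePanel, normalize_chrom

logger = logging.getLogger("metareid")

DEFAULT_MIN_BASE_QUALITY = 20  # phred; pairs with upstream MAPQ >= 40 filtering


class PileupError(ValueError):
    """Raised when pileup text cannot be decoded."""


@dataclass(frozen=True)
class SiteObservation:
    """Base counts at one SNP site: ``n`` total, ``k`` reference bases."""

    site: SiteKey
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.n < 1 or not (0 <= self.k <= self.n):
            raise ValueError(f"invalid counts n={self.n}, k={self.k}")


@dataclass
class ObservationSet:
    """Column-oriented collection of :class:`SiteObservation`.

    ``n[i]`` and ``k[i]`` are the total and reference-base counts at
    ``sites[i]``; every n is >= 1.
    """

    sites: list[SiteKey]
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if not (len(self.sites) == self.n.size == self.k.size):
            raise ValueError("sites, n and k must have equal length")
        if self.n.size and (self.n.min() < 1 or (self.k < 0).any() or (self.k > self.n).any()):
            raise ValueError("require n >= 1 and 0 <= k <= n at every site")

    @classmethod
    def from_observations(cls, observations: Iterable[SiteObservation]) -> "ObservationSet":
        obs = list(observations)
        return cls(
            sites=[o.site for o in obs],
            n=np.array([o.n for o in obs], dtype=np.int64),
            k=np.array([o.k for o in obs], dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteObservation]:
        for site, n, k in zip(self.sites, self.n, self.k):
            yield SiteObservation(site, int(n), int(k))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_bases(self) -> int:
        return int(self.n.sum())

    def subset(self, indices: Sequence[int]) -> "ObservationSet":
        idx = np.asarray(indices, dtype=np.intp)
        return ObservationSet(
            sites=[self.sites[i] for i in idx], n=self.n[idx], k=self.k[idx]
        )


# ---------------------------------------------------------------------------
# Pileup decoding


def decode_pileup_bases(bases: str, quals: str, ref: str) -> list[tuple[str, int]]:
    """Decode one pileup base string into (base, phred-quality) pairs.

    Handles the full grammar: ``.``/``,`` (reference base), ACGT in either
    case, ``^`` + mapping-quality character (read start), ``$`` (read end),
    ``+n<seq>``/``-n<seq>`` indel runs (skipped, no quality), and ``*``,
    ``>``/``<`` placeholders (consumed with their quality, reported as-is).
    """
    out: list[tuple[str, int]] = []
    ref = ref.upper()
    i = 0
    qi = 0
    L = len(bases)
    while i < L:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus encoded mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            start = i
            while i < L and bases[i].isdigit():
                i += 1
            if start == i:
                raise PileupError(f"indel marker without length at column {i}")
            i += int(bases[start:i])  # inserted/deleted sequence carries no quality
            continue
        if qi >= len(quals):
            raise PileupError("more base entries than quality characters")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            out.append((ref, q))
        elif c.upper() in "ACGTN":
            out.append((c.upper(), q))
        elif c in "*<>":
            out.append((c, q))
        else:
            raise PileupError(f"unexpected pileup character {c!r}")
    if qi != len(quals):
        raise PileupError("fewer base entries than quality characters")
    return out


def pileup_to_counts(
    pileup_source: str | Path,
    panel: SitePanel,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> ObservationSet:
    """Convert 6-column samtools pileup text into per-site base counts.

    Only bases equal to the panel's ref or alt allele, with quality at or
    above ``min_base_quality``, are counted; deletions (``*``) and reference
    skips (``>``/``<``) never count. Mapping-quality filtering is assumed to
    have been applied when the pileup was generated.
    """
    sites: list[SiteKey] = []
    n_list: list[int] = []
    k_list: list[int] = []
    with open(pileup_source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise PileupError(
                    f"{pileup_source}: line {lineno}: expected 6 columns, got {len(parts)}"
                )
            chrom, pos_s, ref, depth_s, bases, quals = parts[:6]
            pos = int(pos_s)
            idx = panel.lookup(chrom, pos)
            if idx is None:
                continue
            try:
                decoded = decode_pileup_bases(bases, quals, ref)
            except PileupError as exc:
                raise PileupError(f"{chrom}:{pos}: {exc}") from None
            if len(decoded) != int(depth_s):
                raise PileupError(
                    f"{chrom}:{pos}: depth field {depth_s} does not match "
                    f"{len(decoded)} decoded bases"
                )
            site = panel.sites[idx]
            n = k = 0
            for base, q in decoded:
                if q < min_base_quality or base in "*<>":
                    continue
                if base == site.ref:
                    n += 1
                    k += 1
                elif base == site.alt:
                    n += 1
                # third-allele bases are excluded from n: the model is biallelic
            if n >= 1:
                sites.append(site)
                n_list.append(n)
                k_list.append(k)
    return ObservationSet(
        sites=sites,
        n=np.asarray(n_list, dtype=np.int64),
        k=np.asarray(k_list, dtype=np.int64),
    )


def pileup_base_counts(
    pileup_source: str | Path,
    chrom: str | None = None,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[tuple[str, dict[str, int]]]:
    """Per-position full base counts from pileup text (no panel restriction).

    Returns a list of (reference base, {base: count}) entries, one per
    position with at least one counted base; used for the mitochondrial
    non-major-allele fraction.
    """
    out: list[tuple[str, dict[str, int]]] = []
    target = normalize_chrom(chrom) if chrom is not None else None
    with open(pileup_source) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                continue
            if target is not None and normalize_chrom(parts[0]) != target:
                continue
            ref = parts[2].upper()
            counts: dict[str, int] = {}
            for base, q in decode_pileup_bases(parts[4], parts[5], ref):
                if q < min_base_quality or base not in "ACGT":
                    continue
                counts[base] = counts.get(base, 0) + 1
            if counts:
                out.append((ref, counts))
    return out


def nonmajor_allele_fraction(
    position_counts: Sequence[tuple[str, Mapping[str, int]]]
) -> float:
    """Fraction of read bases disagreeing with each position's major base.

    ``position_counts`` holds (reference base, base -> count) per mtDNA
    position; the major base is decided by plurality, ties broken toward the
    reference. A single-donor sample yields ~0; a mixture of two haplotypes
    at fraction f yields ~min(f, 1 - f) at the positions where they differ.

    Raises
    ------
    ValueError
        If there is no covered position (zero mtDNA coverage).
    """
    total = nonmajor = 0
    for ref, counts in position_counts:
        depth = sum(counts.values())
        if depth == 0:
            continue
        best = max(counts.values())
        ties = [b for b, c in counts.items() if c == best]
        major = ref if ref in ties else sorted(ties)[0]
        total += depth
        nonmajor += depth - counts.get(major, 0)
    if total == 0:
        raise ValueError("non-major allele fraction undefined: zero mtDNA coverage")
    return nonmajor / total
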