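"""Reading, writing and aligning the standard formats the tool touches.

The central containers are :class:`SitePanel` (biallelic SNP sites with
per-population alternative-allele frequencies), :class:`GenotypeSet`
(candidate individuals' alt-allele dosages aligned to a panel) and
:class:`RegionMask` (BED intervals, e.g. non-pseudo-autosomal regions).

Conventions
-----------
* VCF, pileup and site-count tables are 1-based; BED is 0-based half-open.
* Chromosome names are normalized by stripping a leading ``chr``.
* Allele matching between files requires the exact (ref, alt) pair or the
  exact swap (dosage complemented); anything else is treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger("metareid")

#: Sentinel for an unobserved dosage in a :class:`GenotypeSet`.
MISSING: int = -1

_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel, genotype or region file cannot be used."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so GRCh37/GRCh38 naming coexists."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class SiteKey(NamedTuple):
    """A biallelic SNP site: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "SiteKey":
        if self.pos < 1:
            raise PanelError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise PanelError(f"alleles must be single bases A/C/G/T: {self}")
        if self.ref == self.alt:
            raise PanelError(f"ref and alt must differ: {self}")
        return self


@dataclass
class SitePanel:
    """Ordered biallelic SNP sites with per-population alt-allele frequencies.

    Parameters
    ----------
    sites
        Sites in genomic order (chromosome, then position ascending).
    freq
        Mapping population label -> array of alternative-allele frequencies,
        one per site, each in [0, 1].
    """

    sites: list[SiteKey]
    freq: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for s in self.sites:
            key = (s.chrom, s.pos)
            if key in seen:
                raise PanelError(f"duplicate site at {s.chrom}:{s.pos}")
            seen.add(key)
        for pop, p in self.freq.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.sites),):
                raise PanelError(
                    f"frequency vector for {pop!r} has length {p.shape}, "
                    f"expected {len(self.sites)}"
                )
            with np.errstate(invalid="ignore"):
                if np.any((p < 0) | (p > 1)):
                    raise PanelError(f"frequencies for {pop!r} outside [0, 1]")
            self.freq[pop] = p
        self._index = {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        return list(self.freq)

    def lookup(self, chrom: str, pos: int) -> int | None:
        """Index of the site at (chrom, pos), or None if absent."""
        return self._index.get((normalize_chrom(chrom), pos))

    def frequencies(self, population: str) -> np.ndarray:
        try:
            return self.freq[population]
        except KeyError:
            raise PanelError(
                f"unknown population {population!r}; panel has {self.populations}"
            ) from None

    def maf(self, population: str) -> np.ndarray:
        """Minor-allele frequency per site for one population."""
        p = self.frequencies(population)
        return np.minimum(p, 1.0 - p)

    def subset(self, indices: Sequence[int]) -> "SitePanel":
        idx = list(indices)
        return SitePanel(
            sites=[self.sites[i] for i in idx],
            freq={pop: p[idx] for pop, p in self.freq.items()},
        )


@dataclass
class GenotypeSet:
    """Alt-allele dosages (0/1/2, or MISSING) aligned to a :class:`SitePanel`.

    ``dosage`` has shape (n_individuals, n_sites).
    """

    individuals: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.individuals):
            raise PanelError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("dosage values must be 0, 1, 2 or MISSING")

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def __len__(self) -> int:
        return len(self.individuals)

    def dosages_for(self, individual: str) -> np.ndarray:
        try:
            i = self.individuals.index(individual)
        except ValueError:
            raise PanelError(f"unknown individual {individual!r}") from None
        return self.dosage[i]


@dataclass
class RegionMask:
    """A set of half-open 0-based genomic intervals (BED semantics).

    Overlapping or adjacent intervals are merged on construction.
    """

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise PanelError(
                    f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)"
                )
        self.intervals = self._merge(self.intervals)

    @staticmethod
    def _merge(
        intervals: Iterable[tuple[str, int, int]]
    ) -> list[tuple[str, int, int]]:
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(intervals):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged.pop()
                merged.append((chrom, prev[1], max(prev[2], end)))
            else:
                merged.append((chrom, start, end))
        return merged

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        c = normalize_chrom(chrom)
        zero = pos - 1
        return any(
            chrom_ == c and start <= zero < end
            for chrom_, start, end in self.intervals
        )

    def masked_length(self, chrom: str) -> int:
        """Total number of bases covered by the mask on ``chrom``."""
        c = normalize_chrom(chrom)
        return sum(end - start for ch, start, end in self.intervals if ch == c)


# ---------------------------------------------------------------------------
# VCF input


def _is_biallelic_snv(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _BASES
        and alts[0].upper() in _BASES
    )


def read_frequency_panel(
    vcf_source: str | Path,
    population_labels: Sequence[str],
    sample_populations: Mapping[str, str] | None = None,
) -> SitePanel:
    """Read a biallelic-SNV allele-frequency panel from a VCF.

    Frequencies are resolved, per population label, from an INFO field named
    ``<POP>_AF`` or ``AF_<POP>`` (or plain ``AF``); when ``sample_populations``
    maps the VCF samples to population labels, frequencies are instead
    computed from genotypes as alt-allele count / (2 x non-missing samples).

    Indels and multiallelic records are dropped (counts logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    group_cols: dict[str, np.ndarray] = {}
    if sample_populations is not None:
        samples = list(vcf.samples)
        for pop in population_labels:
            members = [i for i, s in enumerate(samples) if sample_populations.get(s) == pop]
            if not members:
                raise PanelError(f"no samples assigned to population {pop!r}")
            group_cols[pop] = np.asarray(members)

    sites: list[SiteKey] = []
    freqs: dict[str, list[float]] = {pop: [] for pop in population_labels}
    n_dropped = 0
    for variant in vcf:
        if not _is_biallelic_snv(variant.REF, variant.ALT):
            n_dropped += 1
            continue
        site = SiteKey(
            normalize_chrom(variant.CHROM),
            int(variant.POS),
            variant.REF.upper(),
            variant.ALT[0].upper(),
        ).validate()
        if sample_populations is not None:
            dosage = _gt_types_to_dosage(variant.gt_types)
            for pop in population_labels:
                d = dosage[group_cols[pop]]
                ok = d != MISSING
                if not ok.any():
                    freqs[pop].append(np.nan)
                else:
                    freqs[pop].append(float(d[ok].sum()) / (2.0 * int(ok.sum())))
        else:
            for pop in population_labels:
                value = None
                for key in (f"{pop}_AF", f"AF_{pop}", "AF" if pop == "AF" else None):
                    if key is None:
                        continue
                    value = variant.INFO.get(key)
                    if value is not None:
                        break
                if value is None and len(population_labels) == 1:
                    value = variant.INFO.get("AF")
                if value is None:
                    raise PanelError(
                        f"no INFO frequency field found for population {pop!r} "
                        f"at {site.chrom}:{site.pos}"
                    )
                if isinstance(value, tuple):
                    value = value[0]
                freqs[pop].append(float(value))
        sites.append(site)

    if n_dropped:
        logger.info("frequency panel: dropped %d non-biallelic-SNV records", n_dropped)
    if not sites:
        raise PanelError("no biallelic SNVs found in the frequency panel VCF")
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    return SitePanel(
        sites=[sites[i] for i in order],
        freq={pop: np.asarray(freqs[pop], dtype=float)[order] for pop in population_labels},
    )


def _gt_types_to_dosage(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    out = np.full(gt_types.shape, MISSING, dtype=np.int16)
    out[gt_types == 0] = 0
    out[gt_types == 1] = 1
    out[gt_types == 3] = 2
    return out


def read_genotypes(vcf_source: str | Path, panel: SitePanel) -> GenotypeSet:
    """Read candidate genotypes from a VCF, aligned to ``panel``.

    Records whose (ref, alt) is the exact swap of the panel's are complemented
    (dosage 2 - g); other allele mismatches are dropped. Sites absent from the
    VCF stay MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    individuals = list(vcf.samples)
    dosage = np.full((len(individuals), len(panel)), MISSING, dtype=np.int16)
    n_overlap = n_swapped = n_mismatch = 0
    for variant in vcf:
        if not _is_biallelic_snv(variant.REF, variant.ALT):
            continue
        idx = panel.lookup(variant.CHROM, int(variant.POS))
        if idx is None:
            continue
        site = panel.sites[idx]
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        d = _gt_types_to_dosage(variant.gt_types)
        if (ref, alt) == (site.ref, site.alt):
            pass
        elif (ref, alt) == (site.alt, site.ref):
            swap = d != MISSING
            d = np.where(swap, 2 - d, d)
            n_swapped += 1
        else:
            n_mismatch += 1
            continue
        dosage[:, idx] = d
        n_overlap += 1
    if n_swapped:
        logger.info("genotypes: complemented %d allele-swapped records", n_swapped)
    if n_mismatch:
        logger.info("genotypes: dropped %d allele-mismatched records", n_mismatch)
    if n_overlap == 0:
        raise PanelError("no sites in the genotype VCF overlap the panel")
    return GenotypeSet(individuals=individuals, dosage=dosage)


# ---------------------------------------------------------------------------
# Site-count tables

SITE_COUNT_HEADER = "#chrom\tpos\tref\talt\tn_ref\tn_alt"


def read_site_counts(table_source: str | Path, panel: SitePanel):
    """Read a tab-separated per-site base-count table aligned to ``panel``.

    Columns: chrom, pos, ref, alt, n_ref, n_alt. Rows with zero total depth
    are dropped; rows at positions absent from the panel are skipped (logged).

    Returns
    -------
    ObservationSet
    """
    from .site_observe import ObservationSet

    sites: list[SiteKey] = []
    n_list: list[int] = []
    k_list: list[int] = []
    n_skipped = 0
    with open(table_source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise PanelError(
                    f"{table_source}: line {lineno}: expected 6 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                chrom = normalize_chrom(parts[0])
                pos = int(parts[1])
                ref, alt = parts[2].upper(), parts[3].upper()
                n_ref, n_alt = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise PanelError(f"{table_source}: line {lineno}: {exc}") from None
            if n_ref < 0 or n_alt < 0:
                raise PanelError(f"{table_source}: line {lineno}: negative count")
            if n_ref + n_alt == 0:
                continue
            idx = panel.lookup(chrom, pos)
            if idx is None or (panel.sites[idx].ref, panel.sites[idx].alt) != (ref, alt):
                n_skipped += 1
                continue
            sites.append(panel.sites[idx])
            n_list.append(n_ref + n_alt)
            k_list.append(n_ref)
    if n_skipped:
        logger.info("site counts: skipped %d rows not matching the panel", n_skipped)
    return ObservationSet(
        sites=sites,
        n=np.asarray(n_list, dtype=np.int64),
        k=np.asarray(k_list, dtype=np.int64),
    )


def write_site_counts(path: str | Path, obs) -> None:
    """Write an ObservationSet as the canonical site-count TSV."""
    with open(path, "w") as handle:
        handle.write(SITE_COUNT_HEADER + "\n")
        for site, n, k in zip(obs.sites, obs.n, obs.k):
            handle.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{k}\t{n - k}\n"
            )


# ---------------------------------------------------------------------------
# VCF output (simulator products only)

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_panel_vcf(path: str | Path, panel: SitePanel) -> None:
    """Write a sites-only VCF carrying per-population AF INFO fields."""
    pops = panel.populations
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for pop in pops:
            handle.write(
                f'##INFO=<ID={pop}_AF,Number=1,Type=Float,'
                f'Description="Alt allele frequency in {pop}">\n'
            )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, s in enumerate(panel.sites):
            info = ";".join(f"{pop}_AF={panel.freq[pop][i]:.6g}" for pop in pops)
            handle.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t{info or '.'}\n")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(path: str | Path, panel: SitePanel, genotypes: GenotypeSet) -> None:
    """Write simulated genotypes as an unphased GT-only VCF."""
    if genotypes.n_sites != len(panel):
        raise PanelError("genotypes are not aligned to the panel")
    with open(path, "w") as handle:
        handle.write(_VCF_HEADER)
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for i, s in enumerate(panel.sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.dosage[:, i])
            handle.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED masks


def read_bed_mask(bed_source: str | Path) -> RegionMask:
    """Read a 3+ column BED file into a :class:`RegionMask` (intervals merged)."""
    intervals: list[tuple[str, int, int]] = []
    with open(bed_source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelError(f"{bed_source}: line {lineno}: fewer than 3 columns")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PanelError(f"{bed_source}: line {lineno}: {exc}") from None
            if start >= end:
                raise PanelError(
                    f"{bed_source}: line {lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return RegionMask(intervals=intervals)
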