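"""Per-sample genotype calling rules and the site pre-filter cascade.

The genotype rules: a site with coverage below 5X is missing; an alt-allele
frequency at or above 0.8 (or at or below 0.2) is a homozygous call; a
frequency strictly between those bounds is heterozygous only when each allele
is supported by at least 4 reads, otherwise the site is missing.

The pre-filter cascade ahead of the ED scan keeps biallelic sites, drops
sites where any single base reaches 95% of the wild-type pool, then drops
sites where either pool is below 10X; the accounting after each stage is
reported in the same order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io import BASES, PooledSiteCounts

logger = logging.getLogger(__name__)

MISSING = "missing"
HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class GenotypeCall:
    state: str
    allele_pair: tuple[str, str] | None = None
    hom_allele: str | None = None  # "ref" or "alt" when state == homozygous

    def __post_init__(self) -> None:
        if self.state == HETEROZYGOUS and self.allele_pair is not None:
            a, b = self.allele_pair
            if a == b:
                raise ValueError("heterozygous call requires two distinct bases")


@dataclass(frozen=True)
class FilterAccounting:
    """Site counts surviving each pre-filter stage, in cascade order."""

    total: int
    after_biallelic: int
    after_frequency: int
    after_depth: int

    def __post_init__(self) -> None:
        counts = (self.total, self.after_biallelic, self.after_frequency, self.after_depth)
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter accounting must be non-increasing, got {counts}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [[self.total, self.after_biallelic, self.after_frequency, self.after_depth]],
            columns=["Total", "Biallelic", "Frequency", "NA"],
        )


def call_genotype(
    ref_reads: int,
    alt_reads: int,
    ref_base: str | None = None,
    alt_base: str | None = None,
    min_depth: int = 5,
    hom_threshold: float = 0.8,
    min_het_reads: int = 4,
) -> GenotypeCall:
    """Classify a biallelic site of one sample from its ref/alt read counts.

    Thresholds are inclusive: depth exactly ``min_depth`` is callable, alt
    frequency exactly ``hom_threshold`` (or ``1 - hom_threshold``) is
    homozygous, and a heterozygous call needs at least ``min_het_reads`` on
    each allele.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    if depth < min_depth:
        return GenotypeCall(MISSING)
    # compare each allele's own frequency to the threshold so that the
    # inclusive boundaries (exactly 0.8 / 0.2) are exact in floating point
    if alt_reads / depth >= hom_threshold:
        pair = (alt_base, alt_base) if alt_base else None
        return GenotypeCall(HOMOZYGOUS, pair, hom_allele="alt")
    if ref_reads / depth >= hom_threshold:
        pair = (ref_base, ref_base) if ref_base else None
        return GenotypeCall(HOMOZYGOUS, pair, hom_allele="ref")
    if min(ref_reads, alt_reads) >= min_het_reads:
        pair = (ref_base, alt_base) if ref_base and alt_base else None
        return GenotypeCall(HETEROZYGOUS, pair)
    return GenotypeCall(MISSING)


def _retained_bases(site: PooledSiteCounts) -> list[int]:
    """Indices of bases with nonzero count summed over both pools."""
    return [
        i
        for i in range(4)
        if site.counts_mut[i] + site.counts_wt[i] > 0
    ]


def prefilter_sites(
    sites: Sequence[PooledSiteCounts],
    min_depth: int = 10,
    fix_threshold: float = 0.95,
    screen_mut_pool: bool = False,
) -> tuple[list[PooledSiteCounts], FilterAccounting]:
    """Apply the pre-scan filter cascade and account for each stage.

    Stage 1 keeps sites with exactly two bases observed across both pools;
    stage 2 drops sites where any single base reaches ``fix_threshold`` of the
    wild-type pool (computed over the two retained bases; set
    ``screen_mut_pool`` to screen the mutant pool as well); stage 3 drops
    sites where either pool's depth over the retained bases is below
    ``min_depth``.
    """
    total = len(sites)

    biallelic = [(s, _retained_bases(s)) for s in sites]
    biallelic = [(s, kept) for s, kept in biallelic if len(kept) == 2]

    def fixed_in_pool(counts, kept) -> bool:
        depth = sum(counts[i] for i in kept)
        if depth == 0:
            return False
        return any(counts[i] / depth >= fix_threshold for i in kept)

    unfixed = [
        (s, kept)
        for s, kept in biallelic
        if not fixed_in_pool(s.counts_wt, kept)
        and not (screen_mut_pool and fixed_in_pool(s.counts_mut, kept))
    ]

    deep = [
        s
        for s, kept in unfixed
        if sum(s.counts_mut[i] for i in kept) >= min_depth
        and sum(s.counts_wt[i] for i in kept) >= min_depth
    ]

    accounting = FilterAccounting(
        total=total,
        after_biallelic=len(biallelic),
        after_frequency=len(unfixed),
        after_depth=len(deep),
    )
    logger.info(
        "prefilter: %d total -> %d biallelic -> %d frequency -> %d depth",
        *[accounting.total, accounting.after_biallelic,
          accounting.after_frequency, accounting.after_depth],
    )
    return deep, accounting
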