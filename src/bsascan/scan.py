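"""Euclidean-distance genome scan for bulked-segregant analysis.

At each segregating site the two pools' base-frequency vectors
``(A, C, G, T)`` are compared by their Euclidean distance

    ED = sqrt((A_mut - A_wt)^2 + (C_mut - C_wt)^2
              + (G_mut - G_wt)^2 + (T_mut - T_wt)^2),

which is 0 for identical pools and sqrt(2) for pools fixed on different
alleles. Raising ED to the 4th power suppresses sampling noise; the ED^4
track is then smoothed along each chromosome with a degree-1 LOESS (tricube
weights, k-nearest-neighbour window covering a fixed fraction of the
chromosome's sites). The genome-wide association threshold is the median of
all fitted values plus three sample standard deviations; maximal runs of
sites at or above it become associated regions, and sites inside a region
with mutant-pool mutation frequency > 0.75 and raw ED > 0.5 are the
candidate SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import BASES, _BASE_INDEX, PooledSiteCounts

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tunable parameters of the ED scan.

    power
        Exponent applied to ED before smoothing (4 suppresses background).
    span
        Fraction of each chromosome's sites in the local-regression window.
    threshold_sd_mult
        Multiplier on the standard deviation in the Median + k*SD threshold.
    cand_freq_min, cand_ed_min
        Strict lower bounds on mutant-pool mutation frequency and raw ED for
        a site in a region to count as a candidate.
    min_sites_for_fit
        Chromosomes with fewer sites keep their raw ED^power values.
    """

    power: float = 4.0
    span: float = 0.1
    threshold_sd_mult: float = 3.0
    cand_freq_min: float = 0.75
    cand_ed_min: float = 0.5
    min_sites_for_fit: int = 10

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")


@dataclass
class EDRecord:
    chrom: str
    pos: int
    ref_base: str
    freq_mut: tuple[float, float, float, float]
    freq_wt: tuple[float, float, float, float]
    ed: float
    ed4: float
    fitted: float | None = None

    @property
    def mut_nonref_freq(self) -> float:
        """Mutation frequency: non-reference allele fraction in the mutant pool."""
        return 1.0 - self.freq_mut[_BASE_INDEX[self.ref_base]]


@dataclass
class AssociatedRegion:
    chrom: str
    start: int
    end: int
    n_sites: int
    peak_fitted: float
    sites: list[EDRecord] = field(default_factory=list)
    candidates: list[EDRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.n_sites < 1:
            raise ValueError("region must contain at least one site")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and self.end >= start


# ---------------------------------------------------------------------------
# ED statistic
# ---------------------------------------------------------------------------

def compute_ed(site: PooledSiteCounts, power: float = 4.0) -> EDRecord:
    """Compute pool base frequencies and the ED statistic for one site."""
    dm, dw = site.depth_mut, site.depth_wt
    if dm == 0 or dw == 0:
        raise ValueError(f"zero-depth pool at {site.chrom}:{site.pos}")
    fm = tuple(c / dm for c in site.counts_mut)
    fw = tuple(c / dw for c in site.counts_wt)
    ed = math.sqrt(sum((a - b) ** 2 for a, b in zip(fm, fw)))
    return EDRecord(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=site.ref_base,
        freq_mut=fm,
        freq_wt=fw,
        ed=ed,
        ed4=ed**power,
    )


def compute_ed_records(
    sites: Sequence[PooledSiteCounts], config: ScanConfig | None = None
) -> list[EDRecord]:
    config = config or ScanConfig()
    return [compute_ed(s, power=config.power) for s in sites]


# ---------------------------------------------------------------------------
# LOESS smoothing
# ---------------------------------------------------------------------------

def _loess_degree1(pos: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local linear fit evaluated at every site.

    The window at site i is its k nearest sites by genomic distance
    (k = ceil(span * n), at least 3), ties broken toward the lower index; the
    bandwidth is the largest distance in the window, so the farthest
    neighbour gets weight zero.
    """
    n = len(pos)
    k = min(n, max(3, math.ceil(span * n)))
    pos = np.asarray(pos, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.arange(n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(pos - pos[i])
        idx = np.lexsort((order, d))[:k]
        dd = d[idx]
        h = dd.max()
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - (dd / h) ** 3) ** 3
        x = pos[idx] - pos[i]
        yy = y[idx]
        sw = w.sum()
        swx = (w * x).sum()
        swx2 = (w * x * x).sum()
        swy = (w * yy).sum()
        swxy = (w * x * yy).sum()
        denom = sw * swx2 - swx * swx
        if denom <= 0 or not np.isfinite(denom):
            fitted[i] = swy / sw
        else:
            # intercept of the weighted line at x = 0
            fitted[i] = (swy * swx2 - swx * swxy) / denom
    return np.clip(fitted, 0.0, None)


def fit_scan(records: Sequence[EDRecord], config: ScanConfig | None = None) -> list[EDRecord]:
    """Smooth ED^power along each chromosome; returns records with ``fitted`` set.

    Chromosomes with fewer than ``min_sites_for_fit`` sites keep their raw
    values (with a warning). Positions must be strictly increasing within a
    chromosome.
    """
    config = config or ScanConfig()
    out: list[EDRecord] = []
    for chrom, group in _group_by_chrom(records):
        pos = np.array([r.pos for r in group], dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions on {chrom} must be strictly increasing")
        y = np.array([r.ed4 for r in group])
        if len(group) < config.min_sites_for_fit:
            logger.warning(
                "chromosome %s has %d < %d sites; fitted values fall back to raw ED^%g",
                chrom, len(group), config.min_sites_for_fit, config.power,
            )
            fitted = y
        else:
            fitted = _loess_degree1(pos, y, config.span)
        out.extend(replace(r, fitted=float(f)) for r, f in zip(group, fitted))
    return out


def _group_by_chrom(records: Sequence[EDRecord]) -> Iterable[tuple[str, list[EDRecord]]]:
    current: list[EDRecord] = []
    chrom = None
    for r in records:
        if chrom is not None and r.chrom != chrom:
            yield chrom, current
            current = []
        chrom = r.chrom
        current.append(r)
    if current:
        yield chrom, current


# ---------------------------------------------------------------------------
# threshold, regions, candidates
# ---------------------------------------------------------------------------

def association_threshold(fitted: Sequence[float], sd_mult: float = 3.0) -> float:
    """Median + sd_mult * SD of the genome-wide fitted values (sample SD, n-1)."""
    arr = np.asarray(fitted, dtype=float)
    if arr.size < 2:
        raise ValueError("association threshold needs at least 2 fitted values")
    return float(np.median(arr) + sd_mult * np.std(arr, ddof=1))


def call_regions(records: Sequence[EDRecord], threshold: float) -> list[AssociatedRegion]:
    """Maximal runs of consecutive same-chromosome sites with fitted >= threshold."""
    regions: list[AssociatedRegion] = []
    run: list[EDRecord] = []

    def flush() -> None:
        if run:
            regions.append(
                AssociatedRegion(
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos,
                    n_sites=len(run),
                    peak_fitted=max(r.fitted for r in run),
                    sites=list(run),
                )
            )

    for chrom, group in _group_by_chrom(records):
        run = []
        for r in group:
            if r.fitted is None:
                raise ValueError("call_regions requires fitted values; run fit_scan first")
            if r.fitted >= threshold:
                run.append(r)
            else:
                flush()
                run = []
        flush()
        run = []
    return regions


def select_candidates(
    regions: Sequence[AssociatedRegion], config: ScanConfig | None = None
) -> list[AssociatedRegion]:
    """Mark region member sites as candidates (strict thresholds on both rules).

    A candidate has mutant-pool non-reference frequency strictly above
    ``cand_freq_min`` and raw ED strictly above ``cand_ed_min``; sites outside
    every region are never candidates.
    """
    config = config or ScanConfig()
    for region in regions:
        region.candidates = [
            r
            for r in region.sites
            if r.mut_nonref_freq > config.cand_freq_min and r.ed > config.cand_ed_min
        ]
    return list(regions)


def run_scan(
    sites: Sequence[PooledSiteCounts], config: ScanConfig | None = None
) -> tuple[list[EDRecord], float, list[AssociatedRegion]]:
    """Full scan: ED, smoothing, threshold, regions, candidates."""
    config = config or ScanConfig()
    records = fit_scan(compute_ed_records(sites, config), config)
    threshold = association_threshold([r.fitted for r in records], config.threshold_sd_mult)
    regions = select_candidates(call_regions(records, threshold), config)
    return records, threshold, regions


def scan_table(records: Sequence[EDRecord], regions: Sequence[AssociatedRegion]):
    """Per-site scan results as a DataFrame (for the scan TSV artifact)."""
    import pandas as pd

    in_region = {(r.chrom, r.pos) for reg in regions for r in reg.sites}
    candidate = {(r.chrom, r.pos) for reg in regions for r in reg.candidates}
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_base,
                **{f"mut_{b}": f for b, f in zip(BASES, r.freq_mut)},
                **{f"wt_{b}": f for b, f in zip(BASES, r.freq_wt)},
                "mut_freq": r.mut_nonref_freq,
                "ed": r.ed,
                "ed4": r.ed4,
                "fitted": r.fitted,
                "in_region": (r.chrom, r.pos) in in_region,
                "candidate": (r.chrom, r.pos) in candidate,
            }
        )
    return pd.DataFrame(rows)
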