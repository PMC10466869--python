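"""Synthetic two-bulk pooled sequencing data with planted QTL, plus phenotypes.

The generator emulates an extreme-phenotype bulked-segregant design: two
pools of 3 animals each drawn from the tails of the phenotype distribution,
sequenced to ~28X mean coverage. Each segregating site has a shared baseline
alternate-allele frequency; at a planted QTL the two pools' frequencies are
pushed apart by ``delta``, decaying linearly to zero over ``linkage_window``
bp to mimic linkage around the causal site. Read counts are binomial draws
from the pool frequency at a Poisson per-pool depth; finite-pool resampling
is not modelled (``pool_size`` is carried in the config for future
overdispersion).

Phenotypes follow the additive fixed-effects model
``melatonin = mu + genotype effect + age effect + N(0, sd)``, floored at 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import BASES, PhenotypeRecord, PooledSiteCounts

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Two-bulk simulation parameters.

    ``qtls`` is a list of ``(chrom, pos, delta)`` with delta the pool
    allele-frequency divergence at the QTL peak; ``linkage_window`` is the
    distance (bp) over which that divergence decays linearly to zero.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    n_sites: int = 5000
    qtls: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("chr1", 25_000_000, 0.8)]
    )
    linkage_window: int = 2_000_000
    depth_mean: float = 28.0
    pool_size: int = 3
    baseline_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        for chrom, pos, delta in self.qtls:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in chrom_lengths")
            if not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(f"QTL position {pos} outside {chrom}")
            if not 0 < delta <= 1:
                raise ValueError(f"QTL delta must be in (0, 1], got {delta}")
        lo, hi = self.baseline_maf_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("baseline_maf_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class SimTruth:
    """Ground truth: per-site true pool frequencies and the QTL intervals."""

    chrom: list[str]
    pos: list[int]
    freq_mut: list[float]
    freq_wt: list[float]
    qtl_intervals: list[tuple[str, int, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "chrom": self.chrom,
                    "pos": self.pos,
                    "freq_mut": self.freq_mut,
                    "freq_wt": self.freq_wt,
                    "qtl_intervals": [list(t) for t in self.qtl_intervals],
                },
                fh,
            )


def qtl_weight(
    chrom: str,
    pos: int,
    qtls: Sequence[tuple[str, int, float]],
    linkage_window: int,
) -> float:
    """Effective pool divergence delta*w at a site: linear decay with distance.

    w = max(0, 1 - distance/linkage_window); with several QTL the largest
    effective divergence wins.
    """
    best = 0.0
    for qchrom, qpos, delta in qtls:
        if qchrom != chrom:
            continue
        w = max(0.0, 1.0 - abs(pos - qpos) / linkage_window)
        best = max(best, delta * w)
    return best


def pool_frequencies(p: float, effective_delta: float) -> tuple[float, float]:
    """True alt-allele frequencies (mutant, wild-type) at a site.

    The mutant pool is shifted up and the wild-type pool down by half the
    effective divergence, clamped into [0, 1].
    """
    f_mut = min(1.0, max(0.0, p + effective_delta / 2.0))
    f_wt = min(1.0, max(0.0, p - effective_delta / 2.0))
    return f_mut, f_wt


def _site_positions(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(config.n_sites, lengths / lengths.sum())
    out: list[tuple[str, int]] = []
    for chrom, n in zip(chroms, alloc):
        length = config.chrom_lengths[chrom]
        positions: set[int] = set()
        while len(positions) < n:
            draw = rng.integers(1, length + 1, size=n - len(positions))
            positions.update(int(p) for p in draw)
        out.extend((chrom, p) for p in sorted(positions))
    return out


def simulate_bulks(config: SimulationConfig) -> tuple[list[PooledSiteCounts], SimTruth]:
    """Simulate the two-pool count table and its ground truth.

    Deterministic for a fixed ``config.seed``. Sites where both pools draw
    zero depth are dropped (logged); frequency clamps at strong QTL are
    logged as a count.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_positions(config, rng)
    lo, hi = config.baseline_maf_range

    records: list[PooledSiteCounts] = []
    truth_chrom: list[str] = []
    truth_pos: list[int] = []
    truth_fm: list[float] = []
    truth_fw: list[float] = []
    n_clamped = 0
    n_zero_depth = 0

    for chrom, pos in sites:
        p = float(rng.uniform(lo, hi))
        dw = qtl_weight(chrom, pos, config.qtls, config.linkage_window)
        if dw > 0 and (p + dw / 2 > 1 or p - dw / 2 < 0):
            n_clamped += 1
        f_mut, f_wt = pool_frequencies(p, dw)

        ref, alt = rng.choice(4, size=2, replace=False)
        depth_mut = int(rng.poisson(config.depth_mean))
        depth_wt = int(rng.poisson(config.depth_mean))
        alt_mut = int(rng.binomial(depth_mut, f_mut)) if depth_mut else 0
        alt_wt = int(rng.binomial(depth_wt, f_wt)) if depth_wt else 0
        if depth_mut + depth_wt == 0:
            n_zero_depth += 1
            continue

        counts_mut = [0, 0, 0, 0]
        counts_wt = [0, 0, 0, 0]
        counts_mut[ref] = depth_mut - alt_mut
        counts_mut[alt] = alt_mut
        counts_wt[ref] = depth_wt - alt_wt
        counts_wt[alt] = alt_wt

        records.append(
            PooledSiteCounts(
                chrom=chrom,
                pos=pos,
                ref_base=BASES[ref],
                counts_mut=tuple(counts_mut),
                counts_wt=tuple(counts_wt),
            )
        )
        truth_chrom.append(chrom)
        truth_pos.append(pos)
        truth_fm.append(f_mut)
        truth_fw.append(f_wt)

    if n_clamped:
        logger.info("clamped pool frequencies into [0, 1] at %d sites", n_clamped)
    if n_zero_depth:
        logger.info("dropped %d sites with zero depth in both pools", n_zero_depth)

    truth = SimTruth(
        chrom=truth_chrom,
        pos=truth_pos,
        freq_mut=truth_fm,
        freq_wt=truth_fw,
        qtl_intervals=[
            (chrom, max(1, pos - config.linkage_window), pos + config.linkage_window)
            for chrom, pos, _ in config.qtls
        ],
    )
    return records, truth


def simulate_phenotypes(
    n_animals: int = 195,
    genotype_effects: Mapping[str, float] | None = None,
    age_effects: Mapping[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    mu: float = 1.64,
    genotype_freqs: Mapping[str, float] | None = None,
    site: str = "chr1:25000000",
) -> list[PhenotypeRecord]:
    """Simulate per-animal melatonin phenotypes at one typed site.

    Defaults reflect a flock mean of 1.64 ng/mL with a roughly 9:1 common/rare
    genotype split and a +2 ng/mL effect of the rare genotype. ``noise_sd``
    must be non-negative; melatonin is floored at 0 (assay floor).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    genotype_effects = dict(genotype_effects or {"GG": 0.0, "CG": 2.0})
    if len(genotype_effects) < 2:
        raise ValueError("need at least 2 genotype classes")
    age_effects = dict(age_effects or {"1yr": 0.0, "2yr": 0.2, "3yr": 0.4})

    genotypes = sorted(genotype_effects)
    if genotype_freqs is None:
        gfreqs = np.full(len(genotypes), 1.0 / len(genotypes))
    else:
        gfreqs = np.array([genotype_freqs[g] for g in genotypes], dtype=float)
        gfreqs = gfreqs / gfreqs.sum()
    ages = sorted(age_effects)

    rng = np.random.default_rng(seed)
    records = []
    n_floored = 0
    for i in range(n_animals):
        g = genotypes[rng.choice(len(genotypes), p=gfreqs)]
        a = ages[rng.integers(len(ages))]
        value = mu + genotype_effects[g] + age_effects[a]
        if noise_sd > 0:
            value += float(rng.normal(0.0, noise_sd))
        if value < 0:
            n_floored += 1
            value = 0.0
        records.append(
            PhenotypeRecord(
                sample_id=f"animal{i + 1:03d}",
                melatonin=value,
                age=a,
                genotypes={site: g},
            )
        )
    if n_floored:
        logger.info("floored %d negative melatonin draws at 0", n_floored)
    return records
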