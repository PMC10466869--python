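"""End-to-end orchestration: prefilter -> ED scan -> regions -> candidates ->
annotation -> enrichment -> association, with a JSON run manifest.

The manifest records input hashes, a config echo, and per-stage counts
(filter-cascade accounting, region/candidate totals), so identical configs
produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate as _annotate
from . import assoc as _assoc
from . import enrich as _enrich
from . import io as _io
from . import plots as _plots
from . import simulate as _simulate
from .scan import ScanConfig, run_scan, scan_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str | None = None
    counts_format: str | None = None
    gene_models: str | None = None
    genome: str | None = None
    term_map: str | None = None
    phenotypes: str | None = None
    out_dir: str = "bsascan_out"
    min_depth: int = 10
    fix_threshold: float = 0.95
    scan: ScanConfig = field(default_factory=ScanConfig)
    q_cutoff: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan_keys = {f for f in ScanConfig.__dataclass_fields__}
        scan_kwargs = {k: raw.pop(k) for k in list(raw) if k in scan_keys}
        cfg = cls(**raw)
        if scan_kwargs:
            cfg.scan = ScanConfig(**scan_kwargs)
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on the configured inputs; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "scan"},
            "scan": asdict(config.scan),
        },
        "inputs": {},
        "stages": {},
    }
    for key in ("counts", "gene_models", "genome", "term_map", "phenotypes"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    if not config.counts:
        raise ValueError("pipeline requires a counts input (VCF or TSV count table)")

    logger.info("[load] reading pooled counts from %s", config.counts)
    sites = _io.read_pooled_counts(config.counts, format=config.counts_format)
    logger.info("[filter] applying pre-filter cascade")
    kept, accounting = _import_filters().prefilter_sites(
        sites, min_depth=config.min_depth, fix_threshold=config.fix_threshold
    )
    accounting.to_frame().to_csv(out / "filter_accounting.tsv", sep="\t", index=False)
    manifest["stages"]["filter"] = {
        "total": accounting.total,
        "biallelic": accounting.after_biallelic,
        "frequency": accounting.after_frequency,
        "depth": accounting.after_depth,
    }

    logger.info("[scan] ED statistic, smoothing, threshold, regions")
    records, threshold, regions = run_scan(kept, config.scan)
    table = scan_table(records, regions)
    table.to_csv(out / "scan.tsv", sep="\t", index=False)
    _io.write_regions_bed(regions, out / "regions.bed")
    candidates = table[table["candidate"]]
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    _plots.scan_plot(records, regions, threshold, out / "scan.png")
    manifest["stages"]["scan"] = {
        "threshold": threshold,
        "n_sites": len(records),
        "n_regions": len(regions),
        "total_region_bp": int(sum(r.length for r in regions)),
        "n_candidates": int(candidates.shape[0]),
    }

    candidate_genes: set[str] = set()
    if config.gene_models:
        logger.info("[annotate] classifying candidate SNPs")
        models = _io.read_gene_models(config.gene_models)
        genome = None
        if config.genome:
            from pyfaidx import Fasta

            genome = Fasta(str(config.genome))
        ann = _annotate.annotate_candidates(regions, models, genome)
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        candidate_genes = {g for g in ann["gene"] if g}
        manifest["stages"]["annotate"] = {
            "n_annotated": int(ann.shape[0]),
            "n_candidate_genes": len(candidate_genes),
            "category_counts": ann["category"].value_counts().to_dict(),
        }
    else:
        logger.info("[annotate] no gene models supplied; stage skipped")

    if config.term_map and candidate_genes:
        logger.info("[enrich] hypergeometric over-representation test")
        term_map, term_names = _io.read_term_map(config.term_map)
        background = {g for genes in term_map.values() for g in genes}
        results = _enrich.enrich(
            candidate_genes, term_map, background, term_names, q_cutoff=config.q_cutoff
        )
        _enrich.results_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        _plots.enrichment_bubble(results, out / "enrichment.png")
        manifest["stages"]["enrich"] = {
            "n_terms_tested": len(results),
            "n_significant": sum(r.significant for r in results),
        }
    else:
        logger.info("[enrich] no term map (or no candidate genes); stage skipped")

    if config.phenotypes:
        logger.info("[assoc] genotype-phenotype association")
        phen = _io.read_phenotypes(config.phenotypes)
        associations = _assoc.associate_all_sites(phen, alpha=config.alpha)
        _assoc.association_table(associations).to_csv(
            out / "association.tsv", sep="\t", index=False
        )
        manifest["stages"]["assoc"] = {
            "n_sites": len(associations),
            "n_significant": sum(a.significant for a in associations),
        }
    else:
        logger.info("[assoc] no phenotype table supplied; stage skipped")

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _import_filters():
    from . import filters

    return filters


def run_demo(out_dir: str | Path, seed: int = 7, n_sites: int = 5000) -> dict:
    """One-command synthetic demo: simulate bulks + phenotypes, run the pipeline.

    Returns the manifest augmented with the simulation truth summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = _simulate.SimulationConfig(n_sites=n_sites, seed=seed)
    records, truth = _simulate.simulate_bulks(sim_cfg)
    counts_path = out / "sim_counts.tsv"
    _io.write_pooled_counts(records, counts_path)
    truth.to_json(out / "sim_truth.json")
    phen = _simulate.simulate_phenotypes(seed=seed + 1)
    phen_path = out / "sim_phenotypes.tsv"
    _io.write_phenotypes(phen, phen_path)

    cfg = PipelineConfig(
        counts=str(counts_path),
        phenotypes=str(phen_path),
        out_dir=str(out),
        seed=seed,
    )
    manifest = run_pipeline(cfg)
    manifest["truth"] = {
        "qtl_intervals": [list(t) for t in truth.qtl_intervals],
        "regions_overlap_truth": any(
            _overlaps_any(reg_line, truth.qtl_intervals)
            for reg_line in _read_bed(out / "regions.bed")
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_bed(path: Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.split("\t")
            if len(fields) >= 3:
                out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def _overlaps_any(region: tuple[str, int, int], intervals) -> bool:
    chrom, start, end = region
    return any(c == chrom and start <= e and end >= s for c, s, e in intervals)
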