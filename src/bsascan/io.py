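"""Reading and writing the pipeline's on-disk artifacts.

Internal coordinates are 1-based inclusive throughout; the BED writer is the
only place where the 0-based half-open convention appears. Chromosome names
are compared as exact strings (no ``chr`` normalisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COUNT_COLUMNS = [
    "chrom", "pos", "ref",
    "mutA", "mutC", "mutG", "mutT",
    "wtA", "wtC", "wtG", "wtT",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class PooledSiteCounts:
    """Per-site A/C/G/T read counts for the two phenotype bulks.

    ``counts_mut`` holds the high-phenotype ("mutant") pool, ``counts_wt`` the
    low-phenotype ("wild-type") pool, each ordered (A, C, G, T).
    """

    chrom: str
    pos: int
    ref_base: str
    counts_mut: tuple[int, int, int, int]
    counts_wt: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in _BASE_INDEX:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        if any(c < 0 for c in self.counts_mut + self.counts_wt):
            raise ValueError("read counts must be non-negative")

    @property
    def depth_mut(self) -> int:
        return sum(self.counts_mut)

    @property
    def depth_wt(self) -> int:
        return sum(self.counts_wt)


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model with 1-based inclusive intervals.

    ``start``/``end`` span the coding region; ``exons`` are the coding exon
    intervals (sorted, non-overlapping). UTR intervals live outside the coding
    span.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    strand: str
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon ({s}, {e}) has start > end")
            if s < self.start or e > self.end:
                raise ValueError(f"exon ({s}, {e}) outside coding span [{self.start}, {self.end}]")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def extent(self) -> tuple[int, int]:
        """Full transcript footprint including UTRs."""
        starts = [self.start] + [s for s, _ in self.utr5 + self.utr3]
        ends = [self.end] + [e for _, e in self.utr5 + self.utr3]
        return min(starts), max(ends)


@dataclass
class PhenotypeRecord:
    """One animal: melatonin concentration (ng/mL), age class, genotypes."""

    sample_id: str
    melatonin: float
    age: str
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.melatonin):
            raise ValueError(f"melatonin must be finite, got {self.melatonin}")
        if self.melatonin < 0:
            raise ValueError(f"melatonin must be >= 0, got {self.melatonin}")


# ---------------------------------------------------------------------------
# pooled counts
# ---------------------------------------------------------------------------

def _sorted_records(records: list[PooledSiteCounts], source: str) -> list[PooledSiteCounts]:
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        logger.info("input %s not sorted by (chrom, pos); sorting on load", source)
        records = sorted(records, key=lambda r: (r.chrom, r.pos))
    return records


def read_pooled_counts(path: str | Path, format: str | None = None) -> list[PooledSiteCounts]:
    """Read per-site pool counts from a VCF (AD fields) or a TSV count table.

    ``format`` is ``"vcf"`` or ``"tsv"``; by default it is inferred from the
    file suffix. For VCF, the first sample is the high-phenotype (mutant) pool
    and the second the low-phenotype (wild-type) pool; multi-allelic rows are
    expanded into per-base counts and non-SNV alleles are ignored. Records are
    returned sorted by (chrom, pos); sites with all eight counts zero are
    dropped.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        records = _read_counts_vcf(path)
    elif format == "tsv":
        records = _read_counts_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    records = [r for r in records if r.depth_mut + r.depth_wt > 0]
    return _sorted_records(records, str(path))


def _read_counts_tsv(path: Path) -> list[PooledSiteCounts]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: count table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PooledSiteCounts(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref,
                counts_mut=(int(row.mutA), int(row.mutC), int(row.mutG), int(row.mutT)),
                counts_wt=(int(row.wtA), int(row.wtC), int(row.wtG), int(row.wtT)),
            )
        )
    return records


def _read_counts_vcf(path: Path) -> list[PooledSiteCounts]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise FormatError(
            f"{path}: expected exactly two samples (mutant pool, wild-type pool), "
            f"found {len(vcf.samples)}: {vcf.samples}"
        )
    records = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: missing AD field at {variant.CHROM}:{variant.POS}")
        alleles = [variant.REF] + list(variant.ALT)
        counts = [[0, 0, 0, 0], [0, 0, 0, 0]]  # mut, wt
        for ai, allele in enumerate(alleles):
            if allele not in _BASE_INDEX:
                continue  # skip indels / symbolic alleles
            bi = _BASE_INDEX[allele]
            for si in range(2):
                depth = int(ad[si][ai])
                if depth >= 0:  # cyvcf2 encodes missing as negative
                    counts[si][bi] += depth
        if variant.REF not in _BASE_INDEX:
            continue
        records.append(
            PooledSiteCounts(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref_base=variant.REF,
                counts_mut=tuple(counts[0]),
                counts_wt=tuple(counts[1]),
            )
        )
    return records


def write_pooled_counts(records: Sequence[PooledSiteCounts], path: str | Path) -> None:
    """Write records as the 11-column TSV count table (round-trips exactly)."""
    rows = [
        (r.chrom, r.pos, r.ref_base, *r.counts_mut, *r.counts_wt)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions / BED
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write associated regions as BED (0-based half-open), score = peak fitted."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions, start=1):
            fh.write(
                f"{region.chrom}\t{region.start - 1}\t{region.end}\t"
                f"region_{i}\t{region.peak_fitted:.6g}\n"
            )


# ---------------------------------------------------------------------------
# term maps
# ---------------------------------------------------------------------------

def read_term_map(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene->term mapping.

    Accepts a two-column TSV (gene, term) or a GMT-like file
    (term, description, gene1, gene2, ...). Returns ``(term_to_genes,
    term_names)``; for the two-column form the term name equals the term id.
    """
    path = Path(path)
    term_to_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            if len(fields) == 2 and path.suffix.lower() != ".gmt":
                gene, term = fields
                term_to_genes.setdefault(term, set()).add(gene)
                term_names.setdefault(term, term)
            else:
                term, name, *genes = fields
                if not genes:
                    raise FormatError(f"{path}:{lineno}: GMT line lists no genes")
                term_to_genes.setdefault(term, set()).update(genes)
                term_names[term] = name
    return term_to_genes, term_names


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read single-transcript gene models from GFF3 (gene/mRNA/CDS/UTR features).

    Only the first mRNA of each gene is used; CDS features become the coding
    exons. Genes without CDS features are skipped with a notice.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        cds = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            logger.info("gene %s has no CDS features; skipped", gene.id)
            continue
        utr5 = tuple(
            (f.start, f.end)
            for f in sorted(db.children(parent, featuretype="five_prime_UTR"), key=lambda f: f.start)
        )
        utr3 = tuple(
            (f.start, f.end)
            for f in sorted(db.children(parent, featuretype="three_prime_UTR"), key=lambda f: f.start)
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=min(f.start for f in cds),
                end=max(f.end for f in cds),
                exons=tuple((f.start, f.end) for f in cds),
                strand=gene.strand,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV: sample, melatonin, age, one column per typed site.

    Empty cells in genotype columns mean missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "melatonin", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        genotypes = {}
        for col, raw in zip(df.columns, row):
            if col in required:
                continue
            if isinstance(raw, str) and raw.strip():
                genotypes[col] = raw.strip()
        records.append(
            PhenotypeRecord(
                sample_id=str(row[0]),
                melatonin=float(row[df.columns.get_loc("melatonin")]),
                age=str(row[df.columns.get_loc("age")]),
                genotypes=genotypes,
            )
        )
    return records


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    site_cols = sorted({s for r in records for s in r.genotypes})
    rows = []
    for r in records:
        row = {"sample": r.sample_id, "melatonin": r.melatonin, "age": r.age}
        for s in site_cols:
            row[s] = r.genotypes.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
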