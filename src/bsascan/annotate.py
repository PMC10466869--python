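"""Genic-context classification of SNPs and coding consequences.

Each site is classified against single-transcript gene models with the
precedence exonic > splicing > UTR5/UTR3 > intronic > upstream/downstream
(within 1 kb) > intergenic; "splicing" means within 2 bp of an exon-intron
boundary on the intron side. For exonic sites the affected codon is read
from the reference genome with the transcript's strand and frame and both
alleles are translated with the standard code, yielding synonymous,
non-synonymous, stop-gain or stop-loss calls and an amino-acid change in
"X/Y" form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io import GeneModel

logger = logging.getLogger(__name__)

SPLICE_WINDOW = 2
FLANK = 1000

_PRECEDENCE = {
    "exonic": 0,
    "splicing": 1,
    "UTR5": 2,
    "UTR3": 3,
    "intronic": 4,
    "upstream": 5,
    "downstream": 5,
    "intergenic": 9,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SnpAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    category: str
    gene_id: str | None = None
    consequence: str | None = None
    aa_change: str | None = None


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Reference bases [start, end] 1-based inclusive; works for str or pyfaidx."""
    return str(genome[chrom][start - 1 : end]).upper()


def _category_for_gene(pos: int, gene: GeneModel) -> str | None:
    for s, e in gene.exons:
        if s <= pos <= e:
            return "exonic"
    if gene.start <= pos <= gene.end:
        for i in range(len(gene.exons) - 1):
            intron_start = gene.exons[i][1] + 1
            intron_end = gene.exons[i + 1][0] - 1
            if intron_start <= pos <= intron_end:
                if pos - intron_start < SPLICE_WINDOW or intron_end - pos < SPLICE_WINDOW:
                    return "splicing"
                return "intronic"
        return "intronic"
    for s, e in gene.utr5:
        if s <= pos <= e:
            return "UTR5"
    for s, e in gene.utr3:
        if s <= pos <= e:
            return "UTR3"
    lo, hi = gene.extent
    if lo - FLANK <= pos < lo:
        return "upstream" if gene.strand == "+" else "downstream"
    if hi < pos <= hi + FLANK:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def _coding_consequence(
    pos: int, alt: str, gene: GeneModel, genome: Mapping[str, object]
) -> tuple[str, str]:
    """(consequence, "ref_aa/alt_aa") for a substitution inside a coding exon."""
    cds = "".join(_fetch(genome, gene.chrom, s, e) for s, e in gene.exons)
    offset = 0
    for s, e in gene.exons:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    if len(cds) % 3 != 0:
        logger.warning("gene %s CDS length %d not a multiple of 3", gene.gene_id, len(cds))
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        offset = len(cds) - 1 - offset
        alt = _COMPLEMENT[alt]
    codon_idx = offset // 3
    within = offset % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return "unknown", ""
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop-gain"
    elif ref_aa == "*":
        consequence = "stop-loss"
    else:
        consequence = "non-synonymous"
    return consequence, f"{ref_aa}/{alt_aa}"


def classify_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, object] | None = None,
) -> SnpAnnotation:
    """Classify one substitution against the gene models.

    ``genome`` maps chromosome name to its sequence (plain string or a
    pyfaidx record); it is required to call coding consequences and to
    sanity-check the reference base. Overlapping genes are resolved by
    category precedence, ties by gene order.
    """
    for base, label in ((ref, "ref"), (alt, "alt")):
        if base not in _COMPLEMENT:
            raise ValueError(f"{label} base must be one of A/C/G/T, got {base!r}")

    best_cat = "intergenic"
    best_gene: GeneModel | None = None
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        cat = _category_for_gene(pos, gene)
        if cat is not None and _PRECEDENCE[cat] < _PRECEDENCE[best_cat]:
            best_cat, best_gene = cat, gene

    consequence = aa_change = None
    if best_cat == "exonic" and genome is not None:
        genome_ref = _fetch(genome, chrom, pos, pos)
        if genome_ref != ref:
            logger.warning(
                "reference mismatch at %s:%d: genome has %s, site claims %s",
                chrom, pos, genome_ref, ref,
            )
        consequence, aa_change = _coding_consequence(pos, alt, best_gene, genome)

    return SnpAnnotation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        category=best_cat,
        gene_id=best_gene.gene_id if best_gene else None,
        consequence=consequence,
        aa_change=aa_change,
    )


def annotate_candidates(regions, gene_models, genome=None):
    """Annotate every candidate SNP from the called regions.

    The alternate allele at each candidate is the most frequent non-reference
    base in the mutant pool. Returns a DataFrame (site, category, gene,
    consequence, aa_change).
    """
    import pandas as pd

    from .io import BASES

    rows = []
    for region in regions:
        for rec in region.candidates:
            ref_idx = BASES.index(rec.ref_base)
            alt_idx = max(
                (i for i in range(4) if i != ref_idx), key=lambda i: rec.freq_mut[i]
            )
            ann = classify_site(
                rec.chrom, rec.pos, rec.ref_base, BASES[alt_idx], gene_models, genome
            )
            rows.append(
                {
                    "site": f"{rec.chrom}:{rec.pos}",
                    "ref": ann.ref,
                    "alt": ann.alt,
                    "category": ann.category,
                    "gene": ann.gene_id or "",
                    "consequence": ann.consequence or "",
                    "aa_change": ann.aa_change or "",
                }
            )
    return pd.DataFrame(
        rows, columns=["site", "ref", "alt", "category", "gene", "consequence", "aa_change"]
    )


def summarize_annotations(annotations: Sequence[SnpAnnotation]) -> dict[str, int]:
    """Category counts over a set of annotations (functional-region summary)."""
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
    return counts
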