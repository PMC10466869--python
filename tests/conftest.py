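import pytest

from bsascan.io import PooledSiteCounts


@pytest.fixture
def cascade_toy():
    """Six sites built to lose exactly one per pre-filter stage.

    Site 1 shows three bases (dropped at the biallelic stage); site 2's
    wild-type pool is 95% one base (frequency stage); site 3's mutant pool
    has depth 9 (depth stage); sites 4-6 survive everything.
    """
    return [
        PooledSiteCounts("chr1", 100, "A", (10, 10, 10, 0), (10, 10, 0, 0)),
        PooledSiteCounts("chr1", 200, "A", (10, 10, 0, 0), (19, 1, 0, 0)),
        PooledSiteCounts("chr1", 300, "A", (5, 4, 0, 0), (20, 20, 0, 0)),
        PooledSiteCounts("chr1", 400, "A", (25, 5, 0, 0), (5, 25, 0, 0)),
        PooledSiteCounts("chr1", 500, "G", (0, 5, 20, 0), (0, 12, 13, 0)),
        PooledSiteCounts("chr2", 100, "C", (6, 24, 0, 0), (24, 6, 0, 0)),
    ]


TOY_CHROM_SEQ = (
    "TTTTTTTTTT"        # 1-10   upstream flank
    "ATGGAGAAA"         # 11-19  exon 1 (M E K)
    "GTAAGTACAG"        # 20-29  intron
    "CCCTAA"            # 30-35  exon 2 (P *)
    "TTTTTTTTTT" * 20   # downstream flank
)


@pytest.fixture
def toy_gene():
    from bsascan.io import GeneModel

    return GeneModel(
        gene_id="toygene",
        chrom="chrA",
        start=11,
        end=35,
        exons=((11, 19), (30, 35)),
        strand="+",
        utr5=((5, 10),),
        utr3=((36, 40),),
    )


@pytest.fixture
def toy_genome():
    return {"chrA": TOY_CHROM_SEQ}
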