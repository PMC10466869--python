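"""Genotype-calling rules and the pre-scan filter cascade on a hand-built toy.

The genotype rules: depth < 5 is missing; alt frequency >= 0.8 (or <= 0.2)
is homozygous; otherwise heterozygous if both alleles have >= 4 reads, else
missing. The filter cascade keeps biallelic sites, drops wild-type-fixed
sites (>= 95% one base), then drops sites under 10X in either pool.
"""

from bsascan import PooledSiteCounts, call_genotype, prefilter_sites

for ref, alt in [(2, 2), (1, 9), (7, 3), (5, 5), (2, 8)]:
    call = call_genotype(ref, alt, ref_base="G", alt_base="C")
    print(f"ref={ref} alt={alt} -> {call.state}"
          + (f" {call.allele_pair}" if call.allele_pair else ""))

toy = [
    PooledSiteCounts("chr1", 100, "A", (10, 10, 10, 0), (10, 10, 0, 0)),  # triallelic
    PooledSiteCounts("chr1", 200, "A", (10, 10, 0, 0), (19, 1, 0, 0)),    # wt 95% fixed
    PooledSiteCounts("chr1", 300, "A", (5, 4, 0, 0), (20, 20, 0, 0)),     # mut depth 9
    PooledSiteCounts("chr1", 400, "A", (25, 5, 0, 0), (5, 25, 0, 0)),
    PooledSiteCounts("chr1", 500, "G", (0, 5, 20, 0), (0, 12, 13, 0)),
    PooledSiteCounts("chr2", 100, "C", (6, 24, 0, 0), (24, 6, 0, 0)),
]
kept, acc = prefilter_sites(toy)
print(f"\ncascade accounting: Total={acc.total} Biallelic={acc.after_biallelic} "
      f"Frequency={acc.after_frequency} NA={acc.after_depth}")
# Each stage removes exactly one toy site: 6 -> 5 -> 4 -> 3.
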