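"""Hypergeometric over-representation analysis of candidate gene sets.

For a term carried by M of the N annotated background genes and m of the n
annotated candidate genes, the enrichment p-value is the upper tail
P(X >= m) with X ~ Hypergeometric(N, M, n). Q-values are Benjamini-Hochberg
over all tested terms; a term is significantly enriched at q <= 0.05. The
rich factor m/M measures what fraction of a term's background genes are hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    m: int
    M: int
    n: int
    N: int
    p_value: float
    q_value: float
    rich_factor: float
    significant: bool


def hypergeom_p(m: int, M: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m).

    N annotated background genes, M of them carrying the term, n annotated
    candidates, m of them carrying the term. Computed in log space via the
    hypergeometric survival function; no normal approximation.
    """
    if not (0 <= M <= N and 0 <= n <= N and m >= 0):
        raise ValueError(f"invalid hypergeometric input m={m}, M={M}, n={n}, N={N}")
    if m > min(M, n):
        raise ValueError(f"m={m} exceeds min(M={M}, n={n})")
    if m == 0:
        return 1.0
    p = float(hypergeom.sf(m - 1, N, M, n))
    return min(1.0, max(0.0, p))


def enrich(
    candidates: Iterable[str],
    term_map: Mapping[str, set[str]],
    background: Iterable[str],
    term_names: Mapping[str, str] | None = None,
    q_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with at least one candidate gene for over-representation.

    The universe is the annotated background: genes of ``background`` that
    appear under at least one term. Candidates outside the background are
    dropped with a logged count. Results are sorted by (p, term_id).
    """
    background = set(background)
    candidates = set(candidates)
    dropped = candidates - background
    if dropped:
        logger.info("dropped %d candidate genes absent from the background", len(dropped))
        candidates &= background

    annotated = {g for genes in term_map.values() for g in genes} & background
    N = len(annotated)
    cand_annotated = candidates & annotated
    n = len(cand_annotated)
    if n == 0 or N == 0:
        return []

    term_names = term_names or {}
    tested = []
    for term_id in sorted(term_map):
        genes = term_map[term_id] & annotated
        m = len(genes & cand_annotated)
        if m == 0:
            continue
        M = len(genes)
        tested.append((term_id, m, M))
    if not tested:
        return []

    pvals = [hypergeom_p(m, M, n, N) for _, m, M in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=term_names.get(term_id, term_id),
            m=m,
            M=M,
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
            rich_factor=m / M,
            significant=bool(q <= q_cutoff),
        )
        for (term_id, m, M), p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_table(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term": r.term_id,
                "name": r.term_name,
                "m": r.m,
                "M": r.M,
                "n": r.n,
                "N": r.N,
                "p": r.p_value,
                "q": r.q_value,
                "rich_factor": r.rich_factor,
                "significant": r.significant,
            }
            for r in results
        ]
    )
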