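"""Hypergeometric over-representation test on a small gene universe.

Ten background genes, three candidates all carrying the term "hit": the
upper-tail hypergeometric p is C(3,3)*C(7,0)/C(10,3) = 1/120, and the rich
factor m/M = 1.0 says every background gene with the term is a candidate.
"""

from bsascan import enrich, hypergeom_p

background = {f"g{i}" for i in range(10)}
term_map = {"hit": {"g0", "g1", "g2"}, "broad": set(background)}
results = enrich({"g0", "g1", "g2"}, term_map, background)

print(f"P(X >= 4 | N=10, M=5, n=4) = {hypergeom_p(4, 5, 4, 10):.5f}  (= 5/210)")
for r in results:
    print(f"{r.term_id}: m={r.m} M={r.M} n={r.n} N={r.N} "
          f"p={r.p_value:.5f} q={r.q_value:.5f} rich_factor={r.rich_factor:.2f} "
          f"significant={r.significant}")
# "hit" ranks first: all 3 of its background genes are candidates, which is
# maximally surprising under random draws from the 10-gene universe.
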