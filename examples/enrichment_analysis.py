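"""Hypergeometric over-representation analysis of a gene list.

A query of M genes from a universe of N_G is tested against every
annotation term: P(t >= T) under the hypergeometric law, over-represented
when p < 0.05.
"""

from deeplrp import hypergeom_tail
from deeplrp.enrichment import enrich
from deeplrp.synthetic import SyntheticSpec, generate

# the textbook example: 4 genes drawn from 10, term of size 5, all 4 hit
p = hypergeom_tail(T=4, M=4, N_G=10, N_term=5)
print(f"P(t >= 4 | M=4, N_G=10, N_term=5) = {p:.7f}  (= 5/210)")

# enrich a noisy version of a planted module against the generator's GMT
data = generate(SyntheticSpec(seed=5))
planted = data.truth.informative_genes["cancer"]
query = planted[:15] + ["G0490", "G0491"]  # 15 true genes + 2 stray ones
analysis = enrich(query, data.database, alpha=0.05)
print(f"query of {len(query)} genes against {len(data.database.terms)} terms "
      f"(universe {data.database.n_G} genes)")
for r in analysis.results[:3]:
    print(f"  {r.term_id} {r.term_name!r}: T={r.T}/{r.N_term}, "
          f"p={r.p_raw:.3g}, significant={r.significant}")
# the planted term dominates: 15 of its 20 genes in a 17-gene query is
# astronomically unlikely under random draws from 500 genes.
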