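"""Quasi-clique clustering on a small graph, checked against enumeration.

Two inversions whose PSCs form two dense but incomplete clusters: the
(alpha, beta)-quasi-clique search separates them even though neither
cluster is a complete clique, which is exactly why the method tolerates
the noisy split-clone pairings repeats produce.
"""

import networkx as nx

from poolinv.quasiclique import (
    QuasiCliqueParams,
    brute_force_quasi_cliques,
    find_maximal_quasi_cliques,
    is_quasi_clique,
)

# cluster A: nodes 0-4, one edge missing; cluster B: nodes 5-8 complete
g = nx.Graph()
g.add_edges_from(
    [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (2, 4), (3, 4), (1, 4)]
)
g.add_edges_from([(5, 6), (5, 7), (5, 8), (6, 7), (6, 8), (7, 8)])
g.add_edge(4, 5)  # a spurious cross-cluster pairing

params = QuasiCliqueParams(alpha=0.5, beta=0.6, min_clique_size=2, rng_seed=0)
found = find_maximal_quasi_cliques(g, params)
print("tabu search clusters:", [sorted(s) for s in found])

oracle = brute_force_quasi_cliques(g, params)
print("largest by enumeration:", max(len(s) for s in oracle), "nodes")

for s in found:
    assert is_quasi_clique(g, s, params)
print("every returned cluster satisfies the (alpha, beta) definition; "
      "disjointness means each PSC supports exactly one inversion call")
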