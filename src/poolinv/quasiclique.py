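"""(alpha, beta)-quasi-clique extraction from the inversion cluster graph.

Every PSC is a node; two nodes are joined iff their left breakpoint
intervals intersect and their right breakpoint intervals intersect.  True
inversions appear as dense but -- because of repeats, nested events and
clone-reconstruction noise -- rarely complete subgraphs, so instead of
maximum cliques we extract maximal (alpha, beta)-quasi-cliques: node sets
V' where every node has internal degree >= alpha * |V'| and the internal
edge count reaches a beta fraction of the possible |V'|(|V'|-1)/2.

Extraction is an iterative tabu local search over candidate sizes: grow
greedily from a high-degree seed, then alternate dropping the internal
node with the fewest internal links and adding the external node with
the most, with recently moved nodes tabu for a fixed number of rounds.
The largest feasible subset found is made maximal, removed from the
graph, and the search repeats, so returned subsets are disjoint: each
PSC supports one call.  An exhaustive enumeration oracle for graphs of
up to 15 nodes backs the tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .splitclones import PairedSplitClones

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class QuasiCliqueParams:
    alpha: float = 0.50  # minimum internal-degree fraction (gamma)
    beta: float = 0.60  # minimum internal-edge fraction (lambda)
    tabu_rounds: int | None = None  # default: ceil(|graph| / 10)
    min_clique_size: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.tabu_rounds is not None and self.tabu_rounds < 1:
            raise ValueError("tabu_rounds must be >= 1")

    def effective_tabu_rounds(self, n_nodes: int) -> int:
        if self.tabu_rounds is not None:
            return self.tabu_rounds
        return max(1, math.ceil(n_nodes / 10))


def _intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def build_cluster_graph(pscs: Sequence[PairedSplitClones]) -> nx.Graph:
    """Graph over PSC indices; edge iff both breakpoint intervals intersect.

    A sweep over left-interval starts avoids the full quadratic comparison.
    """
    g = nx.Graph()
    for i, p in enumerate(pscs):
        g.add_node(i, psc=p)
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(pscs):
        by_chrom.setdefault(p.chromosome, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: pscs[i].left_bp[0])
        los = np.array([pscs[i].left_bp[0] for i in idxs])
        for a_pos, i in enumerate(idxs):
            hi = pscs[i].left_bp[1]
            b_pos = a_pos + 1
            # all j after i (sorted by lo) with lo_j < hi_i overlap on the left
            last = int(np.searchsorted(los, hi, side="left"))
            for b_pos in range(a_pos + 1, last):
                j = idxs[b_pos]
                if _intervals_intersect(pscs[i].right_bp, pscs[j].right_bp):
                    g.add_edge(i, j)
    return g


def is_quasi_clique(graph: nx.Graph, subset: Iterable, params: QuasiCliqueParams) -> bool:
    """True iff every node's internal degree is >= alpha*|V'| and the
    undirected internal edge count is >= beta * |V'|(|V'|-1)/2."""
    nodes = set(subset)
    if not nodes:
        raise ValueError("subset must be non-empty")
    n = len(nodes)
    if n == 1:
        return True
    sub = graph.subgraph(nodes)
    min_deg = min(dict(sub.degree()).values())
    if min_deg + _EPS < params.alpha * n:
        return False
    need_edges = params.beta * n * (n - 1) / 2
    return sub.number_of_edges() + _EPS >= need_edges


# ---------------------------------------------------------------------------
# tabu local search
# ---------------------------------------------------------------------------


def _links(graph: nx.Graph, node, subset: set) -> int:
    return sum(1 for v in graph.neighbors(node) if v in subset)


def _pick(cands: list[tuple[int, object]], rng: np.random.Generator, best_high: bool):
    """Choose among (score, node); ties broken randomly but reproducibly."""
    if not cands:
        return None
    key = max(cands)[0] if best_high else min(cands)[0]
    tied = sorted(n for s, n in cands if s == key)
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def _grow_to(graph: nx.Graph, seed_node, k: int, rng: np.random.Generator) -> set:
    """Greedy growth: repeatedly add the external node with the most
    internal links until the subset reaches size k."""
    subset = {seed_node}
    while len(subset) < k:
        frontier = {v for u in subset for v in graph.neighbors(u)} - subset
        if not frontier:
            frontier = set(graph.nodes) - subset
            if not frontier:
                break
        adds = [(_links(graph, v, subset), v) for v in frontier]
        subset.add(_pick(adds, rng, best_high=True))
    return subset


def _fixed_k_tabu(
    graph: nx.Graph,
    seed_node,
    k: int,
    params: QuasiCliqueParams,
    rng: np.random.Generator,
    max_iter: int,
) -> set | None:
    """Search for a feasible subset of exactly k nodes: grow greedily, then
    alternate removing the internal node with the fewest links and adding
    the external node with the most, with recently moved nodes tabu."""
    rounds = params.effective_tabu_rounds(graph.number_of_nodes())
    subset = _grow_to(graph, seed_node, k, rng)
    if len(subset) < k:
        return None
    if is_quasi_clique(graph, subset, params):
        return subset
    tabu: dict = {}
    for it in range(max_iter):
        rems = [(_links(graph, u, subset), u) for u in subset if tabu.get(u, -1) < it]
        u_rem = _pick(rems, rng, best_high=False)
        if u_rem is None:
            break
        subset.remove(u_rem)
        tabu[u_rem] = it + rounds
        ext = set(graph.nodes) - subset
        adds = [(_links(graph, v, subset), v) for v in ext if tabu.get(v, -1) < it]
        if not adds:  # everything tabu: aspiration fallback
            adds = [(_links(graph, v, subset), v) for v in ext]
        v_add = _pick(adds, rng, best_high=True)
        subset.add(v_add)
        tabu[v_add] = it + rounds
        if is_quasi_clique(graph, subset, params):
            return subset
    return None


def _largest_feasible_greedy(
    graph: nx.Graph, order, params: QuasiCliqueParams, rng: np.random.Generator
) -> set | None:
    """Baseline for large components: grow greedily from a few seeds and
    keep the largest feasible subset seen along the way."""
    best: set | None = None
    for seed_node in order[:6]:
        subset = {seed_node}
        while True:
            frontier = {v for u in subset for v in graph.neighbors(u)} - subset
            if not frontier:
                break
            adds = [(_links(graph, v, subset), v) for v in frontier]
            subset.add(_pick(adds, rng, best_high=True))
            if (
                len(subset) >= params.min_clique_size
                and (best is None or len(subset) > len(best))
                and is_quasi_clique(graph, subset, params)
            ):
                best = set(subset)
    return best


def _best_quasi_clique(
    work: nx.Graph, params: QuasiCliqueParams, rng: np.random.Generator
) -> set | None:
    """Largest feasible subset the tabu search can find in ``work``."""
    n = work.number_of_nodes()
    deg = dict(work.degree())
    order = sorted(work.nodes(), key=lambda v: (-deg[v], v))
    if n <= 30:
        # exhaustive size descent: the first feasible size is the answer
        for k in range(n, params.min_clique_size - 1, -1):
            for seed_node in order:
                for _ in range(2):
                    found = _fixed_k_tabu(work, seed_node, k, params, rng, 4 * n + 10)
                    if found is not None:
                        return found
        return None
    # large component: greedy baseline, then ascend while sizes succeed
    best = _largest_feasible_greedy(work, order, params, rng)
    if best is None:
        return None
    k = len(best) + 1
    misses = 0
    while k <= n and misses < 2:
        found = None
        for seed_node in order[:4]:
            found = _fixed_k_tabu(work, seed_node, k, params, rng, 2 * n + 10)
            if found is not None:
                break
        if found is not None:
            best = found
            misses = 0
        else:
            misses += 1
        k += 1
    return best


def _maximalize(graph: nx.Graph, subset: set, params: QuasiCliqueParams) -> set:
    """Greedily add external nodes while the subset stays feasible."""
    subset = set(subset)
    while True:
        cands = []
        for v in {w for u in subset for w in graph.neighbors(u)} - subset:
            if is_quasi_clique(graph, subset | {v}, params):
                cands.append((_links(graph, v, subset), v))
        if not cands:
            return subset
        score = max(cands)[0]
        v = min(n for s, n in cands if s == score)
        subset.add(v)


def find_maximal_quasi_cliques(
    graph: nx.Graph, params: QuasiCliqueParams
) -> list[frozenset]:
    """Disjoint maximal quasi-cliques by repeated tabu extraction.

    Deterministic given ``params.rng_seed``: components, seeds and
    tie-breaks follow a fixed ordering.
    """
    rng = np.random.default_rng(params.rng_seed)
    results: list[frozenset] = []
    for comp in sorted(nx.connected_components(graph), key=min):
        if len(comp) < params.min_clique_size:
            continue
        work = graph.subgraph(comp).copy()
        while work.number_of_nodes() >= params.min_clique_size:
            best = _best_quasi_clique(work, params, rng)
            if best is None:
                break
            best = _maximalize(work, best, params)
            results.append(frozenset(best))
            work.remove_nodes_from(best)
    return results


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _feasible_mask(mask: int, adj: list[int], params: QuasiCliqueParams) -> bool:
    n_in = mask.bit_count()
    if n_in == 1:
        return True
    deg_sum = 0
    m = mask
    while m:
        v = (m & -m).bit_length() - 1
        d = (adj[v] & mask).bit_count()
        if d + _EPS < params.alpha * n_in:
            return False
        deg_sum += d
        m &= m - 1
    return deg_sum / 2 + _EPS >= params.beta * n_in * (n_in - 1) / 2


def brute_force_quasi_cliques(
    graph: nx.Graph, params: QuasiCliqueParams
) -> list[frozenset]:
    """All feasible subsets (size >= min_clique_size) that have no feasible
    proper superset.  Exhaustive over 2^|V| subsets; refuses |V| > 15."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n > 15:
        raise ValueError("brute-force oracle is limited to graphs of <= 15 nodes")
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges():
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    feasible = [
        m
        for m in range(1, 1 << n)
        if m.bit_count() >= params.min_clique_size and _feasible_mask(m, adj, params)
    ]
    feasible.sort(key=int.bit_count, reverse=True)
    maximal: list[int] = []
    for m in feasible:
        if not any(m != big and m & big == m for big in maximal):
            maximal.append(m)
    out = []
    for m in maximal:
        out.append(frozenset(nodes[i] for i in range(n) if m >> i & 1))
    return out


def max_feasible_size(graph: nx.Graph, params: QuasiCliqueParams) -> int:
    """Size of the largest feasible subset (brute force; <= 15 nodes)."""
    cliques = brute_force_quasi_cliques(graph, params)
    return max((len(c) for c in cliques), default=0)


def graph_to_edgelist(graph: nx.Graph) -> str:
    lines = [f"{u}\t{v}" for u, v in sorted(graph.edges())]
    return "\n".join(lines) + ("\n" if lines else "")
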