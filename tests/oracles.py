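"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation: exact rational arithmetic for the contingency tests, explicit
path enumeration for network construction, and scipy.sparse.csgraph for
shortest-path distances.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.sparse.csgraph import shortest_path
import networkx as nx


def fisher_2x2_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by exact rational enumeration."""
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    if n == 0:
        return 1.0
    den = comb(n, r1)
    obs = comb(c1, a) * comb(n - c1, b)
    total = Fraction(0)
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        w = comb(c1, x) * comb(n - c1, r1 - x)
        if w <= obs:
            total += Fraction(w, den)
    return float(min(total, Fraction(1)))


def fisher_2x3_enum(row1, row2) -> float:
    """Two-sided 2x3 exact p by rational enumeration over all tables with the
    observed margins (multivariate hypergeometric null)."""
    r1, r2 = sum(row1), sum(row2)
    if r1 == 0 or r2 == 0:
        return 1.0
    cols = [x + y for x, y in zip(row1, row2)]
    den = comb(r1 + r2, r1)
    obs = comb(cols[0], row1[0]) * comb(cols[1], row1[1]) * comb(cols[2], row1[2])
    total = Fraction(0)
    for a0 in range(0, min(r1, cols[0]) + 1):
        for a1 in range(0, min(r1 - a0, cols[1]) + 1):
            a2 = r1 - a0 - a1
            if a2 > cols[2]:
                continue
            w = comb(cols[0], a0) * comb(cols[1], a1) * comb(cols[2], a2)
            if w <= obs:
                total += Fraction(w, den)
    return float(min(total, Fraction(1)))


def hypergeom_upper_enum(overlap: int, n_universe: int, n_reference: int, n_query: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) by rational summation."""
    total = Fraction(0)
    den = comb(n_universe, n_query)
    for k in range(overlap, min(n_reference, n_query) + 1):
        if n_query - k > n_universe - n_reference:
            continue
        total += Fraction(comb(n_reference, k) * comb(n_universe - n_reference, n_query - k), den)
    return float(min(total, Fraction(1)))


def seed_network_paths(graph: nx.Graph, seeds) -> tuple[set, set]:
    """Node and edge sets of all simple seed-seed paths of length <= 2,
    found by explicit enumeration over seed pairs and intermediaries."""
    mapped = sorted(s for s in set(seeds) if s in graph)
    nodes, edges = set(mapped), set()
    keep_nodes = set()
    for s, t in combinations(mapped, 2):
        if graph.has_edge(s, t):
            edges.add(tuple(sorted((s, t))))
            keep_nodes.update((s, t))
        for w in graph.nodes:
            if w in (s, t) or w in mapped:
                continue
            if graph.has_edge(s, w) and graph.has_edge(w, t):
                keep_nodes.update((s, t, w))
                edges.add(tuple(sorted((s, w))))
                edges.add(tuple(sorted((w, t))))
    # seeds participate even when isolated; intermediaries only via paths
    return nodes | keep_nodes, edges


def separation_csgraph(set_a, set_b, graph: nx.Graph):
    """(d_AA, d_BB, d_AB, s_AB) via an all-pairs scipy.sparse.csgraph matrix."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    mat = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None)
    dist = shortest_path(mat, method="D", unweighted=True)
    a = sorted(x for x in set_a if x in index)
    b = sorted(x for x in set_b if x in index)

    def mean_min(sources, targets_of):
        vals = []
        for s in sources:
            ds = [dist[index[s], index[t]] for t in targets_of(s)]
            ds = [d for d in ds if np.isfinite(d)]
            if ds:
                vals.append(min(ds))
        return float(np.mean(vals)) if vals else None

    d_aa = mean_min(a, lambda s: [x for x in a if x != s])
    d_bb = mean_min(b, lambda s: [x for x in b if x != s])
    cross = []
    for s in a:
        ds = [dist[index[s], index[t]] for t in b]
        ds = [d for d in ds if np.isfinite(d)]
        if ds:
            cross.append(min(ds))
    for s in b:
        ds = [dist[index[s], index[t]] for t in a]
        ds = [d for d in ds if np.isfinite(d)]
        if ds:
            cross.append(min(ds))
    d_ab = float(np.mean(cross)) if cross else None
    s_ab = None
    if None not in (d_aa, d_bb, d_ab):
        s_ab = d_ab - (d_aa + d_bb) / 2
    return d_aa, d_bb, d_ab, s_ab
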