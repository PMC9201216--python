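"""Patient-similarity clustering and cluster-level phenotype enrichment.

Patients are compared by the Jaccard distance between their network node
sets (1 - |V1 n V2| / |V1 u V2|; edge-set distance available as an option),
clustered agglomeratively with UPGMA (average linkage: the distance between
two clusters is the arithmetic mean of all cross-pair leaf distances), and
every dendrogram node of at least ``min_size`` members is tested for
case/control imbalance with a two-sided 2x2 Fisher exact test against the
rest of the cohort.  Nested significant nodes are reduced to the maximal
(closest-to-root) ones for the headline clusters.  Each cluster can be
summarized as a *layered network*: the union of its members' graphs with
per-node and per-edge support counts.

Tie-breaking is deterministic everywhere (lexicographic by sample id), so a
given distance matrix always yields the same dendrogram and Newick string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .errors import InputError
from .io import Cohort
from .networks import SampleNetwork


def jaccard_distance(g1: SampleNetwork, g2: SampleNetwork, on: str = "nodes") -> float:
    """Jaccard distance between two patient networks on node sets (default)
    or edge sets (``on="edges"``)."""
    if on == "nodes":
        a, b = g1.nodes, g2.nodes
    elif on == "edges":
        a, b = g1.edges, g2.edges
    else:
        raise InputError(f"jaccard 'on' must be nodes|edges (got {on!r})")
    union = a | b
    if not union:
        warnings.warn("jaccard distance of two empty networks; returning 1", stacklevel=2)
        return 1.0
    return 1.0 - len(a & b) / len(union)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise InputError("distance matrix shape does not match the id list")
        if np.isnan(m).any():
            raise InputError("distance matrix contains NaN entries")
        if not np.allclose(m, m.T, atol=1e-12) or not np.allclose(np.diag(m), 0, atol=1e-12):
            raise InputError("distance matrix must be symmetric with zero diagonal")
        if (m < -1e-12).any() or (m > 1 + 1e-9).any():
            raise InputError("Jaccard distances must lie in [0, 1]")
        self.matrix = m


def distance_matrix(networks: Iterable[SampleNetwork], on: str = "nodes") -> DistanceMatrix:
    nets = sorted(networks, key=lambda n: n.sample_id)
    ids = [n.sample_id for n in nets]
    n = len(ids)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = jaccard_distance(nets[i], nets[j], on=on)
    return DistanceMatrix(ids=ids, matrix=m)


@dataclass
class DendrogramNode:
    node_id: int
    height: float
    members: tuple[str, ...]  # sorted leaf sample ids
    children: Optional[tuple[int, int]] = None  # None for leaves
    sample: Optional[str] = None  # set for leaves

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    """Rooted binary UPGMA tree; node ids 0..n-1 are leaves, the last id is
    the root.  Merge heights are cophenetic distances and non-decreasing from
    leaves to root."""

    nodes: list[DendrogramNode]
    ids: list[str]

    @property
    def root(self) -> DendrogramNode:
        return self.nodes[-1]

    def leaves(self) -> list[DendrogramNode]:
        return [n for n in self.nodes if n.is_leaf]

    def internal_nodes(self) -> list[DendrogramNode]:
        return [n for n in self.nodes if not n.is_leaf]

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights in the order of ``self.ids``."""
        index = {s: i for i, s in enumerate(self.ids)}
        n = len(self.ids)
        m = np.zeros((n, n))
        for node in self.internal_nodes():
            left, right = node.children
            for a in self.nodes[left].members:
                for b in self.nodes[right].members:
                    m[index[a], index[b]] = m[index[b], index[a]] = node.height
        return m

    def to_newick(self) -> str:
        def render(node_id: int, parent_height: float) -> str:
            node = self.nodes[node_id]
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.sample}:{branch:.10g}"
            left, right = node.children
            inner = ",".join(render(c, node.height) for c in (left, right))
            return f"({inner}):{branch:.10g}"

        root = self.root
        left, right = root.children
        inner = ",".join(render(c, root.height) for c in (left, right))
        return f"({inner});"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with deterministic tie-breaking.

    At each step the pair of active clusters with the smallest mean cross-pair
    distance merges at that distance; ties are broken by the lexicographically
    smallest (leader_i, leader_j) pair where a cluster's leader is its
    smallest member id.
    """
    ids = dist.ids
    n = len(ids)
    if n < 2:
        raise InputError("UPGMA needs at least 2 samples")
    nodes = [
        DendrogramNode(node_id=i, height=0.0, members=(ids[i],), sample=ids[i]) for i in range(n)
    ]
    active: dict[int, tuple[str, ...]] = {i: (ids[i],) for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist.matrix[i, j]) for i, j in combinations(range(n), 2)
    }

    def pair_d(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    next_id = n
    while len(active) > 1:
        best = None
        for i, j in combinations(sorted(active), 2):
            li, lj = active[i][0], active[j][0]
            leaders = (li, lj) if li < lj else (lj, li)
            cand = (pair_d(i, j), leaders, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        height, _, i, j = best
        members = tuple(sorted(active[i] + active[j]))
        nodes.append(DendrogramNode(node_id=next_id, height=height, members=members, children=(i, j)))
        ni, nj = len(active[i]), len(active[j])
        for k in active:
            if k in (i, j):
                continue
            dk = (ni * pair_d(i, k) + nj * pair_d(j, k)) / (ni + nj)
            d[(k, next_id) if k < next_id else (next_id, k)] = dk
        del active[i], active[j]
        active[next_id] = members
        next_id += 1
    return Dendrogram(nodes=nodes, ids=list(ids))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise InputError("2x2 counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class ClusterResult:
    node_id: int
    members: tuple[str, ...]
    n_cases: int
    n_controls: int
    p_value: float
    dominance: str  # "case" | "control" | "neither"
    significant: bool = False
    maximal: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def _dominance(n_cases: int, n_controls: int, cohort: Cohort) -> str:
    # compare the cluster's case fraction with the cohort's base rate
    size = n_cases + n_controls
    if size == 0:
        return "neither"
    base = cohort.n_cases / (cohort.n_cases + cohort.n_controls)
    frac = n_cases / size
    if frac > base:
        return "case"
    if frac < base:
        return "control"
    return "neither"


def significant_clusters(
    tree: Dendrogram,
    cohort: Cohort,
    min_size: int = 3,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ClusterResult]:
    """Test every internal node of at least ``min_size`` members for
    case/control imbalance (members vs non-members, two-sided Fisher).

    Returns all tested nodes ordered by node id; nodes with p below ``alpha``
    (optionally Bonferroni-corrected over the tested nodes) are flagged
    significant, and significant nodes without a significant ancestor are
    flagged maximal — these are the headline clusters.
    """
    labels = cohort.status
    unlabeled = [s for s in tree.ids if s not in labels]
    if unlabeled:
        raise InputError(f"leaves without case/control label: {unlabeled}")
    total_cases = sum(1 for s in tree.ids if labels[s] == "case")
    total_controls = len(tree.ids) - total_cases

    tested: dict[int, ClusterResult] = {}
    candidates = [node for node in tree.internal_nodes() if len(node.members) >= min_size]
    threshold = alpha / len(candidates) if (bonferroni and candidates) else alpha
    for node in candidates:
        n_cases = sum(1 for s in node.members if labels[s] == "case")
        n_controls = len(node.members) - n_cases
        p = fisher_exact_2x2(n_cases, n_controls, total_cases - n_cases, total_controls - n_controls)
        tested[node.node_id] = ClusterResult(
            node_id=node.node_id,
            members=node.members,
            n_cases=n_cases,
            n_controls=n_controls,
            p_value=p,
            dominance=_dominance(n_cases, n_controls, cohort),
            significant=p < threshold,
        )

    # maximal = significant with no significant ancestor
    parent: dict[int, int] = {}
    for node in tree.internal_nodes():
        for child in node.children:
            parent[child] = node.node_id
    for node_id, result in tested.items():
        if not result.significant:
            continue
        anc = parent.get(node_id)
        has_sig_ancestor = False
        while anc is not None:
            if anc in tested and tested[anc].significant:
                has_sig_ancestor = True
                break
            anc = parent.get(anc)
        result.maximal = not has_sig_ancestor
    return [tested[k] for k in sorted(tested)]


@dataclass
class LayeredNetwork:
    """Union of a cluster's member networks with support counts.

    Node attribute ``support`` counts the member networks containing the
    gene; ``role`` is ``seed`` when the gene is a seed in any member and
    ``imputed`` when it is imputed-only.  Edges carry ``support`` likewise.
    """

    cluster_members: tuple[str, ...]
    graph: nx.Graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def role(self, gene: str) -> str:
        return self.graph.nodes[gene]["role"]


def build_layered_network(members: Iterable[str], networks: dict[str, SampleNetwork]) -> LayeredNetwork:
    members = tuple(sorted(members))
    missing = [m for m in members if m not in networks]
    if missing:
        raise InputError(f"cluster members without a sample network: {missing}")
    g = nx.Graph()
    for m in members:
        net = networks[m]
        for node in net.graph.nodes:
            if node not in g:
                g.add_node(node, support=0, seed_in_any=False)
            g.nodes[node]["support"] += 1
            if node in net.seeds:
                g.nodes[node]["seed_in_any"] = True
        for u, v in net.graph.edges:
            if not g.has_edge(u, v):
                g.add_edge(u, v, support=0)
            g[u][v]["support"] += 1
    for node in g.nodes:
        g.nodes[node]["role"] = "seed" if g.nodes[node].pop("seed_in_any") else "imputed"
    return LayeredNetwork(cluster_members=members, graph=g)


def unique_genes(layer_a: LayeredNetwork, layer_b: LayeredNetwork) -> tuple[dict[str, str], dict[str, str]]:
    """Genes present in exactly one of the two layered networks, each mapped to
    its role (``seed`` if seed in any member network, else ``imputed``)."""
    only_a = layer_a.nodes - layer_b.nodes
    only_b = layer_b.nodes - layer_a.nodes
    return (
        {g: layer_a.role(g) for g in sorted(only_a)},
        {g: layer_b.role(g) for g in sorted(only_b)},
    )
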