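"""Interactome handling and per-patient protein-interaction network construction.

The interactome is an undirected, simple graph over gene symbols with an
integer confidence score per edge (STRING-style, 0-1000).  A patient's
network is anchored on that patient's *seed genes*: the network contains a
seed pair when the two seeds interact directly, and additionally any
*imputed* protein that forms a length-2 bridge between two seeds (a single
intermediary interactor).  Longer paths are deliberately excluded — the
maximum path length between seeds is 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConfigurationError, EmptyNetworkError, ParseError

SEED = "seed"
IMPUTED = "imputed"


@dataclass
class Interactome:
    """Undirected scored gene-interaction graph.

    Parameters
    ----------
    graph
        ``networkx.Graph`` whose nodes are gene symbols and whose edges carry
        an integer ``score`` attribute (0-1000 confidence).
    confidence_threshold
        The minimum edge score that was enforced when the graph was loaded;
        retained for provenance.
    """

    graph: nx.Graph
    confidence_threshold: int = 0

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ConfigurationError("interactome contains self-loops")

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph[gene])

    def distances_from(self, gene: str) -> dict[str, int]:
        """Unweighted BFS hop counts from ``gene`` to every reachable node."""
        return nx.single_source_shortest_path_length(self.graph, gene)

    def thresholded(self, confidence_threshold: int) -> "Interactome":
        """Copy with edges below ``confidence_threshold`` removed (nodes kept
        only if they retain at least one edge)."""
        g = nx.Graph()
        for u, v, score in self.graph.edges(data="score"):
            if score is None or score >= confidence_threshold:
                g.add_edge(u, v, score=score)
        return Interactome(g, confidence_threshold=confidence_threshold)


@dataclass
class SampleNetwork:
    """One patient's protein-interaction graph.

    Nodes are gene symbols; each node has a role: ``seed`` (the patient's own
    prioritized gene) or ``imputed`` (a single-intermediary bridge between two
    seeds).  The graph is always a subgraph of the interactome it was built
    from.
    """

    sample_id: str
    graph: nx.Graph
    seeds: frozenset[str]
    imputed: frozenset[str]
    dropped_seeds: tuple[str, ...] = ()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)


def load_interactome(
    path: str | Path,
    confidence_threshold: int = 400,
    alias_path: str | Path | None = None,
) -> Interactome:
    """Read a STRING-style whitespace/TSV edge list ``protein1 protein2 score``.

    Duplicate edges keep the maximum score (with a warning when scores
    conflict); edges scoring below ``confidence_threshold`` are dropped.  An
    optional two-column alias file maps external identifiers to gene symbols
    before thresholding.
    """
    alias: dict[str, str] = {}
    if alias_path is not None:
        with open(alias_path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"expected 2 columns in alias file, got {len(parts)}", i)
                alias[parts[0]] = parts[1]

    graph = nx.Graph()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", i)
            u, v, raw = parts
            u = alias.get(u, u)
            v = alias.get(v, v)
            try:
                score = int(raw)
            except ValueError as exc:
                if i == 1:  # STRING-style files may carry a header row
                    continue
                raise ParseError(f"non-integer score {raw!r}", i) from exc
            if u == v:
                continue
            if graph.has_edge(u, v):
                old = graph[u][v]["score"]
                if old != score:
                    warnings.warn(
                        f"conflicting scores for edge {u}-{v} ({old} vs {score}); keeping max",
                        stacklevel=2,
                    )
                    graph[u][v]["score"] = max(old, score)
            else:
                graph.add_edge(u, v, score=score)

    keep = [(u, v) for u, v, s in graph.edges(data="score") if s >= confidence_threshold]
    pruned = nx.Graph()
    for u, v in keep:
        pruned.add_edge(u, v, score=graph[u][v]["score"])
    return Interactome(pruned, confidence_threshold=confidence_threshold)


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    """Write the edge list in STRING-style TSV (sorted, one direction only)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in interactome.graph.edges):
            fh.write(f"{u}\t{v}\t{interactome.graph[u][v]['score']}\n")


def _component_key(component: set[str], seeds: set[str]) -> tuple:
    # larger first, then more seeds, then lexicographically smallest node set
    members = sorted(component)
    return (-len(component), -len(component & seeds), members)


def build_sample_network(
    seeds,
    interactome: Interactome,
    max_path_length: int = 2,
    keep_all_components: bool = False,
    include_imputed_edges: bool = False,
) -> SampleNetwork:
    """Build one patient's network from their seed genes.

    Nodes are the mapped seeds plus every interactome protein adjacent to at
    least two distinct seeds (an imputed single intermediary).  Edges are
    seed-seed interactome edges and seed-imputed edges; edges between two
    imputed proteins lie on no length-2 seed-seed path and are excluded unless
    ``include_imputed_edges``.  Finally the network is restricted to its
    largest connected component (ties: more seeds, then lexicographically
    smallest node set) unless ``keep_all_components``.

    ``seeds`` may be a :class:`~cohortnet.genotest.SeedGeneSet` or any iterable
    of gene symbols (then the sample id defaults to ``"?"``).
    """
    if max_path_length not in (1, 2):
        raise ConfigurationError("max_path_length must be 1 or 2")
    sample_id = getattr(seeds, "sample_id", "?")
    seed_genes = list(getattr(seeds, "genes", seeds))
    if not seed_genes:
        raise EmptyNetworkError(f"sample {sample_id}: empty seed gene set")

    g = interactome.graph
    mapped = sorted(set(s for s in seed_genes if s in g))
    dropped = tuple(sorted(set(seed_genes) - set(mapped)))
    if not mapped:
        raise EmptyNetworkError(f"sample {sample_id}: no seed gene maps onto the interactome")
    mapped_set = set(mapped)

    imputed: set[str] = set()
    if max_path_length == 2:
        candidate_count: dict[str, int] = {}
        for s in mapped:
            for w in g[s]:
                if w in mapped_set:
                    continue
                candidate_count[w] = candidate_count.get(w, 0) + 1
        imputed = {w for w, c in candidate_count.items() if c >= 2}

    net = nx.Graph()
    net.add_nodes_from(mapped)
    for s, t in combinations(mapped, 2):
        if g.has_edge(s, t):
            net.add_edge(s, t, score=g[s][t]["score"])
    for w in imputed:
        for s in g[w]:
            if s in mapped_set:
                net.add_edge(s, w, score=g[s][w]["score"])
    if include_imputed_edges:
        for w, x in combinations(sorted(imputed), 2):
            if g.has_edge(w, x):
                net.add_edge(w, x, score=g[w][x]["score"])

    if not keep_all_components and net.number_of_nodes() > 0:
        components = sorted(nx.connected_components(net), key=lambda c: _component_key(c, mapped_set))
        net = net.subgraph(components[0]).copy()

    node_seeds = frozenset(n for n in net.nodes if n in mapped_set)
    node_imputed = frozenset(n for n in net.nodes if n not in mapped_set)
    for n in net.nodes:
        net.nodes[n]["role"] = SEED if n in node_seeds else IMPUTED
    return SampleNetwork(
        sample_id=sample_id,
        graph=net,
        seeds=node_seeds,
        imputed=node_imputed,
        dropped_seeds=dropped,
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write GraphML with deterministic node/edge order (stable bytes)."""
    ordered = nx.Graph()
    for n in sorted(graph.nodes):
        ordered.add_node(n, **{k: graph.nodes[n][k] for k in sorted(graph.nodes[n])})
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        ordered.add_edge(u, v, **{k: graph[u][v][k] for k in sorted(graph[u][v])})
    nx.write_graphml(ordered, path, named_key_ids=True)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
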