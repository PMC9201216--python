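"""Interactome separation between two gene sets, and over-representation.

The separation score follows the network-medicine convention: with
unweighted shortest-path (hop) distances on the interactome,

* ``d_AA`` is the mean over genes ``a`` in A of the distance to the nearest
  *other* gene of A (and likewise ``d_BB``);
* ``d_AB`` is the mean, over all genes of both sets, of the distance to the
  nearest gene of the opposite set (a gene shared by both sets contributes
  0);
* ``s_AB = d_AB - (d_AA + d_BB) / 2``.

A positive score means the two sets occupy topologically separated
neighborhoods of the interactome; a negative score means they overlap.
Unreachable pairs are excluded from the means and counted.

``overrepresentation_test`` is a generic one-sided hypergeometric upper-tail
test of a query gene set against a reference set within a stated universe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

from scipy.stats import hypergeom

from .errors import InputError
from .networks import Interactome


@dataclass
class SeparationResult:
    d_aa: Optional[float]
    d_bb: Optional[float]
    d_ab: Optional[float]
    s_ab: Optional[float]
    n_mapped_a: int
    n_mapped_b: int
    n_unmapped_a: int
    n_unmapped_b: int
    n_unreachable: int

    @property
    def separated(self) -> Optional[bool]:
        return None if self.s_ab is None else self.s_ab > 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _nearest(distances: dict[str, int], targets: set[str]) -> Optional[int]:
    best = None
    for t in targets:
        d = distances.get(t)
        if d is not None and (best is None or d < best):
            best = d
    return best


def separation_score(set_a: Iterable[str], set_b: Iterable[str], interactome: Interactome) -> SeparationResult:
    """Compute ``s_AB`` between two gene sets on the interactome.

    Each set must map at least 2 genes onto the interactome.  BFS runs once
    per mapped gene; all distances are hop counts.
    """
    a_all, b_all = set(set_a), set(set_b)
    g = interactome.graph
    a = sorted(x for x in a_all if x in g)
    b = sorted(x for x in b_all if x in g)
    if len(a) < 2:
        raise InputError(f"set A maps only {len(a)} genes onto the interactome (need >= 2)")
    if len(b) < 2:
        raise InputError(f"set B maps only {len(b)} genes onto the interactome (need >= 2)")
    a_set, b_set = set(a), set(b)

    dist = {x: interactome.distances_from(x) for x in sorted(a_set | b_set)}

    unreachable = 0

    def mean_nearest(sources: list[str], targets_for) -> Optional[float]:
        nonlocal unreachable
        terms = []
        for s in sources:
            d = _nearest(dist[s], targets_for(s))
            if d is None:
                unreachable += 1
            else:
                terms.append(d)
        return sum(terms) / len(terms) if terms else None

    d_aa = mean_nearest(a, lambda s: a_set - {s})
    d_bb = mean_nearest(b, lambda s: b_set - {s})
    cross_terms = []
    for sources, targets in ((a, b_set), (b, a_set)):
        for s in sources:
            d = _nearest(dist[s], targets)
            if d is None:
                unreachable += 1
            else:
                cross_terms.append(d)
    d_ab = sum(cross_terms) / len(cross_terms) if cross_terms else None

    s_ab = None
    if d_aa is not None and d_bb is not None and d_ab is not None:
        s_ab = d_ab - (d_aa + d_bb) / 2.0
    return SeparationResult(
        d_aa=d_aa,
        d_bb=d_bb,
        d_ab=d_ab,
        s_ab=s_ab,
        n_mapped_a=len(a),
        n_mapped_b=len(b),
        n_unmapped_a=len(a_all) - len(a),
        n_unmapped_b=len(b_all) - len(b),
        n_unreachable=unreachable,
    )


def overrepresentation_test(query: Iterable[str], reference: Iterable[str], universe: Iterable[str]) -> float:
    """One-sided hypergeometric upper-tail p for the overlap of ``query`` with
    ``reference`` inside ``universe``."""
    universe = set(universe)
    if not universe:
        raise InputError("universe must be non-empty")
    query = set(query) & universe
    reference = set(reference) & universe
    overlap = len(query & reference)
    m, n_ref, n_query = len(universe), len(reference), len(query)
    if overlap == 0 and (n_ref == 0 or n_query == 0):
        return 1.0
    return float(hypergeom.sf(overlap - 1, m, n_ref, n_query))
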