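"""Per-interval haplotype graph: assembly, conflict resolution, queries.

Each heterozygous site in an interval is a node; pairwise phase
relations (read, trio or caller-physical evidence) are edges carrying an
orientation (cis/trans) and a confidence.  Parental origins are encoded
through a virtual anchor node: a paternal variant connects to the anchor
with a cis edge, a maternal one with a trans edge, so any two
same-origin variants come out cis through the anchor and opposite-origin
variants trans — the anchor behaves like a variant known to sit on the
paternal haplotype.

A pair is phased by its direct edge if one exists, otherwise along the
path with the fewest edges (ties broken by the larger confidence
product): the orientation is cis iff the path contains an even number of
trans edges, and the confidence is the product of the edge confidences,
reflecting the growing uncertainty of longer chains.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import networkx as nx

from phaseclear.datamodel import (
    PairResult,
    ParentalOrigin,
    PhaseEdge,
    VariantSite,
    encode_flags,
)

#: Virtual node representing the paternal haplotype for trio edges.
ANCHOR = ("__origin_anchor__",)


def physical_phase_edge(v1: VariantSite, v2: VariantSite) -> Optional[PhaseEdge]:
    """Phase relation adopted from a caller's physical-phasing annotation.

    Two variants in the same caller phase set (equal PID) with ordered
    phased genotypes (PGT) are cis when their alternate alleles sit on
    the same side of the ordered genotypes, trans otherwise, with
    confidence 1.0.  Intended only as a fallback for a variant that is
    neither visible in the reads nor trio-phaseable.
    """
    if v1.phase_set_id is None or v1.phase_set_id != v2.phase_set_id:
        return None
    if not v1.phase_set_gt or not v2.phase_set_gt:
        return None
    sides = []
    for v in (v1, v2):
        parts = v.phase_set_gt.split("|")
        if len(parts) != 2 or parts[0] == parts[1]:
            return None
        # the alt allele's side: index of the non-reference allele
        try:
            sides.append([int(p) != 0 for p in parts].index(True))
        except ValueError:
            return None
    return PhaseEdge(
        endpoints=frozenset((v1.key, v2.key)),
        orientation="cis" if sides[0] == sides[1] else "trans",
        confidence=1.0,
        source="physical",
    )


class PhaseGraph:
    """Multigraph over het sites in one interval plus the origin anchor."""

    def __init__(self) -> None:
        self._g = nx.MultiGraph()
        self._g.add_node(ANCHOR)

    def add_variant(self, v: VariantSite) -> None:
        self._g.add_node(v.key)

    def add_edge(self, u, w, edge: PhaseEdge) -> None:
        self._g.add_edge(u, w, orientation=edge.orientation,
                         confidence=edge.confidence, source=edge.source)

    def add_trio_origin(self, v: VariantSite, origin: ParentalOrigin) -> None:
        """Encode a parental origin as an edge to the anchor node
        (paternal = cis, maternal = trans)."""
        edge = PhaseEdge(
            endpoints=frozenset((v.key, ANCHOR)),
            orientation="cis" if origin.origin == "paternal" else "trans",
            confidence=origin.confidence,
            source="trio",
        )
        self.add_edge(v.key, ANCHOR, edge)

    @property
    def graph(self) -> nx.MultiGraph:
        return self._g

    def direct_edge(self, u, w) -> Optional[dict]:
        if not self._g.has_edge(u, w):
            return None
        datas = list(self._g[u][w].values())
        if len(datas) != 1:
            raise RuntimeError("resolve_conflicts must run before queries")
        return datas[0]


def build_graph(
    variants: Sequence[VariantSite],
    read_edges: Sequence[tuple[VariantSite, VariantSite, PhaseEdge]] = (),
    trio_origins: Sequence[tuple[VariantSite, ParentalOrigin]] = (),
    physical_edges: Sequence[tuple[VariantSite, VariantSite, PhaseEdge]] = (),
) -> PhaseGraph:
    """Assemble one interval's evidence into a phase graph.

    Read edges are added as-is; each trio origin becomes an anchor edge,
    which lets pedigree-phased variants bridge otherwise disjoint
    read-phased blocks; physical edges are expected to be pre-filtered
    to the fallback condition (endpoint not found in reads and not
    trio-phased) and never override read or trio evidence.
    """
    g = PhaseGraph()
    for v in variants:
        g.add_variant(v)
    for u, w, e in read_edges:
        g.add_edge(u.key, w.key, e)
    for v, origin in trio_origins:
        g.add_trio_origin(v, origin)
    for u, w, e in physical_edges:
        g.add_edge(u.key, w.key, e)
    return g


def resolve_conflicts(g: PhaseGraph) -> PhaseGraph:
    """Collapse parallel edges, keeping the most confident evidence.

    Between one node pair: edges of one orientation collapse to the
    max-confidence edge; conflicting orientations are resolved by
    confidence; an exact confidence tie between conflicting orientations
    drops the pair entirely (abstain).
    """
    mg = g.graph
    pairs = {}
    for a, b, key, data in mg.edges(keys=True, data=True):
        pairs.setdefault(frozenset((a, b)), []).append(data)
    for pair, datas in pairs.items():
        a, b = tuple(pair)
        best_by_orient = {}
        for d in datas:
            o = d["orientation"]
            if o not in best_by_orient or d["confidence"] > best_by_orient[o]["confidence"]:
                best_by_orient[o] = d
        mg.remove_edges_from([(a, b, k) for k in list(mg[a][b])])
        if len(best_by_orient) == 1:
            (d,) = best_by_orient.values()
            mg.add_edge(a, b, **d)
        else:
            dc, dt = best_by_orient["cis"], best_by_orient["trans"]
            if dc["confidence"] > dt["confidence"]:
                mg.add_edge(a, b, **dc)
            elif dt["confidence"] > dc["confidence"]:
                mg.add_edge(a, b, **dt)
            # exact tie: drop both
    return g


def _best_path(mg: nx.MultiGraph, u, w) -> Optional[list]:
    """Fewest-edges path from u to w, ties broken by maximal confidence
    product; None if disconnected."""
    if u not in mg or w not in mg:
        return None
    try:
        paths = list(nx.all_shortest_paths(mg, u, w))
    except nx.NetworkXNoPath:
        return None
    def product(path):
        return math.prod(
            mg[a][b][next(iter(mg[a][b]))]["confidence"]
            for a, b in itertools.pairwise(path)
        )
    return max(paths, key=product)


def query_pair(
    g: PhaseGraph,
    v1: VariantSite,
    v2: VariantSite,
    found1: bool = True,
    found2: bool = True,
    innocuous: bool = False,
    threshold: float = 0.34,
) -> PairResult:
    """Phase one candidate pair from the resolved graph.

    A direct edge is preferred; otherwise the fewest-edges path (the
    anchor may be traversed) gives orientation by trans-edge parity and
    confidence by the product of edge confidences.  A disconnected pair
    is unphased; its not-found bit is set iff one of the variant alleles
    was not observed in the alignments.  The innocuous bit is orthogonal.
    Confidences below ``threshold`` do not change the flag — the score is
    reported for downstream filtering.
    """
    if v1.key == v2.key:
        raise ValueError("a pair needs two distinct variants")
    mg = g.graph
    direct = g.direct_edge(v1.key, v2.key)
    if direct is not None:
        orientation = direct["orientation"]
        conf = direct["confidence"]
        source = direct["source"]
    else:
        path = _best_path(mg, v1.key, v2.key)
        if path is None:
            not_found = not (found1 and found2)
            flag = encode_flags(None, innocuous=innocuous, not_found=not_found)
            return PairResult(v1, v2, flag, 0.0, "none")
        n_trans = 0
        conf = 1.0
        sources = set()
        for a, b in itertools.pairwise(path):
            d = mg[a][b][next(iter(mg[a][b]))]
            if d["orientation"] == "trans":
                n_trans += 1
            conf *= d["confidence"]
            sources.add(d["source"])
        orientation = "cis" if n_trans % 2 == 0 else "trans"
        source = sources.pop() if len(sources) == 1 else "path"
    physical = source == "physical"
    flag = encode_flags(orientation, innocuous=innocuous, not_found=False,
                        physical=physical)
    return PairResult(v1, v2, flag, conf, source)
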