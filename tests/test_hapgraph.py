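import itertools
import math

import pytest

from conftest import make_site
from phaseclear.datamodel import ParentalOrigin, PhaseEdge, decode_flags
from phaseclear.hapgraph import (
    build_graph,
    physical_phase_edge,
    query_pair,
    resolve_conflicts,
)


def edge(orientation, confidence, source="read"):
    return PhaseEdge(frozenset(), orientation, confidence, source)


def ps_site(pos, pid, pgt):
    return make_site(pos, phase_set_id=pid, phase_set_gt=pgt)


class TestPhysicalPhaseEdge:
    def test_same_side_is_cis(self):
        e = physical_phase_edge(ps_site(100, "b1", "0|1"), ps_site(200, "b1", "0|1"))
        assert (e.orientation, e.confidence, e.source) == ("cis", 1.0, "physical")

    def test_opposite_sides_is_trans(self):
        e = physical_phase_edge(ps_site(100, "b1", "0|1"), ps_site(200, "b1", "1|0"))
        assert e.orientation == "trans"

    def test_different_blocks_are_unlinked(self):
        assert physical_phase_edge(
            ps_site(100, "b1", "0|1"), ps_site(200, "b2", "0|1")) is None

    def test_missing_annotation(self):
        assert physical_phase_edge(make_site(100), ps_site(200, "b1", "0|1")) is None


class TestBuildAndResolve:
    def test_read_chain_is_one_component(self):
        v = [make_site(p) for p in (100, 200, 300)]
        g = build_graph(v, read_edges=[(v[0], v[1], edge("cis", 0.5)),
                                       (v[1], v[2], edge("trans", 0.5))])
        comps = [c for c in __import__("networkx").connected_components(g.graph)]
        assert {v[0].key, v[1].key, v[2].key} in comps  # anchor isolated

    def test_trio_origins_bridge_blocks(self):
        """Two read-phased blocks each holding one pedigree-phased
        variant join into a single component through the anchor."""
        v = [make_site(p) for p in (100, 200, 5000, 5100)]
        g = build_graph(
            v,
            read_edges=[(v[0], v[1], edge("cis", 0.9)),
                        (v[2], v[3], edge("cis", 0.9))],
            trio_origins=[(v[0], ParentalOrigin("paternal", 1.0)),
                          (v[3], ParentalOrigin("maternal", 1.0))],
        )
        import networkx as nx
        assert nx.has_path(g.graph, v[1].key, v[2].key)

    def test_conflict_resolved_by_confidence(self):
        v = [make_site(100), make_site(200)]
        g = build_graph(v, read_edges=[(v[0], v[1], edge("trans", 0.5))])
        g.add_edge(v[0].key, v[1].key, edge("cis", 1.0, "trio"))
        resolve_conflicts(g)
        d = g.direct_edge(v[0].key, v[1].key)
        assert (d["orientation"], d["source"]) == ("cis", "trio")

    def test_same_orientation_collapses_to_max(self):
        v = [make_site(100), make_site(200)]
        g = build_graph(v, read_edges=[(v[0], v[1], edge("cis", 0.4)),
                                       (v[0], v[1], edge("cis", 0.6))])
        resolve_conflicts(g)
        d = g.direct_edge(v[0].key, v[1].key)
        assert d["confidence"] == 0.6

    def test_exact_conflicting_tie_drops_both(self):
        v = [make_site(100), make_site(200)]
        g = build_graph(v, read_edges=[(v[0], v[1], edge("cis", 0.5)),
                                       (v[0], v[1], edge("trans", 0.5))])
        resolve_conflicts(g)
        assert g.direct_edge(v[0].key, v[1].key) is None


class TestQueryPair:
    def test_direct_trio_pair(self):
        v = [make_site(100), make_site(200)]
        g = resolve_conflicts(build_graph(
            v, trio_origins=[(v[0], ParentalOrigin("paternal", 1.0)),
                             (v[1], ParentalOrigin("paternal", 1.0))]))
        r = query_pair(g, v[0], v[1])
        assert (r.phase, r.confidence, r.source) == ("cis", 1.0, "trio")
        assert r.flag == 1

    def test_path_parity_and_product(self):
        """Two trans hops make cis; confidence is the product 0.72."""
        v = [make_site(p) for p in (100, 200, 300)]
        g = resolve_conflicts(build_graph(
            v, read_edges=[(v[0], v[1], edge("trans", 0.9)),
                           (v[1], v[2], edge("trans", 0.8))]))
        r = query_pair(g, v[0], v[2])
        assert r.phase == "cis"
        assert r.confidence == pytest.approx(0.72, abs=1e-12)

    def test_disconnected_not_found(self):
        v = [make_site(100), make_site(5000)]
        g = resolve_conflicts(build_graph(v))
        r = query_pair(g, v[0], v[1], found1=True, found2=False, innocuous=True)
        assert r.flag == 12
        assert decode_flags(r.flag)["not_found"]
        r2 = query_pair(g, v[0], v[1], found1=True, found2=True)
        assert r2.flag == 0 and r2.phase is None

    def test_query_symmetry(self):
        v = [make_site(p) for p in (100, 200, 300)]
        g = resolve_conflicts(build_graph(
            v,
            read_edges=[(v[0], v[1], edge("trans", 0.7))],
            trio_origins=[(v[1], ParentalOrigin("maternal", 1.0)),
                          (v[2], ParentalOrigin("paternal", 0.66))],
        ))
        for a, b in itertools.combinations(v, 2):
            fwd, rev = query_pair(g, a, b), query_pair(g, b, a)
            assert fwd.flag == rev.flag
            assert fwd.confidence == pytest.approx(rev.confidence, abs=1e-15)

    def test_path_confidence_bounded_by_min_edge(self):
        confs = [0.9, 0.66, 0.8, 0.95]
        v = [make_site(100 * (i + 1)) for i in range(len(confs) + 1)]
        g = resolve_conflicts(build_graph(
            v, read_edges=[(v[i], v[i + 1], edge("cis", c))
                           for i, c in enumerate(confs)]))
        r = query_pair(g, v[0], v[-1])
        assert r.confidence <= min(confs) + 1e-15
        assert r.confidence == pytest.approx(math.prod(confs), abs=1e-12)

    def test_cycle_parity_on_consistent_graph(self):
        """In a conflict-free graph built from one true haplotype
        assignment, every cycle carries an even number of trans edges."""
        import networkx as nx
        # plant variants on haplotypes: 1,2 on hapA; 3,4 on hapB
        hap = {1: "A", 2: "A", 3: "B", 4: "B"}
        v = {i: make_site(100 * i) for i in hap}
        edges = []
        for i, j in itertools.combinations(hap, 2):
            orient = "cis" if hap[i] == hap[j] else "trans"
            edges.append((v[i], v[j], edge(orient, 0.9)))
        g = resolve_conflicts(build_graph(list(v.values()), read_edges=edges))
        for cycle in nx.cycle_basis(nx.Graph(g.graph)):
            n_trans = 0
            ring = cycle + [cycle[0]]
            for a, b in zip(ring, ring[1:]):
                d = g.graph[a][b][next(iter(g.graph[a][b]))]
                n_trans += d["orientation"] == "trans"
            assert n_trans % 2 == 0
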