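"""Greedy end-graph linking, chain extraction and ratio-based breaking."""

import random

import pytest

from porec_scaffold.link_weights import EndRef, LinkWeightTable
from porec_scaffold.scaffold_builder import (
    LinkEdge,
    ScaffoldChain,
    break_chains,
    extract_chains,
    greedy_link,
    init_end_graph,
    order_and_orient,
)

H, T = "head", "tail"


def e(c, end):
    return EndRef(c, end)


def table_from(entries):
    """entries: {(end_a, end_b): (w_sim, w_cov)}"""
    t = LinkWeightTable()
    for (a, b), (sim, cov) in entries.items():
        t.entry(a, b).add(1000, cov, sim)
    return t


class TestInitEndGraph:
    def test_three_contigs(self):
        g = init_end_graph(["c1", "c2", "c3"])
        assert len(g._parent) == 6
        for c in ("c1", "c2", "c3"):
            assert g.connected(e(c, H), e(c, T))  # internal edge
            assert g.degree(e(c, H)) == 1

    def test_single_contig(self):
        g = init_end_graph(["c1"])
        assert g.connected(e("c1", H), e("c1", T))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            init_end_graph([])


class TestGreedyLink:
    def test_degree_rule_blocks_second_edge_on_same_end(self):
        g = init_end_graph(["c1", "c2", "c3"])
        cands = [
            ((e("c1", T), e("c2", H)), 20.0),
            ((e("c2", H), e("c3", T)), 18.0),
        ]
        greedy_link(g, cands, threshold=15.0, stage=1)
        assert e("c1", T) in g.links and e("c2", H) in g.links
        assert e("c3", T) not in g.links  # c2.head already at degree 2

    def test_internal_partner_rejected_as_cycle(self):
        g = init_end_graph(["c1"])
        greedy_link(g, [((e("c1", T), e("c1", H)), 50.0)], threshold=15.0, stage=1)
        assert g.links == {}

    def test_three_contig_cycle_rejected(self):
        g = init_end_graph(["c1", "c2", "c3"])
        cands = [
            ((e("c1", T), e("c2", H)), 30.0),
            ((e("c2", T), e("c3", H)), 29.0),
            ((e("c3", T), e("c1", H)), 28.0),  # would close the loop
        ]
        greedy_link(g, cands, threshold=15.0, stage=1)
        assert e("c3", T) not in g.links and e("c1", H) not in g.links
        assert len(g.links) == 4  # two accepted edges, both endpoints indexed

    def test_below_threshold_never_considered(self):
        g = init_end_graph(["c1", "c2"])
        greedy_link(g, [((e("c1", T), e("c2", H)), 14.9)], threshold=15.0, stage=1)
        assert g.links == {}

    def test_equal_weights_resolved_lexicographically(self):
        g = init_end_graph(["c1", "c2", "c3"])
        cands = [
            ((e("c2", H), e("c3", H)), 20.0),
            ((e("c1", H), e("c2", H)), 20.0),
        ]
        greedy_link(g, cands, threshold=15.0, stage=1)
        assert g.links[e("c2", H)].other(e("c2", H)) == e("c1", H)


class TestOrderAndOrient:
    def test_two_stage_selection(self):
        # (c1.t, c2.h): strong sim -> stage 1
        # (c2.t, c3.h): weak sim, decent cov -> stage 2
        # (c3.t, c4.h): below both thresholds -> never linked
        t = table_from(
            {
                (e("c1", T), e("c2", H)): (16.0, 9.0),
                (e("c2", T), e("c3", H)): (5.0, 12.0),
                (e("c3", T), e("c4", H)): (5.0, 5.0),
            }
        )
        g = order_and_orient(["c1", "c2", "c3", "c4"], t)
        assert g.links[e("c1", T)].stage == 1
        assert g.links[e("c2", T)].stage == 2
        assert e("c3", T) not in g.links

    def test_stage_one_links_survive_stage_two(self):
        # stage-2 candidate would steal c2.head if stage-1 links were dropped
        t = table_from(
            {
                (e("c1", T), e("c2", H)): (16.0, 0.0),
                (e("c3", T), e("c2", H)): (0.0, 50.0),
            }
        )
        g = order_and_orient(["c1", "c2", "c3"], t)
        assert g.links[e("c2", H)].other(e("c2", H)) == e("c1", T)


class TestExtractChains:
    @pytest.mark.parametrize(
        "link,expected",
        [
            ((e("c1", T), e("c2", H)), [("c1", "+"), ("c2", "+")]),
            ((e("c1", T), e("c2", T)), [("c1", "+"), ("c2", "-")]),
            ((e("c1", H), e("c2", H)), [("c1", "-"), ("c2", "+")]),
            ((e("c1", H), e("c2", T)), [("c1", "-"), ("c2", "-")]),
        ],
    )
    def test_four_linking_types(self, link, expected):
        g = init_end_graph(["c1", "c2"])
        g.add_link(LinkEdge(link[0], link[1], 20.0, 1))
        (chain,) = extract_chains(g)
        assert chain.entries == expected

    def test_isolated_contig_singleton(self):
        g = init_end_graph(["c1"])
        (chain,) = extract_chains(g)
        assert chain.entries == [("c1", "+")] and chain.joins == []

    def test_canonical_direction_starts_at_smaller_contig(self):
        g = init_end_graph(["c1", "c2", "c3"])
        g.add_link(LinkEdge(e("c3", T), e("c2", H), 20.0, 1))
        g.add_link(LinkEdge(e("c2", T), e("c1", H), 19.0, 1))
        (chain,) = extract_chains(g)
        assert chain.contig_ids == ["c1", "c2", "c3"]

    def test_chains_partition_cluster(self):
        rng = random.Random(3)
        contigs = [f"c{i:02d}" for i in range(12)]
        g = init_end_graph(contigs)
        cands = []
        for i in range(30):
            a, b = rng.sample(contigs, 2)
            cands.append(((e(a, rng.choice([H, T])), e(b, rng.choice([H, T]))), rng.uniform(15, 40)))
        greedy_link(g, cands, threshold=15.0, stage=1)
        chains = extract_chains(g)
        seen = [c for ch in chains for c in ch.contig_ids]
        assert sorted(seen) == sorted(contigs)

    def test_reversal_flips_all_orientations(self):
        g = init_end_graph(["c1", "c2"])
        g.add_link(LinkEdge(e("c1", T), e("c2", T), 20.0, 1))
        (chain,) = extract_chains(g)
        rev = chain.reversed()
        assert rev.entries == [("c2", "+"), ("c1", "-")]
        assert rev.reversed().entries == chain.entries

    def test_acyclic_invariant_matches_reachability_oracle(self):
        # after greedy linking, adding any *rejected* candidate that
        # connected two already-reachable ends would have closed a cycle
        rng = random.Random(5)
        contigs = [f"c{i:02d}" for i in range(20)]
        g = init_end_graph(contigs)
        cands = []
        for _ in range(60):
            a, b = rng.sample(contigs, 2)
            cands.append(((e(a, rng.choice([H, T])), e(b, rng.choice([H, T]))), rng.uniform(15, 40)))
        greedy_link(g, cands, threshold=15.0, stage=1)
        # brute-force reachability over internal + link edges
        adj = {}
        for c in contigs:
            adj.setdefault(e(c, H), set()).add(e(c, T))
            adj.setdefault(e(c, T), set()).add(e(c, H))
        for v, edge in g.links.items():
            adj[v].add(edge.other(v))

        def reachable(src, dst):
            stack, seen = [src], {src}
            while stack:
                cur = stack.pop()
                if cur == dst:
                    return True
                for nxt in adj[cur]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return False

        for v in adj:
            assert g.degree(v) <= 2
        for u in adj:
            for w in adj:
                assert g.connected(u, w) == reachable(u, w)


class TestBreakChains:
    def _chain(self, weights):
        entries = [(f"c{i}", "+") for i in range(len(weights) + 1)]
        joins = [
            LinkEdge(e(f"c{i}", T), e(f"c{i+1}", H), w, 1, w_sim=w, w_cov=0.0)
            for i, w in enumerate(weights)
        ]
        return ScaffoldChain(entries=entries, joins=joins)

    def test_sharp_drop_cuts_chain(self):
        out = break_chains([self._chain([100, 95, 4])], 0.1)
        assert [len(c.entries) for c in out] == [3, 1]

    def test_gentle_decay_untouched(self):
        out = break_chains([self._chain([100, 95, 90])], 0.1)
        assert [len(c.entries) for c in out] == [4]

    def test_single_join_never_cut(self):
        out = break_chains([self._chain([2.0])], 0.1)
        assert [len(c.entries) for c in out] == [2]

    def test_cut_resets_comparison(self):
        # 5/100 < 0.1 cuts; then 4 starts a fresh chain and is not compared
        out = break_chains([self._chain([100, 5, 4])], 0.1)
        assert [len(c.entries) for c in out] == [2, 2]

    def test_both_directions_cuts_leading_jump(self):
        # forward walk never cuts (ratios rise); reverse walk sees 4/95 < 0.1
        out = break_chains([self._chain([4, 95, 100])], 0.1, both_directions=True)
        assert [len(c.entries) for c in out] == [1, 3]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            break_chains([self._chain([1.0])], 1.5)

    def test_contigs_conserved(self):
        ch = self._chain([100, 95, 4, 50, 3])
        out = break_chains([ch], 0.1)
        assert sorted(c for o in out for c in o.contig_ids) == sorted(ch.contig_ids)
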