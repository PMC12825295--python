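"""Ordering and orienting contigs inside a cluster.

Each contig contributes two graph vertices (its head and tail) joined by an
internal edge.  Link edges between ends of different contigs are then
inserted greedily, highest weight first, in two stages: first from the
orientation-precise cosine-similarity weights (threshold 15), then from the
more sensitive terminal-coverage weights (threshold 10) to join what is
still loose.  An edge is accepted only if both endpoints still have degree
< 2 (at most one link per contig end, the internal edge counts) and it does
not close a cycle, so the result is always a forest of simple paths.  Paths
are read off as ordered, oriented chains; finally chains are re-cut where
the join weight drops off sharply relative to its predecessor, a signature
of a spurious join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .link_weights import EndRef, HEAD, TAIL, LinkWeightTable

__all__ = [
    "LinkEdge",
    "EndGraph",
    "ScaffoldChain",
    "init_end_graph",
    "greedy_link",
    "order_and_orient",
    "extract_chains",
    "break_chains",
    "DEFAULT_SIM_THRESHOLD",
    "DEFAULT_COV_THRESHOLD",
    "DEFAULT_BREAK_RATIO",
]

#: Minimum summed cosine-similarity weight for a stage-1 link.
DEFAULT_SIM_THRESHOLD = 15.0
#: Minimum summed terminal-coverage weight for a stage-2 link.
DEFAULT_COV_THRESHOLD = 10.0
#: Chains are cut where consecutive join weights drop below this ratio.
DEFAULT_BREAK_RATIO = 0.1


@dataclass
class LinkEdge:
    """A chosen link between two contig ends, with its provenance."""

    end_a: EndRef
    end_b: EndRef
    weight: float  # the weight it was selected by (stage-specific)
    stage: int  # 1 = cosine similarity, 2 = terminal coverage
    w_sim: float = 0.0
    w_cov: float = 0.0
    gap: int | None = None

    @property
    def w_total(self) -> float:
        return self.w_sim + self.w_cov

    def other(self, v: EndRef) -> EndRef:
        return self.end_b if v == self.end_a else self.end_a


def _other_end(v: EndRef) -> EndRef:
    return EndRef(v.contig_id, TAIL if v.end == HEAD else HEAD)


class EndGraph:
    """Contig-end graph: internal edges plus at most one link per vertex.

    Acyclicity is maintained with union-find over internal + link edges;
    together with the degree cap this keeps the graph a forest of paths.
    """

    def __init__(self, contigs: Sequence[str]):
        if not contigs:
            raise ValueError("cannot build an end graph for an empty cluster")
        self.contigs: list[str] = list(dict.fromkeys(contigs))
        self.links: dict[EndRef, LinkEdge] = {}
        self._parent: dict[EndRef, EndRef] = {}
        for c in self.contigs:
            h, t = EndRef(c, HEAD), EndRef(c, TAIL)
            self._parent[h] = h
            self._parent[t] = t
            self._union(h, t)  # the internal edge

    # -- union-find -------------------------------------------------------
    def _find(self, v: EndRef) -> EndRef:
        root = v
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[v] != root:  # path compression
            self._parent[v], v = root, self._parent[v]
        return root

    def _union(self, a: EndRef, b: EndRef) -> None:
        self._parent[self._find(a)] = self._find(b)

    def connected(self, a: EndRef, b: EndRef) -> bool:
        return self._find(a) == self._find(b)

    # -- degrees and linking ----------------------------------------------
    def degree(self, v: EndRef) -> int:
        """Internal edge (always present) plus the link edge if any."""
        return 1 + (1 if v in self.links else 0)

    def can_link(self, a: EndRef, b: EndRef) -> bool:
        return self.degree(a) < 2 and self.degree(b) < 2 and not self.connected(a, b)

    def add_link(self, edge: LinkEdge) -> None:
        if not self.can_link(edge.end_a, edge.end_b):
            raise ValueError(f"illegal link {edge.end_a} -- {edge.end_b}")
        self.links[edge.end_a] = edge
        self.links[edge.end_b] = edge
        self._union(edge.end_a, edge.end_b)


@dataclass
class ScaffoldChain:
    """An ordered, oriented run of contigs with per-join link info.

    ``entries[i]`` is (contig_id, orientation); orientation is '+' when the
    chain traverses the contig head -> tail.  ``joins[i]`` links entries i
    and i+1.
    """

    entries: list[tuple[str, str]]
    joins: list[LinkEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.joins) != max(0, len(self.entries) - 1):
            raise ValueError("chain needs exactly one join per adjacent entry pair")

    @property
    def contig_ids(self) -> list[str]:
        return [c for c, _ in self.entries]

    def reversed(self) -> "ScaffoldChain":
        flip = {"+": "-", "-": "+"}
        return ScaffoldChain(
            entries=[(c, flip[o]) for c, o in reversed(self.entries)],
            joins=list(reversed(self.joins)),
        )


def init_end_graph(contigs: Sequence[str]) -> EndGraph:
    """Two vertices and one internal edge per contig; no links yet."""
    return EndGraph(contigs)


def _candidate_sort_key(item: tuple[tuple[EndRef, EndRef], float]):
    (a, b), w = item
    return (-w, a.contig_id, a.end, b.contig_id, b.end)


def greedy_link(
    graph: EndGraph,
    candidates: Iterable[tuple[tuple[EndRef, EndRef], float]],
    threshold: float,
    stage: int,
    table: LinkWeightTable | None = None,
) -> EndGraph:
    """Insert candidate links greedily, highest weight first.

    Candidates below ``threshold`` are never considered; equal weights are
    broken lexicographically for determinism.  A candidate is accepted only
    while both ends are free (degree < 2) and its insertion keeps the graph
    acyclic.
    """
    ordered = sorted(
        (((a, b) if a <= b else (b, a), w) for (a, b), w in candidates),
        key=_candidate_sort_key,
    )
    for (a, b), w in ordered:
        if w < threshold:
            break  # sorted descending: nothing below the cut can follow
        if a.contig_id == b.contig_id:
            continue  # both ends of one contig are already joined internally
        if graph.can_link(a, b):
            pw = table.get(a, b) if table is not None else None
            graph.add_link(
                LinkEdge(
                    end_a=a,
                    end_b=b,
                    weight=w,
                    stage=stage,
                    w_sim=pw.w_sim if pw else 0.0,
                    w_cov=pw.w_cov if pw else 0.0,
                )
            )
    return graph


def order_and_orient(
    contigs: Sequence[str],
    table: LinkWeightTable,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> EndGraph:
    """Two-stage greedy linking of a cluster's contigs.

    Stage 1 links by cosine-similarity weight (orientation-precise);
    stage 2 keeps those links and supplements them with terminal-coverage
    links among the still-free ends.
    """
    graph = init_end_graph(contigs)
    members = set(graph.contigs)
    in_cluster = [
        ((a, b), w)
        for (a, b), w in table.items()
        if a.contig_id in members and b.contig_id in members
    ]
    greedy_link(graph, [((a, b), w.w_sim) for (a, b), w in in_cluster], sim_threshold, 1, table)
    greedy_link(graph, [((a, b), w.w_cov) for (a, b), w in in_cluster], cov_threshold, 2, table)
    return graph


def extract_chains(graph: EndGraph) -> list[ScaffoldChain]:
    """Walk each path component into an ordered, oriented chain.

    The walk starts from the path endpoint whose contig is lexicographically
    smaller; traversal entering a contig at its head yields '+', at its
    tail '-'.  A cycle would violate the graph invariant and raises.
    """
    chains: list[ScaffoldChain] = []
    visited: set[str] = set()
    for contig in sorted(graph.contigs):
        if contig in visited:
            continue
        # find a free end of this component by walking left from here
        start = EndRef(contig, HEAD)
        seen: set[str] = {contig}
        while start in graph.links:
            nxt = graph.links[start].other(start)
            if nxt.contig_id in seen:
                raise ValueError("cycle detected in end graph")
            seen.add(nxt.contig_id)
            start = _other_end(nxt)
        # walk from the free end: the chain enters its first contig there
        entry = start
        entries: list[tuple[str, str]] = []
        joins: list[LinkEdge] = []
        while True:
            c = entry.contig_id
            visited.add(c)
            entries.append((c, "+" if entry.end == HEAD else "-"))
            exit_v = _other_end(entry)
            edge = graph.links.get(exit_v)
            if edge is None:
                break
            joins.append(edge)
            entry = edge.other(exit_v)
            if entry.contig_id in {c for c, _ in entries}:
                raise ValueError("cycle detected in end graph")
        chain = ScaffoldChain(entries=entries, joins=joins)
        if len(chain.entries) > 1 and chain.entries[-1][0] < chain.entries[0][0]:
            chain = chain.reversed()
        chains.append(chain)
    return chains


def _forward_cuts(weights: Sequence[float], ratio_threshold: float) -> set[int]:
    """Indices of joins whose weight collapses relative to the previous one.

    A cut resets the comparison: the next join starts a new chain and is not
    tested against anything.
    """
    cuts: set[int] = set()
    prev: float | None = None
    for i, w in enumerate(weights):
        if prev is not None and prev > 0 and w / prev < ratio_threshold:
            cuts.add(i)
            prev = None
        else:
            prev = w
    return cuts


def break_chains(
    chains: Iterable[ScaffoldChain],
    ratio_threshold: float = DEFAULT_BREAK_RATIO,
    both_directions: bool = False,
) -> list[ScaffoldChain]:
    """Cut chains at abrupt join-weight drops.

    Walking each chain in its canonical direction, a join is cut when its
    W_total falls below ``ratio_threshold`` times the previous join's.
    With ``both_directions`` the reverse walk may add further cuts.
    """
    if not (0 < ratio_threshold < 1):
        raise ValueError("ratio_threshold must be in (0, 1)")
    out: list[ScaffoldChain] = []
    for chain in chains:
        weights = [j.w_total for j in chain.joins]
        cuts = _forward_cuts(weights, ratio_threshold)
        if both_directions:
            n = len(weights)
            rev = _forward_cuts(list(reversed(weights)), ratio_threshold)
            cuts |= {n - 1 - i for i in rev}
        if not cuts:
            out.append(chain)
            continue
        entries: list[tuple[str, str]] = []
        joins: list[LinkEdge] = []
        for i, e in enumerate(chain.entries):
            entries.append(e)
            if i < len(chain.joins):
                if i in cuts:
                    out.append(ScaffoldChain(entries=entries, joins=joins))
                    entries, joins = [], []
                else:
                    joins.append(chain.joins[i])
        out.append(ScaffoldChain(entries=entries, joins=joins))
    return out
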