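"""Weighted hypergraph over contigs and its pairwise projection.

Each grouped Pore-C read becomes one hyperedge joining every contig it
aligns to, weighted by the geometric mean of the per-contig aligned lengths
(a balanced summary that damps the influence of a single unusually long or
short alignment).  For clustering, hyperedges are projected onto an ordinary
weighted graph: every unordered contig pair inside a hyperedge receives the
full hyperedge weight, and the weights are summed over hyperedges.  A
percentile filter then removes the weakest pairwise links before community
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .alignment_io import PorecRead

__all__ = [
    "Hyperedge",
    "PairGraph",
    "hyperedge_weight",
    "build_hyperedges",
    "aggregate_pair_weights",
    "percentile_filter",
    "DEFAULT_PAIR_WEIGHT_PERCENTILE",
]

#: Pairwise edges below this percentile of the weight distribution are dropped.
DEFAULT_PAIR_WEIGHT_PERCENTILE = 10.0


@dataclass(frozen=True)
class Hyperedge:
    """One Pore-C read as a weighted multi-way link over >=2 contigs.

    ``members`` pairs each contig with the total aligned length of the
    read's fragments on that contig; ``weight`` is their geometric mean.
    """

    read_id: str
    members: tuple[tuple[str, int], ...]
    weight: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("hyperedge needs >=2 member contigs")
        if any(l < 1 for _, l in self.members):
            raise ValueError("member aligned lengths must be >=1")

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.members)


class PairGraph:
    """Undirected weighted contig graph (no self-loops at construction).

    Community aggregation may introduce self-weights; a stored self-weight
    is the sum of collapsed intra-community edge weights and contributes
    *twice* to the node's weighted degree, so that the total weight 2m is
    conserved by aggregation.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self._self: dict[str, float] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        if node not in self._adj:
            self._adj[node] = {}

    def add_edge_weight(self, a: str, b: str, w: float) -> None:
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        if a == b:
            self._self[a] = self._self.get(a, 0.0) + w
            self.add_node(a)
            return
        self.add_node(a)
        self.add_node(b)
        self._adj[a][b] = self._adj[a].get(b, 0.0) + w
        self._adj[b][a] = self._adj[b].get(a, 0.0) + w

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def has_node(self, node: str) -> bool:
        return node in self._adj

    def neighbors(self, node: str) -> dict[str, float]:
        return self._adj[node]

    def self_weight(self, node: str) -> float:
        return self._self.get(node, 0.0)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Each undirected edge once, (a, b, w) with a < b; no self-loops."""
        for a, nbrs in self._adj.items():
            for b, w in nbrs.items():
                if a < b:
                    yield a, b, w

    def edge_weight(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    @property
    def n_edges(self) -> int:
        return sum(len(n) for n in self._adj.values()) // 2

    def degree(self, node: str) -> float:
        """Weighted degree k_i; a self-weight counts twice."""
        return sum(self._adj[node].values()) + 2.0 * self._self.get(node, 0.0)

    @property
    def total_weight_2m(self) -> float:
        """2m = sum of all weighted degrees."""
        return sum(self.degree(n) for n in self._adj)

    @property
    def m(self) -> float:
        """Half the total edge weight sum."""
        return self.total_weight_2m / 2.0

    def copy(self) -> "PairGraph":
        g = PairGraph()
        for n in self._adj:
            g.add_node(n)
        for a, b, w in self.edges():
            g.add_edge_weight(a, b, w)
        for n, w in self._self.items():
            g.add_edge_weight(n, n, w)
        return g


def hyperedge_weight(lengths: Iterable[float]) -> float:
    """Geometric mean of per-contig aligned lengths, computed in log space.

    For a read covering n contigs with aligned lengths l_1..l_n the weight
    is (prod l_j)^(1/n); log-space evaluation avoids overflow for long
    concatemers.
    """
    ls = list(lengths)
    if not ls:
        raise ValueError("hyperedge_weight needs at least one length")
    if any(l <= 0 for l in ls):
        raise ValueError("aligned lengths must be positive")
    return math.exp(sum(math.log(l) for l in ls) / len(ls))


def build_hyperedges(reads: Iterable[PorecRead]) -> list[Hyperedge]:
    """Turn each grouped read into a hyperedge.

    Fragment lengths on the same contig within one read are summed first,
    giving a single per-contig aligned length; the hyperedge weight is the
    geometric mean of those sums.
    """
    edges: list[Hyperedge] = []
    for read in reads:
        per_contig: dict[str, int] = {}
        for frag in read.fragments:
            per_contig[frag.contig_id] = per_contig.get(frag.contig_id, 0) + frag.aligned_len
        members = tuple(sorted(per_contig.items()))
        edges.append(
            Hyperedge(
                read_id=read.read_id,
                members=members,
                weight=hyperedge_weight([l for _, l in members]),
            )
        )
    return edges


def aggregate_pair_weights(hyperedges: Iterable[Hyperedge]) -> PairGraph:
    """Project hyperedges to a pairwise graph (clique expansion).

    Every unordered pair of distinct contigs within a hyperedge receives the
    full hyperedge weight once; weights sum over hyperedges.  All member
    contigs become nodes even if they end up with no surviving edges.
    """
    g = PairGraph()
    for he in hyperedges:
        contigs = he.contig_ids
        for c in contigs:
            g.add_node(c)
        for i in range(len(contigs)):
            for j in range(i + 1, len(contigs)):
                g.add_edge_weight(contigs[i], contigs[j], he.weight)
    return g


def percentile_filter(
    graph: PairGraph, pct: float = DEFAULT_PAIR_WEIGHT_PERCENTILE
) -> PairGraph:
    """Drop edges whose weight falls strictly below the pct-th percentile.

    The threshold is the linear-interpolation percentile of the edge-weight
    multiset; edges with weight >= threshold are kept (so a uniform-weight
    graph is untouched), and the node set never shrinks.
    """
    if not (0 <= pct < 100):
        raise ValueError("pct must be in [0, 100)")
    edges = list(graph.edges())
    out = PairGraph()
    for n in graph.nodes:
        out.add_node(n)
    if not edges or pct == 0:
        for a, b, w in edges:
            out.add_edge_weight(a, b, w)
        return out
    threshold = float(np.percentile([w for _, _, w in edges], pct))
    for a, b, w in edges:
        if w >= threshold:
            out.add_edge_weight(a, b, w)
    return out
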