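"""Shared fixtures: boundary alignment records, synthetic datasets, oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from porec_scaffold.alignment_io import FragmentAlignment
from porec_scaffold.hypergraph import PairGraph
from porec_scaffold.pipeline import PipelineConfig, evaluate_layout, scaffold_from_fragments
from porec_scaffold.synthetic import default_fixture


def make_fragment(
    read_id="r1",
    contig_id="c1",
    start=0,
    length=500,
    mapq=60,
    strand="+",
    read_start=0,
):
    return FragmentAlignment(
        read_id=read_id,
        contig_id=contig_id,
        contig_start=start,
        contig_end=start + length,
        read_start=read_start,
        read_end=read_start + length,
        strand=strand,
        mapq=mapq,
    )


@pytest.fixture
def boundary_records():
    """Six records probing the filter boundaries by hand enumeration.

    r1 and r2 survive as multi-way reads; r3's records fall to the length
    (exactly 100 bp) and mapq (49) cuts and both sit on one contig.
    """
    return [
        make_fragment("r1", "c1", 0, 101, mapq=50),
        make_fragment("r1", "c2", 0, 200, mapq=60, read_start=101),
        make_fragment("r2", "c2", 100, 800, mapq=60),
        make_fragment("r2", "c3", 0, 700, mapq=60, read_start=800),
        make_fragment("r3", "c9", 0, 100, mapq=60),
        make_fragment("r3", "c9", 500, 5000, mapq=49, read_start=100),
    ]


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced-size dataset for fast pipeline-level tests."""
    genome, contigs, truth, frags = default_fixture(
        seed=5, chrom_len=300_000, mean_contig=30_000, n_reads=6_000
    )
    return genome, contigs, truth, frags


@pytest.fixture(scope="session")
def study_run():
    """Full pipeline on the study fixture (2 x 1 Mb, ~40 contigs, 20k reads)."""
    genome, contigs, truth, frags = default_fixture(seed=3)
    result = scaffold_from_fragments(
        {c: len(s) for c, s in contigs.items()}, frags, PipelineConfig()
    )
    scaffolds = [
        ([(c, o) for c, o in ch.entries], [j.gap for j in ch.joins])
        for ch in result.layout.scaffolds
    ]
    metrics = evaluate_layout(truth, scaffolds, result.partition)
    return dict(
        genome=genome,
        contigs=contigs,
        truth=truth,
        fragments=frags,
        result=result,
        metrics=metrics,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def modularity_oracle(nodes, edges, labels, gamma=1.0):
    """Direct ordered-pair evaluation of the modularity sum, from scratch.

    ``edges``: dict of unordered (a, b) -> weight, no self-loops.  Kept
    deliberately independent of the package's implementation.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for (a, b), wt in edges.items():
        w[idx[a], idx[b]] += wt
        w[idx[b], idx[a]] += wt
    k = w.sum(axis=1)
    two_m = k.sum()
    lab = np.array([labels[x] for x in nodes])
    q = 0.0
    for i in range(n):
        for j in range(n):
            if lab[i] == lab[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions via restricted-growth strings."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield {}
        return
    rgs = [0] * n

    def rec(i, maxv):
        if i == n:
            yield {items[j]: rgs[j] for j in range(n)}
            return
        for v in range(maxv + 2):
            rgs[i] = v
            yield from rec(i + 1, max(maxv, v))

    yield from rec(1, 0)


def brute_force_max_modularity(nodes, edges, gamma=1.0):
    """Exhaustive maximum of the modularity over all partitions (n <= 8)."""
    best = -np.inf
    best_labels = None
    for labels in set_partitions(nodes):
        q = modularity_oracle(nodes, edges, labels, gamma)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels


def random_weighted_graph(rng, n_nodes, p_edge=0.5):
    """Seeded random connected-ish weighted graph as (nodes, edges dict)."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges[(nodes[i], nodes[j])] = float(np.round(rng.uniform(0.1, 5.0), 3))
    if not edges:  # ensure at least one edge so 2m > 0
        edges[(nodes[0], nodes[1])] = 1.0
    return nodes, edges


def to_pair_graph(nodes, edges) -> PairGraph:
    g = PairGraph()
    for n in nodes:
        g.add_node(n)
    for (a, b), w in edges.items():
        g.add_edge_weight(a, b, w)
    return g
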