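"""Dual-weight accumulation over contig-end pairs."""

import itertools
import math
import random

import numpy as np
import pytest

from porec_scaffold.alignment_io import PorecRead
from porec_scaffold.link_weights import (
    EndRef,
    accumulate,
    cosine_weight,
    coverage_weight,
    observe_read,
    scale_params,
)
from porec_scaffold.terminal_bins import assign_bins, interval_bin_cover

from conftest import make_fragment


class TestWeightFormulas:
    @pytest.mark.parametrize(
        "ca,cb,alpha,expected",
        [(4, 1, 1.0, 2.0), (0, 5, 1.0, 0.0), (3, 3, 0.5, 1.5)],
    )
    def test_coverage_weight(self, ca, cb, alpha, expected):
        assert coverage_weight(ca, cb, alpha) == pytest.approx(expected)

    def test_cosine_identical_vectors_gives_beta(self):
        u = np.array([1, 1, 0, 0, 0])
        assert cosine_weight(u, u, 1.0) == pytest.approx(1.0)
        assert cosine_weight(u, u, 0.7) == pytest.approx(0.7)

    def test_cosine_orthogonal(self):
        assert cosine_weight(np.array([1, 0, 0, 0, 0]), np.array([0, 1, 0, 0, 0]), 1.0) == 0.0

    def test_cosine_partial_overlap(self):
        got = cosine_weight(np.array([1, 1, 0, 0, 0]), np.array([1, 0, 0, 0, 0]), 2.0)
        assert got == pytest.approx(2 / math.sqrt(2), rel=1e-9)

    def test_cosine_zero_vector_defined_as_zero(self):
        assert cosine_weight(np.zeros(5), np.ones(5), 1.0) == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ua = (rng.random(5) < 0.5).astype(int)
            ub = (rng.random(5) < 0.5).astype(int)
            assert 0.0 <= cosine_weight(ua, ub, 2.0) <= 2.0 + 1e-12
        assert coverage_weight(5, 5, 1.3) <= 5 * 1.3 + 1e-12


def layouts_for(lengths: dict, bin_size: int):
    return {c: assign_bins(l, bin_size, c) for c, l in lengths.items()}


class TestObserveRead:
    LENGTHS = {"c1": 12000, "c2": 12000}

    def test_tail_head_observation(self):
        layouts = layouts_for(self.LENGTHS, 1000)
        read = PorecRead(
            "r1",
            (
                make_fragment("r1", "c1", 10_500, 1400),  # covers 2 tail bins of c1
                make_fragment("r1", "c2", 0, 2100, read_start=1400),  # 3 head bins of c2
            ),
        )
        obs = observe_read(read, layouts)
        by_type = {(o.end_a.end, o.end_b.end): o for o in obs}
        th = by_type[("tail", "head")]
        assert (th.C_a, th.C_b) == (2, 3)

    def test_mid_contig_read_yields_nothing(self):
        layouts = layouts_for(self.LENGTHS, 1000)
        read = PorecRead(
            "r1",
            (
                make_fragment("r1", "c1", 6000, 300),
                make_fragment("r1", "c2", 5800, 300, read_start=300),
            ),
        )
        assert observe_read(read, layouts) == []

    def test_read_touching_both_ends_of_one_contig(self):
        layouts = layouts_for(self.LENGTHS, 1000)
        read = PorecRead(
            "r1",
            (
                make_fragment("r1", "c1", 0, 500),
                make_fragment("r1", "c1", 11_000, 500, read_start=500),
                make_fragment("r1", "c2", 0, 500, read_start=1000),
            ),
        )
        obs = observe_read(read, layouts)
        kinds = {(o.end_a, o.end_b) for o in obs}
        assert kinds == {
            (EndRef("c1", "head"), EndRef("c2", "head")),
            (EndRef("c1", "tail"), EndRef("c2", "head")),
        }

    def test_no_self_pairs(self):
        layouts = layouts_for({"c1": 12000}, 1000)
        read = PorecRead(
            "r1",
            (
                make_fragment("r1", "c1", 0, 500),
                make_fragment("r1", "c1", 11_500, 500, read_start=500),
            ),
        )
        assert observe_read(read, layouts) == []

    def test_vectors_are_or_over_fragments(self):
        layouts = layouts_for(self.LENGTHS, 1000)
        read = PorecRead(
            "r1",
            (
                make_fragment("r1", "c1", 0, 300),
                make_fragment("r1", "c1", 2000, 300, read_start=300),
                make_fragment("r1", "c2", 0, 300, read_start=600),
            ),
        )
        (hh,) = [o for o in observe_read(read, layouts) if o.end_a.end == "head"]
        assert hh.U_a.tolist() == [1, 0, 1, 0, 0]


def brute_force_accumulate(reads, lengths, bin_sizes, alpha, beta):
    """Independent triple loop: reads x scales x end-type pairs."""
    table: dict[tuple, list[float]] = {}
    for read in reads:
        for b in bin_sizes:
            layouts = layouts_for(lengths, b)
            vecs = {}
            for frag in read.fragments:
                lay = layouts[frag.contig_id]
                h = interval_bin_cover(frag.contig_start, frag.contig_end, lay.head_bins)
                t = interval_bin_cover(frag.contig_start, frag.contig_end, lay.tail_bins)
                if frag.contig_id in vecs:
                    vecs[frag.contig_id] = (
                        np.maximum(vecs[frag.contig_id][0], h),
                        np.maximum(vecs[frag.contig_id][1], t),
                    )
                else:
                    vecs[frag.contig_id] = (h, t)
            for ca, cb in itertools.combinations(sorted(vecs), 2):
                for ea, eb in itertools.product(("head", "tail"), repeat=2):
                    ua = vecs[ca][0 if ea == "head" else 1]
                    ub = vecs[cb][0 if eb == "head" else 1]
                    if ua.sum() == 0 or ub.sum() == 0:
                        continue
                    key = (EndRef(ca, ea), EndRef(cb, eb))
                    cov = math.sqrt(int(ua.sum()) * int(ub.sum())) * alpha[b]
                    sim = (
                        float(ua @ ub)
                        / (math.sqrt(float(ua @ ua)) * math.sqrt(float(ub @ ub)))
                        * beta[b]
                    )
                    entry = table.setdefault(key, [0.0, 0.0])
                    entry[0] += cov
                    entry[1] += sim
    return table


class TestAccumulate:
    def _simple_reads(self, n=2):
        reads = []
        for i in range(n):
            reads.append(
                PorecRead(
                    f"r{i}",
                    (
                        make_fragment(f"r{i}", "c1", 8200, 3700),  # 4 tail bins at B=1000
                        make_fragment(f"r{i}", "c2", 100, 3800, read_start=3700),  # 4 head bins
                    ),
                )
            )
        return reads

    def test_summation_over_reads(self):
        lengths = {"c1": 12000, "c2": 12000}
        layouts = {1000: layouts_for(lengths, 1000)}
        table = accumulate(self._simple_reads(2), layouts, {1000: 1.0}, {1000: 1.0})
        w = table.get(EndRef("c1", "tail"), EndRef("c2", "head"))
        assert w.w_cov == pytest.approx(8.0)  # two reads x sqrt(4*4)

    def test_scale_weighting(self):
        lengths = {"c1": 12000, "c2": 12000}
        layouts = {
            1000: layouts_for(lengths, 1000),
            1001: layouts_for(lengths, 1001),
        }
        table = accumulate(self._simple_reads(1), layouts, {1000: 1.0, 1001: 0.5}, {1000: 0.0, 1001: 0.0})
        w = table.get(EndRef("c1", "tail"), EndRef("c2", "head"))
        assert w.w_cov == pytest.approx(4.0 + 2.0)

    def test_absent_pair_is_none(self):
        lengths = {"c1": 12000, "c2": 12000}
        layouts = {1000: layouts_for(lengths, 1000)}
        table = accumulate(self._simple_reads(1), layouts, {1000: 1.0}, {1000: 1.0})
        assert table.get(EndRef("c1", "head"), EndRef("c2", "tail")) is None

    def test_symmetry_under_end_swap(self):
        lengths = {"c1": 12000, "c2": 12000}
        layouts = {1000: layouts_for(lengths, 1000)}
        table = accumulate(self._simple_reads(1), layouts, {1000: 1.0}, {1000: 1.0})
        a, b = EndRef("c1", "tail"), EndRef("c2", "head")
        assert table.get(a, b) is table.get(b, a)
        assert table.get(a, b).w_total == pytest.approx(
            table.get(a, b).w_cov + table.get(a, b).w_sim
        )

    def test_matches_brute_force_triple_loop(self):
        rng = random.Random(13)
        lengths = {f"c{i}": rng.randrange(3_000, 30_000) for i in range(5)}
        bin_sizes = (400, 1000, 5000)
        alpha, beta = scale_params(bin_sizes)
        reads = []
        for r in range(100):
            k = rng.randint(2, 4)
            frags = []
            pos = 0
            for contig in rng.sample(sorted(lengths), k):
                L = lengths[contig]
                start = rng.randrange(0, max(1, L - 600))
                flen = rng.randrange(150, 600)
                flen = min(flen, L - start)
                frags.append(
                    make_fragment(f"r{r}", contig, start, flen, read_start=pos)
                )
                pos += flen
            reads.append(PorecRead(f"r{r}", tuple(frags)))
        layouts = {b: layouts_for(lengths, b) for b in bin_sizes}
        table = accumulate(reads, layouts, alpha, beta)
        expected = brute_force_accumulate(reads, lengths, bin_sizes, alpha, beta)
        assert len(table) == len(expected)
        for key, (cov, sim) in expected.items():
            got = table.get(*key)
            assert got.w_cov == pytest.approx(cov, rel=1e-9)
            assert got.w_sim == pytest.approx(sim, rel=1e-9)

    def test_removing_a_read_never_increases_weights(self):
        lengths = {"c1": 12000, "c2": 12000}
        layouts = {1000: layouts_for(lengths, 1000)}
        reads = self._simple_reads(3)
        full = accumulate(reads, layouts, {1000: 1.0}, {1000: 1.0})
        fewer = accumulate(reads[:-1], layouts, {1000: 1.0}, {1000: 1.0})
        for (a, b), w in full.items():
            prev = fewer.get(a, b)
            assert prev is None or (
                prev.w_cov <= w.w_cov + 1e-12 and prev.w_sim <= w.w_sim + 1e-12
            )


def test_scale_params_split():
    alpha, beta = scale_params((400, 1000, 2000, 5000, 10000, 20000))
    assert alpha[400] == alpha[2000] == 1.0
    assert alpha[5000] == alpha[20000] == 0.5
    assert beta[400] == 1.0 and beta[20000] == 0.5
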