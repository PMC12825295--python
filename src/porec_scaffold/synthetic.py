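"""Ground-truth synthetic data: genome, fragmentation, Pore-C contacts.

The generator emulates the data a scaffolder sees: a multi-chromosome
genome is fragmented in silico into contigs with known order, orientation
and inter-contig gaps, and multi-fragment Pore-C reads are simulated whose
inter-fragment genomic distances follow a power-law contact decay
(P(d) ~ d^-xi).  Alignments are emitted directly in contig coordinates
(PAF), bypassing sequence-level read synthesis and the aligner: the tests
target the scaffolding math, not base-level alignment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .alignment_io import FragmentAlignment

__all__ = [
    "TruthContig",
    "TruthLayout",
    "simulate_genome",
    "fragment_genome",
    "simulate_porec",
    "sample_power_law",
    "write_paf",
    "default_fixture",
    "FIXTURE_DEFAULTS",
]

#: The "small" study fixture: desk-scale but large enough for stable
#: clustering, ordering and gap-fit statistics.
FIXTURE_DEFAULTS = dict(
    n_chrom=2,
    chrom_len=1_000_000,
    gc=0.5,
    mean_contig=50_000,
    gap_range=(100, 10_000),
    flip_prob=0.5,
    n_reads=20_000,
    decay_xi=1.0,
    frag_len=(200, 2_000),
    intra_chrom_prob=0.97,
)

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class TruthContig:
    """One contig's true placement on its source chromosome.

    ``orientation`` records how the contig sequence was emitted: '-' means
    the emitted sequence is the reverse complement of the chromosome
    segment.  ``gap_after`` is the true gap (bp) to the next contig on the
    chromosome, 0 for the last one.
    """

    contig_id: str
    chrom: str
    start: int
    length: int
    orientation: str
    gap_after: int

    @property
    def end(self) -> int:
        return self.start + self.length


class TruthLayout:
    """Per-chromosome ordered contig placements with gap truth."""

    def __init__(self, chroms: dict[str, list[TruthContig]]):
        self.chroms = chroms
        self._starts = {
            chrom: [c.start for c in contigs] for chrom, contigs in chroms.items()
        }

    def all_contigs(self) -> list[TruthContig]:
        return [c for contigs in self.chroms.values() for c in contigs]

    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length for c in self.all_contigs()}

    def chrom_of(self) -> dict[str, str]:
        return {c.contig_id: c.chrom for c in self.all_contigs()}

    def by_id(self) -> dict[str, TruthContig]:
        return {c.contig_id: c for c in self.all_contigs()}

    def adjacent_pairs(self) -> list[tuple[TruthContig, TruthContig, int]]:
        """(left, right, gap) for every truly adjacent pair."""
        out = []
        for contigs in self.chroms.values():
            for left, right in zip(contigs, contigs[1:]):
                out.append((left, right, left.gap_after))
        return out

    def locate(self, chrom: str, pos: int) -> TruthContig | None:
        """Contig containing genomic position ``pos``, or None if in a gap."""
        contigs = self.chroms.get(chrom)
        if not contigs:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        c = contigs[i]
        return c if pos < c.end else None

    # -- text round-trip ---------------------------------------------------
    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tcontig_id\tstart\tlength\torientation\tgap_after\n")
            for chrom in self.chroms:
                for c in self.chroms[chrom]:
                    fh.write(
                        f"{c.chrom}\t{c.contig_id}\t{c.start}\t{c.length}\t"
                        f"{c.orientation}\t{c.gap_after}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "TruthLayout":
        chroms: dict[str, list[TruthContig]] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 6:
                    continue
                chroms.setdefault(cols[0], []).append(
                    TruthContig(
                        contig_id=cols[1],
                        chrom=cols[0],
                        start=int(cols[2]),
                        length=int(cols[3]),
                        orientation=cols[4],
                        gap_after=int(cols[5]),
                    )
                )
        for contigs in chroms.values():
            contigs.sort(key=lambda c: c.start)
        return cls(chroms)


def simulate_genome(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    gc: float = 0.5,
    seed: int = 1,
) -> dict[str, str]:
    """Random i.i.d.-base chromosomes at the given GC fraction."""
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=chrom_len, p=p))
        for i in range(n_chrom)
    }


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def fragment_genome(
    genome: Mapping[str, str],
    mean_contig: int = 50_000,
    gap_range: tuple[int, int] = (100, 10_000),
    flip_prob: float = 0.5,
    seed: int = 1,
    min_contig: int = 5_000,
) -> tuple[dict[str, str], TruthLayout]:
    """Cut each chromosome into contigs with recorded order/orientation/gaps.

    Contig lengths have gamma jitter around ``mean_contig`` (shape 4, so a
    coefficient of variation of 0.5); gaps between consecutive contigs are
    log-uniform in ``gap_range``.  Each contig is independently emitted
    reverse-complemented with probability ``flip_prob``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gap_range
    contigs: dict[str, str] = {}
    chroms: dict[str, list[TruthContig]] = {}
    for chrom, seq in genome.items():
        chrom_len = len(seq)
        rows: list[TruthContig] = []
        pos = 0
        idx = 0
        while chrom_len - pos >= min_contig:
            length = int(rng.gamma(4.0, mean_contig / 4.0))
            length = max(min_contig, min(length, chrom_len - pos))
            gap = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))) if hi > lo else lo
            idx += 1
            cid = f"{chrom}_ctg{idx:03d}"
            orient = "-" if rng.random() < flip_prob else "+"
            segment = seq[pos : pos + length]
            contigs[cid] = _revcomp(segment) if orient == "-" else segment
            rows.append(
                TruthContig(
                    contig_id=cid,
                    chrom=chrom,
                    start=pos,
                    length=length,
                    orientation=orient,
                    gap_after=gap,
                )
            )
            pos += length + gap
        if rows:
            last = rows[-1]
            rows[-1] = TruthContig(  # no junction after the final contig
                last.contig_id, last.chrom, last.start, last.length, last.orientation, 0
            )
        chroms[chrom] = rows
    return contigs, TruthLayout(chroms)


def sample_power_law(rng: np.random.Generator, xi: float, lo: float, hi: float) -> float:
    """Draw a distance with density proportional to d^-xi on [lo, hi]."""
    u = rng.random()
    if abs(xi - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - xi
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def simulate_porec(
    truth: TruthLayout,
    chrom_lengths: Mapping[str, int],
    n_reads: int = 20_000,
    decay_xi: float = 1.0,
    frag_len: tuple[int, int] = (200, 2_000),
    intra_chrom_prob: float = 0.97,
    seed: int = 3,
    min_dist: int = 100,
    order_dist: Callable[[np.random.Generator], int] | None = None,
) -> list[FragmentAlignment]:
    """Simulate multi-way contact reads as fragment alignments.

    Per read: an anchor position is drawn (chromosome weighted by length),
    then the remaining fragment positions follow a random walk whose step
    sizes have power-law density d^-decay_xi, jumping to another chromosome
    with probability 1 - intra_chrom_prob.  Positions falling in
    inter-contig gaps are dropped; the rest are clipped to their contig and
    mapped through the recorded orientation into contig coordinates, with
    mapq 60.  Fragments-per-read defaults to uniform on {2..6} (pre-drop).
    """
    if decay_xi <= 0:
        raise ValueError("decay_xi must be positive")
    rng = np.random.default_rng(seed)
    if order_dist is None:
        order_dist = lambda r: int(r.integers(2, 7))
    chrom_names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = lens / lens.sum()
    flo, fhi = frag_len
    out: list[FragmentAlignment] = []
    for i in range(n_reads):
        read_id = f"read{i:06d}"
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        clen = chrom_lengths[chrom]
        pos = int(rng.integers(0, clen))
        k = order_dist(rng)
        sites: list[tuple[str, int]] = [(chrom, pos)]
        cur_chrom, cur_pos = chrom, pos
        for _ in range(k - 1):
            if len(chrom_names) > 1 and rng.random() > intra_chrom_prob:
                others = [c for c in chrom_names if c != cur_chrom]
                cur_chrom = others[int(rng.integers(0, len(others)))]
                cur_pos = int(rng.integers(0, chrom_lengths[cur_chrom]))
            else:
                cl = chrom_lengths[cur_chrom]
                placed = False
                for _attempt in range(10):
                    d = sample_power_law(rng, decay_xi, min_dist, cl)
                    sign = 1 if rng.random() < 0.5 else -1
                    cand = cur_pos + sign * int(round(d))
                    if 0 <= cand < cl:
                        cur_pos = cand
                        placed = True
                        break
                if not placed:
                    continue
            sites.append((cur_chrom, cur_pos))
        cursor = 0
        for site_chrom, site_pos in sites:
            flen = int(rng.integers(flo, fhi + 1))
            ctg = truth.locate(site_chrom, site_pos)
            if ctg is None:
                continue
            gstart = site_pos
            gend = min(site_pos + flen, ctg.end)
            if gend - gstart < 1:
                continue
            off_start = gstart - ctg.start
            off_end = gend - ctg.start
            if ctg.orientation == "+":
                cstart, cend, strand = off_start, off_end, "+"
            else:
                cstart, cend, strand = ctg.length - off_end, ctg.length - off_start, "-"
            out.append(
                FragmentAlignment(
                    read_id=read_id,
                    contig_id=ctg.contig_id,
                    contig_start=cstart,
                    contig_end=cend,
                    read_start=cursor,
                    read_end=cursor + (cend - cstart),
                    strand=strand,
                    mapq=60,
                )
            )
            cursor += cend - cstart
    return out


def write_paf(
    fragments: list[FragmentAlignment],
    contig_lengths: Mapping[str, int],
    path,
) -> None:
    """Emit fragments as minimally populated 12-column PAF."""
    read_len: dict[str, int] = {}
    for f in fragments:
        read_len[f.read_id] = max(read_len.get(f.read_id, 0), f.read_end)
    with open(path, "w") as fh:
        for f in fragments:
            cols = [
                f.read_id,
                str(read_len[f.read_id]),
                str(f.read_start),
                str(f.read_end),
                f.strand,
                f.contig_id,
                str(contig_lengths[f.contig_id]),
                str(f.contig_start),
                str(f.contig_end),
                str(f.aligned_len),
                str(f.aligned_len),
                str(f.mapq),
            ]
            fh.write("\t".join(cols) + "\n")


def default_fixture(
    seed: int = 3, **overrides
) -> tuple[dict[str, str], dict[str, str], TruthLayout, list[FragmentAlignment]]:
    """The study fixture: genome, contigs, truth layout and contact reads.

    All randomness derives from ``seed`` (genome and fragmentation use
    offsets so the three stages are independent streams).
    """
    params = dict(FIXTURE_DEFAULTS)
    params.update(overrides)
    genome = simulate_genome(
        n_chrom=params["n_chrom"],
        chrom_len=params["chrom_len"],
        gc=params["gc"],
        seed=seed,
    )
    contigs, truth = fragment_genome(
        genome,
        mean_contig=params["mean_contig"],
        gap_range=params["gap_range"],
        flip_prob=params["flip_prob"],
        seed=seed + 1,
    )
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    frags = simulate_porec(
        truth,
        chrom_lengths,
        n_reads=params["n_reads"],
        decay_xi=params["decay_xi"],
        frag_len=params["frag_len"],
        intra_chrom_prob=params["intra_chrom_prob"],
        seed=seed + 2,
    )
    return genome, contigs, truth, frags
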