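"""Dual link weights between contig ends.

For every pair of contig ends (four linking types per contig pair:
head-head, head-tail, tail-head, tail-tail) two complementary weights are
accumulated over all Pore-C reads and all bin scales:

* terminal coverage weight  w_cov = sqrt(C_a * C_b) * alpha, where C is the
  number of terminal bins covered by the read on that end — rewards deep
  coverage of both ends;
* cosine similarity weight  w_sim = cos(U_a, U_b) * beta, on the binary
  bin-coverage vectors — rewards matching coverage *patterns* and is the
  more orientation-specific signal.

Per-scale parameters alpha and beta let short bins (precise, sparse) count
more than long bins (sensitive, blurry).  The per-read values are summed
into totals W_cov, W_sim and W_total = W_cov + W_sim per end pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np

from .alignment_io import PorecRead
from .terminal_bins import BinLayout, DEFAULT_MIN_BIN_OVERLAP, interval_bin_cover

__all__ = [
    "EndRef",
    "CoverageObservation",
    "PairWeights",
    "LinkWeightTable",
    "coverage_weight",
    "cosine_weight",
    "observe_read",
    "accumulate",
    "scale_params",
    "DEFAULT_ALPHA_SHORT",
    "DEFAULT_ALPHA_LONG",
    "DEFAULT_BETA_SHORT",
    "DEFAULT_BETA_LONG",
    "DEFAULT_SHORT_BIN_MAX",
]

DEFAULT_ALPHA_SHORT = 1.0
DEFAULT_ALPHA_LONG = 0.5
DEFAULT_BETA_SHORT = 1.0
DEFAULT_BETA_LONG = 0.5
#: Bin sizes up to this (bp) use the "short" alpha/beta values.
DEFAULT_SHORT_BIN_MAX = 2000

HEAD = "head"
TAIL = "tail"


class EndRef(NamedTuple):
    """One of the two ends of a contig."""

    contig_id: str
    end: str  # "head" | "tail"


def _canonical(a: EndRef, b: EndRef) -> tuple[EndRef, EndRef]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CoverageObservation:
    """One read's simultaneous coverage of two contig ends at one scale."""

    read_id: str
    end_a: EndRef
    end_b: EndRef
    bin_size: int
    U_a: np.ndarray
    U_b: np.ndarray

    @property
    def C_a(self) -> int:
        return int(self.U_a.sum())

    @property
    def C_b(self) -> int:
        return int(self.U_b.sum())


def coverage_weight(C_a: int, C_b: int, alpha: float) -> float:
    """sqrt(C_a * C_b) * alpha."""
    return math.sqrt(C_a * C_b) * alpha


def cosine_weight(U_a: np.ndarray, U_b: np.ndarray, beta: float) -> float:
    """Cosine similarity of the two cover vectors, scaled by beta.

    Defined as 0 when either vector is all-zero.
    """
    na = float(np.dot(U_a, U_a))
    nb = float(np.dot(U_b, U_b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(U_a, U_b)) / math.sqrt(na * nb) * beta


@dataclass
class PairWeights:
    """Accumulated weights for one unordered end pair."""

    w_cov: float = 0.0
    w_sim: float = 0.0
    per_scale: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def w_total(self) -> float:
        return self.w_cov + self.w_sim

    def add(self, bin_size: int, cov: float, sim: float) -> None:
        self.w_cov += cov
        self.w_sim += sim
        pc, ps = self.per_scale.get(bin_size, (0.0, 0.0))
        self.per_scale[bin_size] = (pc + cov, ps + sim)


class LinkWeightTable:
    """Symmetric map (EndRef, EndRef) -> accumulated PairWeights."""

    def __init__(self) -> None:
        self._table: dict[tuple[EndRef, EndRef], PairWeights] = {}

    def get(self, a: EndRef, b: EndRef) -> PairWeights | None:
        return self._table.get(_canonical(a, b))

    def entry(self, a: EndRef, b: EndRef) -> PairWeights:
        return self._table.setdefault(_canonical(a, b), PairWeights())

    def items(self) -> Iterable[tuple[tuple[EndRef, EndRef], PairWeights]]:
        return self._table.items()

    def __len__(self) -> int:
        return len(self._table)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig_a\tend_a\tcontig_b\tend_b\tW_cov\tW_sim\tW_total\n")
            for (a, b), w in sorted(self._table.items()):
                fh.write(
                    f"{a.contig_id}\t{a.end}\t{b.contig_id}\t{b.end}\t"
                    f"{w.w_cov:.6f}\t{w.w_sim:.6f}\t{w.w_total:.6f}\n"
                )


def _read_end_vectors(
    read: PorecRead,
    layouts: Mapping[str, BinLayout],
    min_overlap: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per contig: OR of head / tail cover vectors over the read's fragments."""
    vecs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for frag in read.fragments:
        layout = layouts[frag.contig_id]
        head = interval_bin_cover(frag.contig_start, frag.contig_end, layout.head_bins, min_overlap)
        tail = interval_bin_cover(frag.contig_start, frag.contig_end, layout.tail_bins, min_overlap)
        if frag.contig_id in vecs:
            h, t = vecs[frag.contig_id]
            np.maximum(h, head, out=h)
            np.maximum(t, tail, out=t)
        else:
            vecs[frag.contig_id] = (head, tail)
    return vecs


def observe_read(
    read: PorecRead,
    layouts: Mapping[str, BinLayout],
    min_overlap: int = DEFAULT_MIN_BIN_OVERLAP,
) -> list[CoverageObservation]:
    """All end-pair observations of one read at one bin scale.

    For each unordered pair of distinct contigs in the read and each of the
    four linking types, an observation is emitted when the read covers at
    least one bin on both ends.  Self-pairs (two ends of the same contig)
    are never emitted.
    """
    vecs = _read_end_vectors(read, layouts, min_overlap)
    contigs = sorted(vecs)
    bin_size = layouts[contigs[0]].bin_size if contigs else 0
    out: list[CoverageObservation] = []
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            ca, cb = contigs[i], contigs[j]
            for end_a in (HEAD, TAIL):
                ua = vecs[ca][0] if end_a == HEAD else vecs[ca][1]
                if not ua.any():
                    continue
                for end_b in (HEAD, TAIL):
                    ub = vecs[cb][0] if end_b == HEAD else vecs[cb][1]
                    if not ub.any():
                        continue
                    out.append(
                        CoverageObservation(
                            read_id=read.read_id,
                            end_a=EndRef(ca, end_a),
                            end_b=EndRef(cb, end_b),
                            bin_size=bin_size,
                            U_a=ua,
                            U_b=ub,
                        )
                    )
    return out


def scale_params(
    bin_sizes: Iterable[int],
    alpha_short: float = DEFAULT_ALPHA_SHORT,
    alpha_long: float = DEFAULT_ALPHA_LONG,
    beta_short: float = DEFAULT_BETA_SHORT,
    beta_long: float = DEFAULT_BETA_LONG,
    short_bin_max: int = DEFAULT_SHORT_BIN_MAX,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-scale (alpha, beta) maps: short bins weigh more than long bins."""
    alpha = {b: (alpha_short if b <= short_bin_max else alpha_long) for b in bin_sizes}
    beta = {b: (beta_short if b <= short_bin_max else beta_long) for b in bin_sizes}
    return alpha, beta


def accumulate(
    reads: Iterable[PorecRead],
    layouts_by_scale: Mapping[int, Mapping[str, BinLayout]],
    alpha: Mapping[int, float],
    beta: Mapping[int, float],
    min_overlap: int = DEFAULT_MIN_BIN_OVERLAP,
    use_cov: bool = True,
    use_sim: bool = True,
) -> LinkWeightTable:
    """Sum both weights over all reads and bin scales into one table.

    ``use_cov`` / ``use_sim`` allow single-weight ablation runs; a disabled
    component accumulates as zero.
    """
    table = LinkWeightTable()
    for read in reads:
        for bin_size, layouts in layouts_by_scale.items():
            a = alpha[bin_size]
            b = beta[bin_size]
            for obs in observe_read(read, layouts, min_overlap):
                cov = coverage_weight(obs.C_a, obs.C_b, a) if use_cov else 0.0
                sim = cosine_weight(obs.U_a, obs.U_b, b) if use_sim else 0.0
                table.entry(obs.end_a, obs.end_b).add(bin_size, cov, sim)
    return table
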