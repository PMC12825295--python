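"""Fixed-width bins over contig terminal regions.

Only contacts near contig ends are informative for joining contigs, so each
contig's head (left) and tail (right) regions are tiled with five
consecutive bins of fixed width per bin scale.  Three cases:

1. length >= 10 bins: head and tail regions are disjoint;
2. 5 bins <= length < 10 bins: both regions are built the same way and
   overlap in the middle;
3. length < 5 bins: each region tiles the whole contig from its own end
   (final bin partial), padded with empty bins to five.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import FragmentAlignment

__all__ = [
    "BinLayout",
    "assign_bins",
    "fragment_bin_cover",
    "interval_bin_cover",
    "DEFAULT_BIN_SIZES",
    "DEFAULT_MIN_BIN_OVERLAP",
]

#: Multi-scale defaults: three short scales plus three long scales (bp).
DEFAULT_BIN_SIZES = (400, 1000, 2000, 5000, 10000, 20000)
#: A bin counts as covered when a fragment overlaps it by at least this many bp.
DEFAULT_MIN_BIN_OVERLAP = 1

N_BINS = 5


@dataclass(frozen=True)
class BinLayout:
    """Head and tail bin intervals of one contig at one bin scale.

    ``head_bins`` ascend from position 0; ``tail_bins`` are ordered
    outward-in (``tail_bins[0]`` is the rightmost).  Zero-width intervals
    are padding for contigs shorter than five bins and are never covered.
    """

    contig_id: str
    contig_length: int
    bin_size: int
    head_bins: tuple[tuple[int, int], ...]
    tail_bins: tuple[tuple[int, int], ...]


def assign_bins(contig_length: int, bin_size: int, contig_id: str = "") -> BinLayout:
    """Tile the two terminal regions of a contig into five bins each."""
    if contig_length < 1 or bin_size < 1:
        raise ValueError("contig_length and bin_size must be >= 1")
    L, B = contig_length, bin_size
    if L >= N_BINS * B:
        head = tuple((i * B, (i + 1) * B) for i in range(N_BINS))
        tail = tuple((L - (i + 1) * B, L - i * B) for i in range(N_BINS))
    else:
        head_list: list[tuple[int, int]] = []
        start = 0
        while start < L and len(head_list) < N_BINS:
            head_list.append((start, min(start + B, L)))
            start += B
        while len(head_list) < N_BINS:
            head_list.append((L, L))
        tail_list: list[tuple[int, int]] = []
        end = L
        while end > 0 and len(tail_list) < N_BINS:
            tail_list.append((max(end - B, 0), end))
            end -= B
        while len(tail_list) < N_BINS:
            tail_list.append((0, 0))
        head, tail = tuple(head_list), tuple(tail_list)
    return BinLayout(
        contig_id=contig_id,
        contig_length=L,
        bin_size=B,
        head_bins=head,
        tail_bins=tail,
    )


def interval_bin_cover(
    start: int,
    end: int,
    bins: tuple[tuple[int, int], ...],
    min_overlap: int = DEFAULT_MIN_BIN_OVERLAP,
) -> np.ndarray:
    """Binary cover vector of a [start, end) interval over five bins."""
    out = np.zeros(len(bins), dtype=np.int8)
    for i, (bs, be) in enumerate(bins):
        if be > bs and min(end, be) - max(start, bs) >= min_overlap:
            out[i] = 1
    return out


def fragment_bin_cover(
    fragment: FragmentAlignment,
    layout: BinLayout,
    min_overlap: int = DEFAULT_MIN_BIN_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Head and tail coverage vectors (binary, length 5) for one fragment."""
    if fragment.contig_id != layout.contig_id:
        raise ValueError(
            f"fragment on {fragment.contig_id!r} scored against layout of {layout.contig_id!r}"
        )
    head = interval_bin_cover(fragment.contig_start, fragment.contig_end, layout.head_bins, min_overlap)
    tail = interval_bin_cover(fragment.contig_start, fragment.contig_end, layout.tail_bins, min_overlap)
    return head, tail
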