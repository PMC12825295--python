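"""Power-law gap estimation from join weights.

Chromatin contact frequency decays with genomic distance, so the summed
link weight between two truly adjacent contigs carries information about
the gap separating them:

    W_total = s * gap^(-xi)

Taking base-10 logs gives a line, log10(W) = -xi * log10(gap) + log10(s),
fitted by ordinary least squares on training pairs with known gaps (a
reference genome fragmented in silico).  Prediction inverts the law:
gap = (s / W_total)^(1/xi), rounded and clamped to a sane range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .alignment_io import PorecRead
from .link_weights import (
    EndRef,
    HEAD,
    TAIL,
    LinkWeightTable,
)

__all__ = [
    "GapModel",
    "GapTrainingPair",
    "fit_gap_model",
    "predict_gap",
    "make_training_pairs",
    "DEFAULT_MIN_GAP",
    "DEFAULT_MAX_GAP",
    "DEFAULT_FIXED_GAP",
]

#: Predicted gaps are clamped to [DEFAULT_MIN_GAP, DEFAULT_MAX_GAP] bp.
DEFAULT_MIN_GAP = 10
DEFAULT_MAX_GAP = 1_000_000
#: Joins without usable weight (or without a usable model) get this gap.
DEFAULT_FIXED_GAP = 500


@dataclass(frozen=True)
class GapModel:
    """Fitted power-law parameters: intercept s (natural scale), decay xi."""

    s: float
    xi: float

    @property
    def usable(self) -> bool:
        return self.s > 0 and self.xi > 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"s={self.s!r}\nxi={self.xi!r}\n")

    @classmethod
    def from_file(cls, path) -> "GapModel":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                values[key.strip()] = float(val)
        return cls(s=values["s"], xi=values["xi"])


@dataclass(frozen=True)
class GapTrainingPair:
    """One adjacent contig pair with known gap and measured total weight."""

    true_gap: int
    w_total: float

    def __post_init__(self) -> None:
        if self.true_gap <= 0 or self.w_total <= 0:
            raise ValueError("training pairs need strictly positive gap and weight")


def fit_gap_model(pairs: Iterable[GapTrainingPair]) -> GapModel:
    """OLS fit of log10(W_total) on log10(gap).

    The slope estimates -xi and the intercept log10(s).  Requires at least
    three pairs with at least two distinct gap values.  A non-positive
    fitted xi is returned with a warning; callers should fall back to a
    fixed gap when ``model.usable`` is False.
    """
    ps = list(pairs)
    if len(ps) < 3:
        raise ValueError("need at least 3 training pairs")
    gaps = np.array([p.true_gap for p in ps], dtype=float)
    ws = np.array([p.w_total for p in ps], dtype=float)
    if np.unique(gaps).size < 2:
        raise ValueError("all training gaps identical: slope is unidentifiable")
    x = np.log10(gaps)
    y = np.log10(ws)
    slope, intercept = np.polyfit(x, y, 1)
    model = GapModel(s=float(10.0**intercept), xi=float(-slope))
    if model.xi <= 0:
        warnings.warn(
            "fitted decay exponent is non-positive; weight does not decrease "
            "with gap — falling back to fixed gaps is advised",
            stacklevel=2,
        )
    return model


def predict_gap(
    w_total: float,
    model: GapModel,
    min_gap: int = DEFAULT_MIN_GAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> int:
    """Invert the power law: gap = (s / W_total)^(1/xi), rounded and clamped."""
    if w_total <= 0:
        raise ValueError("predict_gap requires W_total > 0")
    if not model.usable:
        raise ValueError("gap model is unusable (non-positive s or xi)")
    gap = (model.s / w_total) ** (1.0 / model.xi)
    return int(min(max(round(gap), min_gap), max_gap))


def make_training_pairs(
    truth,
    reads: Iterable[PorecRead],
    contig_lengths: Mapping[str, int],
    bin_sizes: Iterable[int] | None = None,
    min_bin_overlap: int | None = None,
    alpha: Mapping[int, float] | None = None,
    beta: Mapping[int, float] | None = None,
) -> list[GapTrainingPair]:
    """Training pairs from a fragmented reference with recorded gaps.

    ``truth`` is a :class:`~porec_scaffold.synthetic.TruthLayout` describing
    the in-silico fragmentation (contig order, emitted orientations and true
    gaps); ``reads`` are grouped fragment alignments against those contigs.
    The total weight for each truly adjacent pair is measured on the facing
    contig ends (accounting for emitted orientations) with the same
    machinery the scaffolder uses.  Pairs with zero weight are excluded.
    """
    from .link_weights import accumulate, scale_params
    from .terminal_bins import DEFAULT_BIN_SIZES, DEFAULT_MIN_BIN_OVERLAP, assign_bins

    bin_sizes = tuple(bin_sizes) if bin_sizes is not None else DEFAULT_BIN_SIZES
    if min_bin_overlap is None:
        min_bin_overlap = DEFAULT_MIN_BIN_OVERLAP
    if alpha is None or beta is None:
        a_def, b_def = scale_params(bin_sizes)
        alpha = alpha if alpha is not None else a_def
        beta = beta if beta is not None else b_def
    layouts_by_scale = {
        b: {c: assign_bins(l, b, c) for c, l in contig_lengths.items()} for b in bin_sizes
    }
    table = accumulate(reads, layouts_by_scale, alpha, beta, min_bin_overlap)

    pairs: list[GapTrainingPair] = []
    for left, right, gap in truth.adjacent_pairs():
        if gap <= 0:
            continue
        # the end of each emitted contig that faces the junction
        end_left = EndRef(left.contig_id, TAIL if left.orientation == "+" else HEAD)
        end_right = EndRef(right.contig_id, HEAD if right.orientation == "+" else TAIL)
        w = table.get(end_left, end_right)
        if w is not None and w.w_total > 0:
            pairs.append(GapTrainingPair(true_gap=gap, w_total=w.w_total))
    if not pairs:
        raise ValueError(
            "no adjacent pair received positive weight; increase read coverage"
        )
    return pairs
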