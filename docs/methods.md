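# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `porec-scaffold`, and what the synthetic tests do and do
not demonstrate.

## Data model and filtering

A Pore-C read is treated as an unordered set of fragment alignments; the
read order of fragments is kept only for bookkeeping.  Aligned length is
measured on the contig interval (`contig_end − contig_start`), not on the
read, since the contig span is what matters for terminal-bin coverage.
Filters: aligned length strictly greater than 100 bp, mapq at least 50
(both exposed as `--min-align-len` / `--min-mapq`).  Reads whose fragments
all map to one contig carry no inter-contig information and are dropped;
multiple fragments of one read on the same contig are all retained because
they contribute to bin coverage, and distinctness is judged on the contig
set only.

## Hyperedge weighting and pairwise projection

Per read, fragment lengths are summed per contig before taking the
geometric mean, so each contig contributes a single aligned-length term.
The geometric mean is computed in log space to stay finite for long
concatemers.  Projection to the pairwise graph gives every unordered
contig pair inside a hyperedge the full hyperedge weight (no division by
the number of pairs): the projection sentence defines plain summation and
any normalization would change the clustering scale of Louvain only
globally.  The 10 % edge filter is a *value* percentile (linear
interpolation, as `numpy.percentile`) with ties kept (`w ≥ t` survives);
the alternative reading — dropping the lowest 10 % of edges by count —
differs only at ties.  Isolated contigs stay in the node set and become
singleton clusters rather than disappearing from the assembly.

## Louvain clustering

The local-move gain is implemented exactly as specified for this method:

```
dQ(i→C) = [(Σ_in + k_i,in)/2m − γ((Σ_tot + k_i)/2m)²] − [Σ_in/2m − γ(Σ_tot/2m)²]
```

This differs from the textbook Blondel gain (which doubles `k_i,in` and
removes the isolated node's own expected-degree term); the textbook
variant is available behind `--canonical-gain` for comparison.  One
observable consequence of the default gain: two nodes joined by a single
unit edge are *not* merged (the gain is −0.25 in either direction), where
canonical Louvain would merge them.  Since both brackets share `Σ_in`, the
gain is independent of whether intra-community weight is counted once or
twice; the implementation exploits the algebraic reduction
`k_i,in/2m − γ·k_i(2Σ_tot + k_i)/(2m)²` and the tests verify it against
direct evaluation of the two-bracket form.

Node sweeps use a Fisher–Yates shuffle from a seeded generator (default
seed 42), reshuffled every sweep; equal gains break toward the lowest
community label, making runs reproducible.  Moves need a net gain of at
least 1e−6.  Aggregation stores each community's intra-weight as a
self-weight that counts twice in the aggregated node's degree, which
conserves the total weight 2m across levels and makes the level-graph
quality equal the flat-partition modularity on the original graph — the
termination test (`ΔQ < 1e−6` between levels, community count stable, or
50 levels) is therefore well defined on either view.  Bookkeeping
(`Σ_in`, `Σ_tot`) is validated against from-scratch recomputation at
1e−9 in the test suite, and the final quality is checked against an
exhaustive partition-enumeration oracle on all graphs with ≤ 8 nodes.

## Terminal bins and dual weights

Five bins per terminal region, per scale.  Contigs at least ten bins long
get disjoint head/tail regions; between five and ten bins the two regions
overlap; shorter contigs are tiled from each end with a final partial bin
and padded to five with empty (never-covered) bins — this generalizes the
printed 2.5-bin example and degrades gracefully.  Equality cases (exactly
10 or exactly 5 bins) use the full-window construction.  A bin counts as
covered at ≥ 1 bp overlap (`--min-bin-overlap`); coverage is binary, not
length-normalized, because the cosine weight is meant to compare coverage
*patterns*, not depths.

Bin scales default to 400/1000/2000 bp (short) and 5/10/20 kb (long).
Short bins are precise but sparse; long bins are sensitive but blurry.  The
scale parameters default to α = β = 1.0 for short and 0.5 for long scales
(`--alpha-short` etc.), implementing "short bins count more"; the exact
values are a package choice.  Where terminal regions overlap, one fragment
may legitimately appear in several end-type observations; all are counted.
Both ends of the same contig are never weighted against each other — the
internal edge of the end graph represents that relation.

The linking thresholds (15 for cosine, 10 for coverage) apply to the
scale-summed weights, i.e. after accumulation over all reads and scales.

## Ordering, orientation, chain breaking

Greedy two-stage insertion: cosine-weight candidates first (they carry the
sharper orientation signal), then coverage-weight candidates among the
still-free ends; stage-1 links are never displaced.  Degree counts the
internal edge, so each contig end accepts at most one link; acyclicity is
enforced with union–find.  Candidate ties break lexicographically on
(contig, end) for determinism.  Chains are walked from the endpoint with
the lexicographically smaller contig id; orientation is `+` when the walk
enters a contig at its head.  Ratio breaking walks each chain in that
canonical direction and cuts a join whose total weight falls below
`--break-ratio` (default 0.1) times the previous join's; a cut resets the
comparison.  `--break-both-directions` additionally applies the test to
the reverse walk, which catches a weak *first* join that the forward walk
cannot see.

## Gap model

`W_total = s·gap^(−ξ)` is fitted as `log10 W = −ξ·log10 gap + log10 s`
by OLS (`numpy.polyfit`, verified against closed-form normal equations at
1e−12).  Prediction inverts the law and clamps to [10 bp, 1 Mb]; joins
with zero weight or an unusable model (ξ ≤ 0) get the fixed default of
500 bp.  Training pairs come from an in-silico fragmented reference with
recorded gaps; pairs with zero weight or zero gap are excluded.

Shipped defaults `s = 1401.17`, `ξ = 0.1418` are the pooled fit over four
wide-gap training simulations of the package's own generator.  A known
limitation, visible in those numbers: summing bin-scale weights over
terminal windows that are much wider than the gaps flattens the weight–gap
relation (a simulated contact decay of ξ_contact = 1.0 yields a weight
decay of only ≈ 0.14; restricting to the short scales roughly doubles it).
Inverting such a shallow law amplifies weight noise by `1/ξ` in the
exponent, so per-join gap errors are large even when ordering and
orientation are correct.  The fit machinery itself is exact: on data that
follow the law it recovers (s, ξ) to 1e−9, and to ±0.05 under 0.1-dex
log-normal noise.  More expressive gap models are out of scope.

## Synthetic data generator

The generator emulates exactly what the scaffolder consumes: chromosomes
of i.i.d. bases, fragmentation with gamma-jittered contig lengths
(shape 4 → CV 0.5), log-uniform gaps, independent 50 % reverse-complement
flips, and multi-way reads whose fragment positions follow a random walk
with power-law step density `d^(−ξ)` (default ξ = 1.0, minimum step
100 bp), 3 % inter-chromosome jumps, fragment lengths uniform in
200–2000 bp, mapq 60.  Fragments landing in gaps are dropped; the rest are
clipped to their contig and mapped through the recorded flip.  The default
study fixture is 2 × 1 Mb chromosomes, ~40 contigs of mean 50 kb, gaps in
100 bp – 10 kb, and 20,000 reads — small enough to run the whole pipeline
in seconds yet large enough for stable clustering and ordering statistics.

What the generator does **not** model: base-level sequencing error,
chimeric concatemer artifacts, restriction-digest boundaries, repeat- or
mappability-driven alignment ambiguity, and copy-number structure.
Passing the synthetic recovery tests therefore demonstrates the
correctness of the graph/weight/ordering machinery under the stated
contact model, not robustness to real-data alignment noise; the quality
filters and percentile/threshold knobs exist precisely for the latter and
are exercised only at their boundary semantics here.

## Problem sizes used in tests

Unit and property tests run on hand-sized graphs (≤ 8 nodes for the
exhaustive modularity oracle, ≤ 100 reads for brute-force weight
recounts).  Pipeline-level tests use a reduced fixture (2 × 300 kb,
6000 reads); the acceptance checks use the full study fixture above.  The
complete suite runs in well under a minute on one CPU.
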