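"""End-to-end scaffolding pipeline and truth-based evaluation.

Wires the four stages together: (1) hypergraph construction from filtered
multi-way alignments, (2) Louvain clustering of the pairwise projection,
(3) per-cluster dual-weight ordering/orientation with chain breaking, and
(4) power-law gap estimation.  Also provides evaluation of an assembly
against a known synthetic truth layout (adjacency precision/recall,
orientation accuracy, cluster purity, gap error).
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import alignment_io, assembly_io, gap_model, hypergraph, link_weights, louvain
from . import scaffold_builder, terminal_bins
from .alignment_io import FragmentAlignment, PorecRead
from .assembly_io import AssemblyLayout
from .gap_model import GapModel
from .louvain import Partition
from .scaffold_builder import ScaffoldChain
from .synthetic import TruthLayout

__all__ = [
    "PipelineConfig",
    "ScaffoldResult",
    "scaffold_from_fragments",
    "run_scaffold",
    "evaluate_layout",
    "evaluate_files",
    "DEFAULT_GAP_S",
    "DEFAULT_GAP_XI",
]

#: Shipped gap-model parameters, obtained by fitting the power-law decay on
#: the package's default simulation recipe (see docs/methods.md); override
#: with --gap-s / --gap-xi or a model file for real data.
DEFAULT_GAP_S = 1401.17
DEFAULT_GAP_XI = 0.1418


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their defaults."""

    min_align_len: int = alignment_io.DEFAULT_MIN_ALIGN_LEN
    min_mapq: int = alignment_io.DEFAULT_MIN_MAPQ
    pair_weight_percentile: float = hypergraph.DEFAULT_PAIR_WEIGHT_PERCENTILE
    resolution: float = louvain.DEFAULT_RESOLUTION
    seed: int = louvain.DEFAULT_SEED
    max_levels: int = louvain.DEFAULT_MAX_LEVELS
    canonical_gain: bool = False
    no_cluster: bool = False
    bin_sizes: tuple[int, ...] = terminal_bins.DEFAULT_BIN_SIZES
    min_bin_overlap: int = terminal_bins.DEFAULT_MIN_BIN_OVERLAP
    alpha_short: float = link_weights.DEFAULT_ALPHA_SHORT
    alpha_long: float = link_weights.DEFAULT_ALPHA_LONG
    beta_short: float = link_weights.DEFAULT_BETA_SHORT
    beta_long: float = link_weights.DEFAULT_BETA_LONG
    short_bin_max: int = link_weights.DEFAULT_SHORT_BIN_MAX
    weights: str = "both"  # "sim" | "cov" | "both"
    sim_threshold: float = scaffold_builder.DEFAULT_SIM_THRESHOLD
    cov_threshold: float = scaffold_builder.DEFAULT_COV_THRESHOLD
    break_ratio: float = scaffold_builder.DEFAULT_BREAK_RATIO
    break_both_directions: bool = False
    gap_s: float = DEFAULT_GAP_S
    gap_xi: float = DEFAULT_GAP_XI
    fixed_gap: int | None = None
    min_gap: int = gap_model.DEFAULT_MIN_GAP
    max_gap: int = gap_model.DEFAULT_MAX_GAP
    default_gap: int = gap_model.DEFAULT_FIXED_GAP

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                raw[k.strip()] = v.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "bin_sizes":
                kwargs[f.name] = tuple(int(x) for x in v.split(",") if x)
            elif f.type in ("bool",):
                kwargs[f.name] = v in ("True", "true", "1")
            elif f.name == "fixed_gap":
                kwargs[f.name] = None if v == "None" else int(v)
            elif f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class ScaffoldResult:
    """Everything the pipeline produced, pre-serialization."""

    layout: AssemblyLayout
    partition: Partition
    table: link_weights.LinkWeightTable
    reads: list[PorecRead]
    counts: dict[str, int] = field(default_factory=dict)


def _log(msg: str, log) -> None:
    if log is not None:
        print(msg, file=log)


def scaffold_from_fragments(
    contig_lengths: Mapping[str, int],
    fragments: Iterable[FragmentAlignment],
    config: PipelineConfig | None = None,
    log=None,
) -> ScaffoldResult:
    """Run the full pipeline on in-memory fragment alignments."""
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    # stage 1: filter, group, hypergraph
    frags = list(
        alignment_io.filter_alignments(fragments, cfg.min_align_len, cfg.min_mapq)
    )
    counts["fragments_kept"] = len(frags)
    reads = alignment_io.group_reads(frags)
    counts["reads_multiway"] = len(reads)
    hyperedges = hypergraph.build_hyperedges(reads)
    counts["hyperedges"] = len(hyperedges)
    graph = hypergraph.aggregate_pair_weights(hyperedges)
    for contig in contig_lengths:  # contigs without contacts stay in play
        graph.add_node(contig)
    counts["pair_edges"] = graph.n_edges
    graph = hypergraph.percentile_filter(graph, cfg.pair_weight_percentile)
    counts["pair_edges_kept"] = graph.n_edges
    _log(
        f"[1] {counts['fragments_kept']} fragments, {counts['reads_multiway']} multi-way reads, "
        f"{counts['hyperedges']} hyperedges, {counts['pair_edges_kept']}/{counts['pair_edges']} pair edges kept",
        log,
    )

    # stage 2: clustering
    if cfg.no_cluster:
        partition = Partition({c: 0 for c in sorted(contig_lengths)})
    else:
        partition = louvain.louvain_cluster(
            graph,
            gamma=cfg.resolution,
            seed=cfg.seed,
            max_levels=cfg.max_levels,
            canonical_gain=cfg.canonical_gain,
        )
    counts["clusters"] = partition.n_communities
    _log(f"[2] {counts['clusters']} clusters", log)

    # stage 3: dual-weight ordering and orientation
    layouts_by_scale = {
        b: {c: terminal_bins.assign_bins(l, b, c) for c, l in contig_lengths.items()}
        for b in cfg.bin_sizes
    }
    alpha, beta = link_weights.scale_params(
        cfg.bin_sizes,
        cfg.alpha_short,
        cfg.alpha_long,
        cfg.beta_short,
        cfg.beta_long,
        cfg.short_bin_max,
    )
    table = link_weights.accumulate(
        reads,
        layouts_by_scale,
        alpha,
        beta,
        cfg.min_bin_overlap,
        use_cov=cfg.weights in ("cov", "both"),
        use_sim=cfg.weights in ("sim", "both"),
    )
    counts["end_pairs"] = len(table)
    chains: list[ScaffoldChain] = []
    links = 0
    for com, members in sorted(partition.communities().items()):
        graph_e = scaffold_builder.order_and_orient(
            sorted(members), table, cfg.sim_threshold, cfg.cov_threshold
        )
        links += len(graph_e.links) // 2
        chains.extend(scaffold_builder.extract_chains(graph_e))
    counts["links"] = links
    chains = scaffold_builder.break_chains(
        chains, cfg.break_ratio, cfg.break_both_directions
    )
    counts["chains"] = len(chains)
    counts["breaks"] = len(chains) - (len(contig_lengths) - links)
    _log(
        f"[3] {counts['end_pairs']} weighted end pairs, {links} links, "
        f"{counts['breaks']} ratio breaks, {counts['chains']} chains",
        log,
    )

    # stage 4: gap estimation
    model = GapModel(s=cfg.gap_s, xi=cfg.gap_xi)
    for chain in chains:
        for join in chain.joins:
            if cfg.fixed_gap is not None:
                join.gap = int(cfg.fixed_gap)
            elif model.usable and join.w_total > 0:
                join.gap = gap_model.predict_gap(
                    join.w_total, model, cfg.min_gap, cfg.max_gap
                )
            else:
                join.gap = cfg.default_gap
    _log("[4] gaps estimated", log)

    return ScaffoldResult(
        layout=AssemblyLayout(scaffolds=chains),
        partition=partition,
        table=table,
        reads=reads,
        counts=counts,
    )


def write_clusters_tsv(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tcluster_id\n")
        for contig in sorted(partition.assignment):
            fh.write(f"{contig}\t{partition.assignment[contig]}\n")


def read_clusters_tsv(path) -> Partition:
    assignment: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 2:
                assignment[cols[0]] = int(cols[1])
    return Partition(assignment)


def run_scaffold(
    contig_fasta,
    alignments_path,
    outdir,
    config: PipelineConfig | None = None,
    log=sys.stderr,
) -> ScaffoldResult:
    """File-level pipeline entry: reads inputs, writes all outputs.

    Outputs in ``outdir``: scaffolds.fasta, scaffolds.agp, clusters.tsv,
    weights.tsv, config.txt.
    """
    import os

    cfg = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    seqs = assembly_io.read_fasta(contig_fasta)
    fragments = alignment_io.parse_alignments(alignments_path)
    result = scaffold_from_fragments(
        {c: len(s) for c, s in seqs.items()}, fragments, cfg, log=log
    )
    cfg.to_file(os.path.join(outdir, "config.txt"))
    write_clusters_tsv(result.partition, os.path.join(outdir, "clusters.tsv"))
    result.table.write_tsv(os.path.join(outdir, "weights.tsv"))
    assembly_io.write_scaffolds(
        result.layout,
        seqs,
        os.path.join(outdir, "scaffolds.fasta"),
        os.path.join(outdir, "scaffolds.agp"),
    )
    _log(f"wrote outputs to {outdir}", log)
    return result


# ---------------------------------------------------------------------------
# evaluation against synthetic truth
# ---------------------------------------------------------------------------


def _scaffolds_from_agp(agp_path) -> list[tuple[list[tuple[str, str]], list[int]]]:
    """Per scaffold: ordered [(contig, orient)] and per-join gap lengths."""
    scaffolds: dict[str, list[tuple[str, str]]] = {}
    gaps: dict[str, list[int]] = {}
    pending_gap: dict[str, int] = {}
    for row in assembly_io.parse_agp(agp_path):
        if row.kind == "W":
            lst = scaffolds.setdefault(row.obj, [])
            if lst:  # a join precedes this contig
                gaps.setdefault(row.obj, []).append(pending_gap.pop(row.obj, 0))
            lst.append((row.component_id, row.orientation))
        else:
            pending_gap[row.obj] = row.gap_length or 0
    return [(scaffolds[o], gaps.get(o, [])) for o in scaffolds]


def evaluate_layout(
    truth: TruthLayout,
    scaffolds: Sequence[tuple[list[tuple[str, str]], list[int]]],
    clusters: Partition | None = None,
) -> dict[str, float | None]:
    """Score an assembly against the synthetic ground truth.

    Reports adjacency precision (fraction of joins connecting truly
    adjacent contigs) and recall, orientation accuracy over correct joins
    (does the join locally reconstruct the chromosome, up to reversal),
    cluster purity (majority-chromosome fraction; minimum and contig-
    weighted overall), and the mean absolute gap error on correct joins.
    """
    by_id = truth.by_id()
    for entries, _ in scaffolds:
        for contig, _o in entries:
            if contig not in by_id:
                raise ValueError(f"contig {contig!r} not present in truth layout")
    true_adjacent: dict[frozenset[str], int] = {}
    for left, right, gap in truth.adjacent_pairs():
        true_adjacent[frozenset((left.contig_id, right.contig_id))] = gap

    n_joins = 0
    n_correct = 0
    n_orient_ok = 0
    gap_abs_err: list[float] = []
    for entries, join_gaps in scaffolds:
        for i in range(len(entries) - 1):
            (ca, oa), (cb, ob) = entries[i], entries[i + 1]
            n_joins += 1
            key = frozenset((ca, cb))
            if key not in true_adjacent:
                continue
            n_correct += 1
            ta, tb = by_id[ca], by_id[cb]
            if ta.start <= tb.start:  # ca is the left contig on the chromosome
                orient_ok = (oa == ta.orientation) and (ob == tb.orientation)
            else:
                orient_ok = (oa != ta.orientation) and (ob != tb.orientation)
            if orient_ok:
                n_orient_ok += 1
            pred_gap = join_gaps[i] if i < len(join_gaps) else 0
            gap_abs_err.append(abs(pred_gap - true_adjacent[key]))

    metrics: dict[str, float | None] = {
        "n_joins": float(n_joins),
        "n_correct_joins": float(n_correct),
        "adjacency_precision": (n_correct / n_joins) if n_joins else None,
        "adjacency_recall": (n_correct / len(true_adjacent)) if true_adjacent else None,
        "orientation_accuracy": (n_orient_ok / n_correct) if n_correct else None,
        "gap_mae": (sum(gap_abs_err) / len(gap_abs_err)) if gap_abs_err else None,
    }

    if clusters is not None:
        chrom_of = truth.chrom_of()
        purities: list[tuple[float, int]] = []
        for com, members in clusters.communities().items():
            tally: dict[str, int] = {}
            for c in members:
                tally[chrom_of[c]] = tally.get(chrom_of[c], 0) + 1
            purities.append((max(tally.values()) / len(members), len(members)))
        metrics["min_cluster_purity"] = min(p for p, _ in purities)
        total = sum(n for _, n in purities)
        metrics["overall_cluster_purity"] = sum(p * n for p, n in purities) / total
        metrics["n_clusters"] = float(len(purities))
    return metrics


def evaluate_files(truth_tsv, agp_path, clusters_tsv=None) -> dict[str, float | None]:
    truth = TruthLayout.read_tsv(truth_tsv)
    scaffolds = _scaffolds_from_agp(agp_path)
    clusters = read_clusters_tsv(clusters_tsv) if clusters_tsv else None
    return evaluate_layout(truth, scaffolds, clusters)
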