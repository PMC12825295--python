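"""Sequence input and scaffold output (FASTA + AGP v2.1).

Scaffold sequences concatenate oriented contigs separated by runs of 'N'
of the estimated gap length; the AGP file describes the same layout with
1-based inclusive coordinates so the assembly can be rebuilt or lifted
with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .scaffold_builder import ScaffoldChain

__all__ = [
    "AssemblyLayout",
    "AgpRow",
    "read_fasta",
    "write_fasta",
    "write_scaffolds",
    "parse_agp",
    "reconstruct_from_agp",
    "FASTA_WIDTH",
]

FASTA_WIDTH = 80
GAP_TYPE = "scaffold"
LINKAGE_EVIDENCE = "proximity_ligation"


@dataclass
class AssemblyLayout:
    """Scaffold chains with resolved gaps, ready for writing."""

    scaffolds: list[ScaffoldChain]

    def contig_ids(self) -> list[str]:
        return [c for chain in self.scaffolds for c in chain.contig_ids]


@dataclass(frozen=True)
class AgpRow:
    """One AGP line: either a W (contig) or N (gap) component."""

    obj: str
    obj_beg: int  # 1-based inclusive
    obj_end: int
    part: int
    kind: str  # "W" | "N"
    component_id: str | None = None  # W rows
    orientation: str | None = None
    gap_length: int | None = None  # N rows


def read_fasta(path) -> dict[str, str]:
    """Contig id (first whitespace token) -> sequence, case preserved."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _chain_length(chain: ScaffoldChain, seqs: Mapping[str, str]) -> int:
    total = sum(len(seqs[c]) for c in chain.contig_ids)
    total += sum(j.gap or 0 for j in chain.joins)
    return total


def write_scaffolds(
    layout: AssemblyLayout,
    seqs: Mapping[str, str],
    out_fasta,
    out_agp,
) -> dict[str, str]:
    """Write scaffold FASTA and AGP v2.1; returns the scaffold sequences.

    Scaffolds are named scaffold_1..n in order of descending length.  Every
    join must carry a resolved integer gap; '-' contigs are
    reverse-complemented.
    """
    for chain in layout.scaffolds:
        for c in chain.contig_ids:
            if c not in seqs:
                raise ValueError(f"no sequence for contig {c!r}")
        for j in chain.joins:
            if j.gap is None or j.gap < 0:
                raise ValueError("all joins need a resolved non-negative gap")
    ordered = sorted(
        layout.scaffolds, key=lambda ch: (-_chain_length(ch, seqs), ch.contig_ids[0])
    )
    scaffold_seqs: dict[str, str] = {}
    agp_rows: list[str] = ["##agp-version\t2.1"]
    for idx, chain in enumerate(ordered, start=1):
        name = f"scaffold_{idx}"
        parts: list[str] = []
        pos = 0  # 0-based running end
        part_no = 0
        for i, (contig, orient) in enumerate(chain.entries):
            seq = seqs[contig]
            if orient == "-":
                seq = _revcomp(seq)
            part_no += 1
            agp_rows.append(
                "\t".join(
                    [
                        name,
                        str(pos + 1),
                        str(pos + len(seq)),
                        str(part_no),
                        "W",
                        contig,
                        "1",
                        str(len(seqs[contig])),
                        orient,
                    ]
                )
            )
            parts.append(seq)
            pos += len(seq)
            if i < len(chain.joins):
                gap = int(chain.joins[i].gap or 0)
                if gap > 0:
                    part_no += 1
                    agp_rows.append(
                        "\t".join(
                            [
                                name,
                                str(pos + 1),
                                str(pos + gap),
                                str(part_no),
                                "N",
                                str(gap),
                                GAP_TYPE,
                                "yes",
                                LINKAGE_EVIDENCE,
                            ]
                        )
                    )
                    parts.append("N" * gap)
                    pos += gap
        scaffold_seqs[name] = "".join(parts)
    write_fasta(scaffold_seqs, out_fasta)
    with open(out_agp, "w") as fh:
        fh.write("\n".join(agp_rows) + "\n")
    return scaffold_seqs


def parse_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            obj, beg, end, part, kind = cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4]
            if kind == "W":
                rows.append(
                    AgpRow(obj, beg, end, part, "W", component_id=cols[5], orientation=cols[8])
                )
            elif kind in ("N", "U"):
                rows.append(AgpRow(obj, beg, end, part, "N", gap_length=int(cols[5])))
            else:
                raise ValueError(f"unsupported AGP component type {kind!r}")
    return rows


def reconstruct_from_agp(path, contig_seqs: Mapping[str, str]) -> dict[str, str]:
    """Rebuild scaffold sequences from an AGP file plus the contig FASTA."""
    out: dict[str, list[str]] = {}
    for row in parse_agp(path):
        parts = out.setdefault(row.obj, [])
        if row.kind == "W":
            seq = contig_seqs[row.component_id]
            if row.orientation == "-":
                seq = _revcomp(seq)
            parts.append(seq)
        else:
            parts.append("N" * (row.gap_length or 0))
    return {name: "".join(parts) for name, parts in out.items()}
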