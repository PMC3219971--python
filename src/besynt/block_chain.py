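"""Chain local-alignment blocks into syntenic regions.

Within one (contig, reference chromosome) group, blocks whose
reference-axis gap is at most 100 kb are single-linkage chained; a chain
is flagged syntenic iff its summed score strictly exceeds 100,000. The
gap is measured on the reference axis only; strand-mixed chains are
permitted (inversions within a syntenic region are expected) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io_formats import HitRecord, ValidationError

__all__ = [
    "AlignmentBlock",
    "ChainedRegion",
    "chain_blocks",
    "blocks_from_hits",
    "export_dotplot",
    "read_dotplot",
]

DEFAULT_GAP_MAX = 100_000
DEFAULT_SCORE_MIN = 100_000


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment between a contig and a reference chromosome."""

    contig_id: str
    contig_start: int
    contig_end: int
    chromosome: str
    ref_start: int
    ref_end: int
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValidationError("block score must be > 0")
        if self.contig_start > self.contig_end or self.ref_start > self.ref_end:
            raise ValidationError("block intervals must be ascending")
        if self.strand not in {"+", "-"}:
            raise ValidationError("strand must be '+' or '-'")


@dataclass(frozen=True)
class ChainedRegion:
    contig_id: str
    chromosome: str
    blocks: tuple[AlignmentBlock, ...]
    summed_score: float
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int
    syntenic: bool
    mixed_strand: bool


def blocks_from_hits(hits: Sequence[HitRecord]) -> list[AlignmentBlock]:
    """Convert 12-column hits (query = contig) into alignment blocks,
    using the raw score if present, otherwise the bit score."""
    return [
        AlignmentBlock(
            contig_id=h.query_id,
            contig_start=min(h.query_start, h.query_end),
            contig_end=max(h.query_start, h.query_end),
            chromosome=h.subject_id,
            ref_start=h.subject_lo,
            ref_end=h.subject_hi,
            score=float(h.raw_score if h.raw_score > 0 else h.bit_score),
            strand=h.subject_strand,
        )
        for h in hits
    ]


def chain_blocks(
    blocks: Sequence[AlignmentBlock],
    gap_max: int = DEFAULT_GAP_MAX,
    score_min: float = DEFAULT_SCORE_MIN,
) -> list[ChainedRegion]:
    """Single-linkage chaining on the reference axis.

    Blocks are grouped by (contig, chromosome) and sorted by reference
    start; a block joins the current chain when its gap to the chain
    (its start minus the running maximum end; negative when overlapping)
    is <= ``gap_max``. A chain is syntenic iff its summed score is
    strictly greater than ``score_min``.
    """
    groups: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.contig_id, b.chromosome), []).append(b)
    regions: list[ChainedRegion] = []
    for (contig_id, chrom), group in sorted(groups.items()):
        group = sorted(group, key=lambda b: (b.ref_start, b.ref_end))
        chain: list[AlignmentBlock] = []
        max_end = None
        for b in group:
            if max_end is not None and b.ref_start - max_end > gap_max:
                regions.append(_finish(contig_id, chrom, chain, score_min))
                chain = []
                max_end = None
            chain.append(b)
            max_end = b.ref_end if max_end is None else max(max_end, b.ref_end)
        if chain:
            regions.append(_finish(contig_id, chrom, chain, score_min))
    return regions


def _finish(
    contig_id: str, chrom: str, chain: list[AlignmentBlock], score_min: float
) -> ChainedRegion:
    total = sum(b.score for b in chain)
    strands = {b.strand for b in chain}
    return ChainedRegion(
        contig_id=contig_id,
        chromosome=chrom,
        blocks=tuple(chain),
        summed_score=total,
        contig_start=min(b.contig_start for b in chain),
        contig_end=max(b.contig_end for b in chain),
        ref_start=min(b.ref_start for b in chain),
        ref_end=max(b.ref_end for b in chain),
        syntenic=total > score_min,
        mixed_strand=len(strands) > 1,
    )


# ---------------------------------------------------------------------------
# Dot-plot export


def export_dotplot(
    blocks: Sequence[AlignmentBlock],
    regions: Sequence[ChainedRegion],
    gene_tracks: Sequence[tuple[str, str, int, int]] = (),
    path: str | Path = "dotplot.tsv",
) -> None:
    """Write dot-plot data: two endpoint rows per block (contig position,
    reference position, score, region id) plus gene-track rows.

    ``gene_tracks`` rows are (axis, id, start, end) with axis 'contig' or
    'reference'. Ordering is deterministic.
    """
    region_of: dict[AlignmentBlock, str] = {}
    for ri, region in enumerate(
        sorted(regions, key=lambda r: (r.contig_id, r.chromosome, r.ref_start))
    ):
        for b in region.blocks:
            region_of[b] = f"region{ri+1}"
    with open(path, "w") as fh:
        fh.write("row_type\tcontig_id\tchromosome\tcontig_pos\tref_pos\tscore\tregion_id\tstrand\n")
        for b in sorted(
            blocks, key=lambda b: (b.contig_id, b.chromosome, b.ref_start, b.contig_start)
        ):
            rid = region_of.get(b, ".")
            ends = (
                (b.contig_start, b.ref_start),
                (b.contig_end, b.ref_end),
            )
            if b.strand == "-":
                ends = (
                    (b.contig_start, b.ref_end),
                    (b.contig_end, b.ref_start),
                )
            for cpos, rpos in ends:
                fh.write(
                    f"point\t{b.contig_id}\t{b.chromosome}\t{cpos}\t{rpos}\t"
                    f"{repr(float(b.score))}\t{rid}\t{b.strand}\n"
                )
        for axis, gid, start, end in gene_tracks:
            fh.write(f"gene\t{axis}\t{gid}\t{start}\t{end}\t.\t.\t.\n")


def read_dotplot(path: str | Path) -> list[dict]:
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
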