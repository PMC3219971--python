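"""Two-pass BES-to-reference anchoring and the subgenome-distribution test.

Pass 1 compares a physical-map contig's (repeat-filtered) BES against a
reference genome at protein level and keeps per-BES best hits with bit
score strictly greater than 80. Any two distinct BES of one contig whose
best-hit loci lie (strictly) less than 500 kb apart on one chromosome
seed a 4-Mbp anchor tract centred on the pair-union midpoint. Pass 2
re-searches all the contig's BES against each tract; the contig is called
anchored to the tract iff it has at least four qualifying (BES, gene)
hits (E <= 1e-4, overlapping an annotated gene, one count per BES-gene
pair) to at least three distinct genes.

The subgenome-distribution test asks whether a contig's best matches into
a triplicated reference fall on one or several post-triplication
subgenomes — the signature used to time the gamma paleohexaploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homology import (
    ScoringScheme,
    SearchJob,
    TranslatedDatabase,
    best_hits,
    translated_search,
)
from .io_formats import GeneModel, Genome, HitRecord, SequenceRecord

__all__ = [
    "AnchorTract",
    "SyntenyCall",
    "NoCall",
    "SubgenomeDistribution",
    "find_anchor_tracts",
    "focused_anchor",
    "subgenome_distribution",
    "anchor_contig",
    "anchor_contigs",
]

DEFAULT_MAX_PAIR_DISTANCE = 500_000
DEFAULT_TRACT_SPAN = 4_000_000
DEFAULT_MIN_BIT_SCORE = 80.0
DEFAULT_FOCUSED_E = 1e-4
DEFAULT_SUBGENOME_E = 1e-6
DEFAULT_MIN_CLONES = 39


@dataclass(frozen=True)
class AnchorTract:
    """A reference-genome window seeded by a close pair of BES best hits."""

    contig_id: str
    genome: str
    chromosome: str
    start: int  # 1-based, clipped to the chromosome
    end: int
    supporting_bes: tuple[str, ...]
    merged: bool = False  # True when overlapping seed tracts were merged

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SyntenyCall:
    """An anchored contig: >= 4 qualifying hits to >= 3 distinct genes."""

    contig_id: str
    genome: str
    chromosome: str
    tract: AnchorTract
    hits: tuple[HitRecord, ...]
    genes: tuple[str, ...]

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class NoCall:
    contig_id: str
    tract: AnchorTract
    reason: str


@dataclass(frozen=True)
class SubgenomeDistribution:
    contig_id: str
    n_genes: int
    subgenomes: tuple[str, ...]
    genes_by_subgenome: Mapping[str, tuple[str, ...]]

    @property
    def n_subgenomes(self) -> int:
        return len(self.subgenomes)

    @property
    def multi_subgenome(self) -> bool:
        return len(self.subgenomes) >= 2


def _hit_locus(hit: HitRecord) -> int:
    """The measurement point for pair distance: subject-interval start."""
    return hit.subject_lo


def find_anchor_tracts(
    contig_bes_best_hits: Mapping[str, Sequence[HitRecord]],
    chromosome_lengths: Mapping[str, int],
    genome_name: str = "reference",
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE,
    tract_span: int = DEFAULT_TRACT_SPAN,
) -> list[AnchorTract]:
    """Seed anchor tracts from close pairs of per-BES best hits.

    ``contig_bes_best_hits`` maps a contig id to its BES best hits (one
    per BES; callers have already applied the bit-score floor and repeat
    filter). Every pair of hits from distinct BES on one chromosome with
    loci strictly less than ``max_pair_distance`` apart seeds a tract of
    width ``tract_span`` centred on the pair-union midpoint, clipped to
    the chromosome; overlapping tracts of one contig are merged.
    """
    tracts: list[AnchorTract] = []
    for contig_id, hits in sorted(contig_bes_best_hits.items()):
        by_chrom: dict[str, list[HitRecord]] = {}
        for h in hits:
            by_chrom.setdefault(h.subject_id, []).append(h)
        for chrom, chits in sorted(by_chrom.items()):
            length = chromosome_lengths[chrom]
            seeds: list[tuple[int, int, str, str]] = []
            for i in range(len(chits)):
                for j in range(i + 1, len(chits)):
                    a, b = chits[i], chits[j]
                    if a.query_id == b.query_id:
                        continue
                    la, lb = _hit_locus(a), _hit_locus(b)
                    if abs(la - lb) < max_pair_distance:
                        seeds.append((min(la, lb), max(la, lb), a.query_id, b.query_id))
            windows = []
            for lo, hi, qa, qb in seeds:
                mid = (lo + hi) / 2.0
                start = max(1, int(round(mid - tract_span / 2.0)))
                end = min(length, int(round(mid + tract_span / 2.0)))
                windows.append((start, end, {qa, qb}))
            # merge overlapping windows of this contig x chromosome
            windows.sort()
            merged: list[tuple[int, int, set[str], bool]] = []
            for start, end, support in windows:
                if merged and start <= merged[-1][1]:
                    ms, me, sup, _ = merged[-1]
                    merged[-1] = (ms, max(me, end), sup | support, True)
                else:
                    merged.append((start, end, set(support), False))
            for start, end, support, was_merged in merged:
                tracts.append(
                    AnchorTract(
                        contig_id=contig_id,
                        genome=genome_name,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        supporting_bes=tuple(sorted(support)),
                        merged=was_merged,
                    )
                )
    return tracts


def focused_anchor(
    contig_bes: Sequence[SequenceRecord],
    tract: AnchorTract,
    reference: Genome,
    e_threshold: float = DEFAULT_FOCUSED_E,
    min_hits: int = 4,
    min_genes: int = 3,
    scheme: ScoringScheme | None = None,
) -> SyntenyCall | NoCall:
    """Second-pass focused protein-level search of a contig against a tract.

    A qualifying hit is a unique (BES, gene) pair: an alignment with
    E <= ``e_threshold`` whose subject interval overlaps an annotated gene
    in the tract (multiple local alignments between the same BES and gene
    count once). The contig anchors iff there are >= ``min_hits``
    qualifying hits to >= ``min_genes`` distinct genes.
    """
    genes_in_tract = [
        g
        for g in reference.genes
        if g.chromosome == tract.chromosome
        and g.start <= tract.end
        and g.end >= tract.start
    ]
    if not genes_in_tract:
        return NoCall(tract.contig_id, tract, "unannotated tract")
    tract_seq = reference.chromosomes[tract.chromosome][tract.start - 1 : tract.end]
    tract_rec = SequenceRecord(f"{tract.chromosome}:{tract.start}-{tract.end}", tract_seq)
    scheme = scheme or ScoringScheme(mode="translated")
    hits = translated_search(
        SearchJob(list(contig_bes), [tract_rec], scheme, e_threshold=e_threshold)
    )
    qualifying: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        s_lo = tract.start - 1 + h.subject_lo
        s_hi = tract.start - 1 + h.subject_hi
        for g in genes_in_tract:
            if s_lo <= g.end and s_hi >= g.start:
                key = (h.query_id, g.gene_id)
                prev = qualifying.get(key)
                if prev is None or h.e_value < prev.e_value:
                    qualifying[key] = h
    genes_hit = sorted({gene for (_bes, gene) in qualifying})
    if len(qualifying) >= min_hits and len(genes_hit) >= min_genes:
        ordered = tuple(
            qualifying[k] for k in sorted(qualifying, key=lambda k: (k[0], k[1]))
        )
        return SyntenyCall(
            contig_id=tract.contig_id,
            genome=tract.genome,
            chromosome=tract.chromosome,
            tract=tract,
            hits=ordered,
            genes=tuple(genes_hit),
        )
    return NoCall(
        tract.contig_id,
        tract,
        f"{len(qualifying)} qualifying hits to {len(genes_hit)} genes",
    )


def subgenome_distributions(
    bes_by_contig: Mapping[str, Sequence[SequenceRecord]],
    reference: Genome,
    e_threshold: float = DEFAULT_SUBGENOME_E,
    min_genes: int = 2,
) -> list[SubgenomeDistribution]:
    """Run :func:`subgenome_distribution` for many contigs, translating
    and indexing the reference gene set once."""
    block_genes = [g for g in reference.genes if g.ancestral_block_id is not None]
    gene_records = [
        SequenceRecord(g.gene_id, reference.gene_sequence(g)) for g in block_genes
    ]
    database = TranslatedDatabase(gene_records)
    out: list[SubgenomeDistribution] = []
    for contig_id, bes in sorted(bes_by_contig.items()):
        res = subgenome_distribution(
            contig_id, bes, reference, e_threshold=e_threshold,
            min_genes=min_genes, _gene_records=gene_records, _database=database,
        )
        if res is not None:
            out.append(res)
    return out


def subgenome_distribution(
    contig_id: str,
    contig_bes: Sequence[SequenceRecord],
    reference: Genome,
    e_threshold: float = DEFAULT_SUBGENOME_E,
    min_genes: int = 2,
    scheme: ScoringScheme | None = None,
    _gene_records: Sequence[SequenceRecord] | None = None,
    _database: TranslatedDatabase | None = None,
) -> SubgenomeDistribution | None:
    """Distribute a contig's best gene matches across reference subgenomes.

    Per BES, the best protein-level hit with E <= ``e_threshold`` to a
    gene carrying an ancestral-block assignment is taken; the contig is
    reported (with its distinct genes and distinct subgenomes) only when
    at least ``min_genes`` distinct genes are matched. The reference's
    genes must carry subgenome labels.
    """
    block_genes = [
        g for g in reference.genes if g.ancestral_block_id is not None
    ]
    if not block_genes:
        raise ValueError("reference genome lacks ancestral-block assignments")
    if all(g.subgenome is None for g in block_genes):
        raise ValueError("reference genome lacks subgenome labels")
    gene_records = _gene_records or [
        SequenceRecord(g.gene_id, reference.gene_sequence(g)) for g in block_genes
    ]
    gene_by_id = {g.gene_id: g for g in block_genes}
    scheme = scheme or ScoringScheme(mode="translated")
    hits = translated_search(
        SearchJob(list(contig_bes), gene_records, scheme, e_threshold=e_threshold),
        database=_database,
    )
    best = best_hits(hits, min_bit_score=0.0)
    genes_hit: dict[str, GeneModel] = {}
    for _bes, h in best.items():
        g = gene_by_id[h.subject_id]
        genes_hit[g.gene_id] = g
    if len(genes_hit) < min_genes:
        return None
    by_sub: dict[str, list[str]] = {}
    for g in genes_hit.values():
        by_sub.setdefault(g.subgenome or "S0", []).append(g.gene_id)
    return SubgenomeDistribution(
        contig_id=contig_id,
        n_genes=len(genes_hit),
        subgenomes=tuple(sorted(by_sub)),
        genes_by_subgenome={s: tuple(sorted(v)) for s, v in sorted(by_sub.items())},
    )


# ---------------------------------------------------------------------------
# Pipeline drivers


def anchor_contig(
    contig_id: str,
    contig_bes: Sequence[SequenceRecord],
    reference: Genome,
    repeat_labels: Mapping[str, str | None] | None = None,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE,
    tract_span: int = DEFAULT_TRACT_SPAN,
    focused_e: float = DEFAULT_FOCUSED_E,
    pass1_e: float = 1e-3,
    scheme: ScoringScheme | None = None,
    database: TranslatedDatabase | None = None,
) -> list[SyntenyCall]:
    """Run the full two-pass anchoring of one contig against one genome.

    ``repeat_labels`` (read id -> repeat class or None) discards
    repeat-classified BES before pass 1; gene-like and unlabelled reads
    are kept. A prebuilt :class:`TranslatedDatabase` over the reference
    chromosomes amortizes indexing across contigs.
    """
    from .repeats import GENE_LABEL

    bes = [
        r
        for r in contig_bes
        if repeat_labels is None
        or repeat_labels.get(r.id) in (None, GENE_LABEL)
    ]
    if not bes:
        return []
    scheme = scheme or ScoringScheme(mode="translated")
    hits = translated_search(
        SearchJob(bes, reference.sequence_records(), scheme, e_threshold=pass1_e),
        database=database,
    )
    best = best_hits(hits, min_bit_score=min_bit_score)
    if len(best) < 2:
        return []
    tracts = find_anchor_tracts(
        {contig_id: list(best.values())},
        reference.chromosome_lengths(),
        genome_name=reference.name,
        max_pair_distance=max_pair_distance,
        tract_span=tract_span,
    )
    calls: list[SyntenyCall] = []
    for tract in tracts:
        result = focused_anchor(
            bes, tract, reference, e_threshold=focused_e, scheme=scheme
        )
        if isinstance(result, SyntenyCall):
            calls.append(result)
    return calls


def anchor_contigs(
    bes_by_contig: Mapping[str, Sequence[SequenceRecord]],
    references: Iterable[Genome],
    clone_counts: Mapping[str, int] | None = None,
    min_clones: int = DEFAULT_MIN_CLONES,
    repeat_labels: Mapping[str, str | None] | None = None,
    **kwargs,
) -> list[SyntenyCall]:
    """Anchor every eligible contig against every reference genome.

    Contigs with fewer than ``min_clones`` clones are skipped when
    ``clone_counts`` is supplied (the physical-map eligibility filter).
    """
    calls: list[SyntenyCall] = []
    databases = {
        ref.name: TranslatedDatabase(ref.sequence_records())
        for ref in references
    }
    for contig_id, bes in sorted(bes_by_contig.items()):
        if clone_counts is not None and clone_counts.get(contig_id, 0) < min_clones:
            continue
        for ref in references:
            calls.extend(
                anchor_contig(
                    contig_id, bes, ref, repeat_labels=repeat_labels,
                    database=databases[ref.name], **kwargs
                )
            )
    return calls


def write_synteny_calls(calls: Sequence[SyntenyCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig_id\tgenome\tchromosome\ttract_start\ttract_end\tn_hits\tn_genes\tgenes\n"
        )
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.genome}\t{c.chromosome}\t{c.tract.start}\t"
                f"{c.tract.end}\t{c.n_hits}\t{c.n_genes}\t{','.join(c.genes)}\n"
            )
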