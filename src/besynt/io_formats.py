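"""Readers and writers for the formats the pipeline touches.

All public coordinates are 1-based inclusive. Sequences are normalized to
upper-case DNA over {A, C, G, T, N}; U is mapped to T on input. Subject
strand in hit tables is encoded by ``s_start > s_end`` (the 12-column
tabular-hit-file dialect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "ValidationError",
    "SequenceRecord",
    "GeneModel",
    "HitRecord",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_gene_models_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_presence_matrix",
    "write_presence_matrix",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENE_TABLE_COLUMNS = (
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "ancestral_block_id",
    "subgenome",
)


class ValidationError(ValueError):
    """A record violated a format or type invariant."""


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ValidationError(f"record '{record_id}': empty sequence")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"record '{record_id}': characters outside ACGTN alphabet: "
            f"{sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (a read, a chromosome, a repeat-library entry)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        object.__setattr__(
            self, "sequence", _normalize_sequence(self.sequence, self.id)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            sequence=self.sequence.translate(_COMPLEMENT)[::-1],
            description=self.description,
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene interval on a chromosome.

    ``ancestral_block_id`` and ``subgenome`` carry the pre-triplication
    ancestral-block context used by the paleopolyploidy analysis; both are
    optional.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    ancestral_block_id: str | None = None
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"gene '{self.gene_id}': strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene '{self.gene_id}': invalid coordinates "
                f"start={self.start}, end={self.end} (need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HitRecord:
    """One local-alignment hit in the 12-column tabular dialect.

    Subject strand is encoded by coordinate order: ``subject_start >
    subject_end`` means the alignment is on the minus strand of the subject.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    raw_score: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: alignment_length "
                f"must be >= 1, got {self.alignment_length}"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: e_value must be >= 0"
            )
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: percent_identity "
                f"out of [0, 100]"
            )
        if self.bit_score < 0:
            raise ValidationError(
                f"hit {self.query_id}/{self.subject_id}: bit_score must be >= 0"
            )

    @property
    def subject_strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"

    @property
    def subject_lo(self) -> int:
        return min(self.subject_start, self.subject_end)

    @property
    def subject_hi(self) -> int:
        return max(self.subject_start, self.subject_end)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T. Duplicate ids and empty
    sequences raise :class:`ValidationError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id '{rec.id}' in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene-model tables (in-house 5-7 column TSV; see GENE_TABLE_COLUMNS)


def read_gene_models(
    path: str | Path,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read the tab-delimited gene-model table.

    Columns: gene_id, chromosome, start, end, strand and optionally
    ancestral_block_id and subgenome ('.' or empty meaning unset). A header
    line starting with 'gene_id' is permitted and skipped. When
    ``chromosome_lengths`` is given, chromosome names and coordinate bounds
    are checked against it.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "gene_id":
                continue
            if len(parts) < 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= 5 tab-separated columns"
                )
            gene_id, chrom, start_s, end_s, strand = parts[:5]
            block = parts[5] if len(parts) > 5 and parts[5] not in ("", ".") else None
            subg = parts[6] if len(parts) > 6 and parts[6] not in ("", ".") else None
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            gene = GeneModel(gene_id, chrom, start, end, strand, block, subg)
            if gene.gene_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene_id '{gene.gene_id}'"
                )
            seen.add(gene.gene_id)
            if chromosome_lengths is not None:
                if chrom not in chromosome_lengths:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown chromosome '{chrom}'"
                    )
                if end > chromosome_lengths[chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: gene '{gene_id}' end {end} exceeds "
                        f"chromosome '{chrom}' length {chromosome_lengths[chrom]}"
                    )
            genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chromosome,
                        str(g.start),
                        str(g.end),
                        g.strand,
                        g.ancestral_block_id or ".",
                        g.subgenome or ".",
                    ]
                )
                + "\n"
            )


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gene_models_gff3(
    path: str | Path,
    chromosome_lengths: Mapping[str, int] | None = None,
    feature_type: str = "gene",
) -> list[GeneModel]:
    """Import shim for GFF3 gene annotations.

    Only seqid, start, end, strand and the ID / ancestral_block_id /
    subgenome attributes are consumed.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValidationError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != feature_type:
                continue
            attr = dict(_GFF_ATTR.findall(attrs))
            gene_id = attr.get("ID", f"gene_{lineno}")
            if gene_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate gene ID '{gene_id}'"
                )
            seen.add(gene_id)
            gene = GeneModel(
                gene_id,
                chrom,
                int(start_s),
                int(end_s),
                strand,
                attr.get("ancestral_block_id"),
                attr.get("subgenome"),
            )
            if chromosome_lengths is not None and chrom not in chromosome_lengths:
                raise ValidationError(
                    f"{path}:{lineno}: unknown chromosome '{chrom}'"
                )
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# 12-column tabular hit files


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as 12 tab-separated columns, no header.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bit score. Floats are
    written with shortest round-trip repr so a read-back is field-identical.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(float(h.percent_identity)),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start),
                        str(h.query_end),
                        str(h.subject_start),
                        str(h.subject_end),
                        repr(float(h.e_value)),
                        repr(float(h.bit_score)),
                    ]
                )
                + "\n"
            )


def read_hit_table(path: str | Path) -> list[HitRecord]:
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise ValidationError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            hits.append(
                HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    query_start=int(parts[6]),
                    query_end=int(parts[7]),
                    subject_start=int(parts[8]),
                    subject_end=int(parts[9]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Genome container (sequences + gene annotations)


@dataclass
class Genome:
    """A named genome: chromosome sequences plus gene models."""

    name: str
    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = self.chromosome_lengths()
        for g in self.genes:
            if g.chromosome not in lengths:
                raise ValidationError(
                    f"gene '{g.gene_id}' references unknown chromosome "
                    f"'{g.chromosome}'"
                )
            if g.end > lengths[g.chromosome]:
                raise ValidationError(
                    f"gene '{g.gene_id}' end {g.end} exceeds chromosome "
                    f"'{g.chromosome}' length {lengths[g.chromosome]}"
                )

    def chromosome_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def sequence_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(name, seq) for name, seq in self.chromosomes.items()]

    def gene_sequence(self, gene: GeneModel) -> str:
        seq = self.chromosomes[gene.chromosome][gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq

    @classmethod
    def from_files(cls, name: str, fasta_path: str | Path,
                   gene_table_path: str | Path | None = None) -> "Genome":
        records = read_fasta(fasta_path)
        chromosomes = {r.id: r.sequence for r in records}
        genes: list[GeneModel] = []
        if gene_table_path is not None:
            genes = read_gene_models(
                gene_table_path, {k: len(v) for k, v in chromosomes.items()}
            )
        return cls(name, chromosomes, genes)

    def to_files(self, fasta_path: str | Path, gene_table_path: str | Path) -> None:
        write_fasta(self.sequence_records(), fasta_path)
        write_gene_models(self.genes, gene_table_path)


# ---------------------------------------------------------------------------
# Presence/absence matrices (CSV; rows = blocks/contigs, columns = taxa)


def write_presence_matrix(matrix, path: str | Path) -> None:
    """Write a block x taxon presence matrix (pandas DataFrame of 0/1)."""
    matrix.astype(int).to_csv(path)


def read_presence_matrix(path: str | Path):
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.astype(bool)
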