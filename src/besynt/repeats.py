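"""Tiered repeat classification, MITE validation, SSR and k-mer surveys.

The classifier reproduces the three-pass survey-read strategy:

1. nucleotide search against a class-annotated repeat library under the
   relaxed +5/-4 scoring (E <= 1e-10) — the *conservative* tier closes
   here;
2. reads without a repeat hit are compared at protein level against a
   coding-sequence database (E <= 1e-5) and labelled gene-like (excluded
   from repeat totals);
3. still-unlabelled reads are nucleotide-searched against the union of
   reads labelled in passes 1-2 and inherit the matched read's label —
   the *comprehensive* ("internal-search") tier. The expansion runs for a
   single round, not to transitive closure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import ScoringScheme, SearchJob, best_hits, local_search, translated_search
from .io_formats import SequenceRecord

__all__ = [
    "REPEAT_HIERARCHY",
    "GENE_LABEL",
    "RepeatCallTable",
    "ClassificationThresholds",
    "classify_repeats_tiered",
    "MiteCandidate",
    "MiteRejection",
    "validate_mite",
    "CopyNumberEstimate",
    "estimate_copy_number",
    "SsrHit",
    "scan_ssrs",
    "KmerSpectrum",
    "kmer_spectrum",
    "gene_te_correlation",
    "parse_library_class",
]

logger = logging.getLogger(__name__)

# leaf class -> superclass
REPEAT_HIERARCHY: dict[str, str] = {
    "hAT": "DNA_TE",
    "MuDR": "DNA_TE",
    "CACTA": "DNA_TE",
    "Helitron": "DNA_TE",
    "DNA_other": "DNA_TE",
    "MITE": "DNA_TE",
    "LTR_copia": "Retro",
    "LTR_gypsy": "Retro",
    "LTR_unclassified": "Retro",
    "LINE": "Retro",
    "SINE": "Retro",
    "retro_unclassified": "Retro",
}

GENE_LABEL = "gene"

_LTR_CLASSES = {"LTR_copia", "LTR_gypsy", "LTR_unclassified"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def parse_library_class(record: SequenceRecord) -> str:
    """Leaf repeat class from a library header: 'class=X' in the
    description, or a RepeatMasker-style 'name#X' id suffix."""
    for token in record.description.split():
        if token.startswith("class="):
            return token[len("class="):]
    if "#" in record.id:
        return record.id.rsplit("#", 1)[1]
    raise ValueError(f"library record '{record.id}' lacks a class annotation")


@dataclass(frozen=True)
class ClassificationThresholds:
    repeat_e: float = 1e-10
    protein_e: float = 1e-5
    internal_e: float = 1e-10


@dataclass
class RepeatCallTable:
    """Per-class read counts and percentages for both tiers."""

    table: pd.DataFrame  # indexed by leaf class (+ 'Total' rows)
    labels: dict[str, dict[str, str | None]]  # read -> {tier: label}
    n_reads: int

    def percent_repeats_sum(self, tier: str) -> float:
        col = f"pct_repeats_{tier}"
        leaf = self.table.loc[self.table.index != "Total", col]
        return float(leaf.sum())


def _tie_class(classes: set[str]) -> str:
    supers = {REPEAT_HIERARCHY.get(c, "Retro") for c in classes}
    if supers == {"Retro"}:
        if classes <= _LTR_CLASSES:
            return "LTR_unclassified"
        return "retro_unclassified"
    if supers == {"DNA_TE"}:
        return "DNA_other"
    return "retro_unclassified"


def classify_repeats_tiered(
    reads: Sequence[SequenceRecord],
    repeat_library: Sequence[SequenceRecord],
    protein_db: Sequence[SequenceRecord],
    thresholds: ClassificationThresholds | None = None,
    scheme: ScoringScheme | None = None,
) -> RepeatCallTable:
    """Three-pass tiered repeat classification of survey reads.

    ``repeat_library`` entries carry leaf-class headers (``class=...``);
    ``protein_db`` holds coding sequences compared at protein level.
    Returns the two-tier call table plus per-read labels (leaf class,
    ``'gene'``, or None).
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    thresholds = thresholds or ClassificationThresholds()
    scheme = scheme or ScoringScheme(mode="nucleotide", match=5, mismatch=-4)
    lib_class = {rec.id: parse_library_class(rec) for rec in repeat_library}

    # pass 1: reads vs repeat library
    conservative: dict[str, str] = {}
    if repeat_library:
        hits1 = local_search(
            SearchJob(reads, repeat_library, scheme, e_threshold=thresholds.repeat_e)
        )
        by_query: dict[str, list] = {}
        for h in hits1:
            by_query.setdefault(h.query_id, []).append(h)
        for rid, hs in by_query.items():
            top = max(h.bit_score for h in hs)
            top_classes = {lib_class[h.subject_id] for h in hs if h.bit_score == top}
            if len(top_classes) == 1:
                conservative[rid] = next(iter(top_classes))
            else:
                cls = _tie_class(top_classes)
                logger.info(
                    "read %s tied between classes %s at bit %.1f; assigned %s",
                    rid, sorted(top_classes), top, cls,
                )
                conservative[rid] = cls

    # pass 2: unhit reads vs protein database (protein level)
    gene_like: set[str] = set()
    unhit = [r for r in reads if r.id not in conservative]
    if unhit and protein_db:
        hits2 = translated_search(
            SearchJob(unhit, protein_db, scheme, e_threshold=thresholds.protein_e)
        )
        gene_like = {h.query_id for h in hits2}

    # pass 3: remaining reads vs the labelled reads (single round)
    comprehensive = dict(conservative)
    labelled_reads = [
        r for r in reads if r.id in conservative or r.id in gene_like
    ]
    remaining = [
        r for r in reads if r.id not in conservative and r.id not in gene_like
    ]
    inherited_gene: set[str] = set()
    if remaining and labelled_reads:
        hits3 = local_search(
            SearchJob(remaining, labelled_reads, scheme,
                      e_threshold=thresholds.internal_e)
        )
        best3 = best_hits(hits3, min_bit_score=0.0)
        for rid, h in best3.items():
            if h.subject_id in conservative:
                comprehensive[rid] = conservative[h.subject_id]
            else:
                inherited_gene.add(rid)

    all_gene = gene_like | inherited_gene
    labels = {
        r.id: {
            "conservative": conservative.get(
                r.id, GENE_LABEL if r.id in gene_like else None
            ),
            "comprehensive": comprehensive.get(
                r.id, GENE_LABEL if r.id in all_gene else None
            ),
        }
        for r in reads
    }

    n_reads = len(reads)
    rows = []
    leaf_classes = [c for c in REPEAT_HIERARCHY]
    totals = {
        "conservative": sum(1 for v in conservative.values()),
        "comprehensive": sum(1 for v in comprehensive.values()),
    }
    for cls in leaf_classes:
        row: dict[str, object] = {"class": cls, "superclass": REPEAT_HIERARCHY[cls]}
        for tier, calls in (("conservative", conservative), ("comprehensive", comprehensive)):
            n = sum(1 for v in calls.values() if v == cls)
            row[f"count_{tier}"] = n
            row[f"pct_reads_{tier}"] = 100.0 * n / n_reads
            row[f"pct_repeats_{tier}"] = (
                100.0 * n / totals[tier] if totals[tier] else 0.0
            )
        rows.append(row)
    total_row: dict[str, object] = {"class": "Total", "superclass": ""}
    for tier in ("conservative", "comprehensive"):
        total_row[f"count_{tier}"] = totals[tier]
        total_row[f"pct_reads_{tier}"] = 100.0 * totals[tier] / n_reads
        total_row[f"pct_repeats_{tier}"] = 100.0 if totals[tier] else 0.0
    rows.append(total_row)
    table = pd.DataFrame(rows).set_index("class")
    return RepeatCallTable(table=table, labels=labels, n_reads=n_reads)


# ---------------------------------------------------------------------------
# MITE validation


@dataclass(frozen=True)
class MiteCandidate:
    sequence: str
    length: int
    tir_length: int
    tsd: str
    at_fraction: float
    hit_count: int = 0
    copy_estimate: int = 0


@dataclass(frozen=True)
class MiteRejection:
    reason: str


def _longest_tir(seq: str, min_len: int = 15, max_mismatch_frac: float = 0.10) -> int:
    """Longest L with prefix-L matching RC(suffix-L) at <= 10% mismatch."""
    best = 0
    rc = seq.translate(_COMPLEMENT)[::-1]
    limit = len(seq) // 2
    for L in range(min_len, limit + 1):
        mism = sum(1 for a, b in zip(seq[:L], rc[:L]) if a != b)
        if mism <= max_mismatch_frac * L:
            best = L
    return best


def _find_tsd(left_flank: str, right_flank: str) -> str | None:
    for k in range(min(10, len(left_flank), len(right_flank)), 1, -1):
        if left_flank[-k:] == right_flank[:k]:
            return left_flank[-k:]
    return None


def validate_mite(
    candidate_sequence: str,
    flanks: tuple[str, str],
    min_length: int = 100,
    max_length: int = 800,
    min_tir: int = 15,
    tir_mismatch_frac: float = 0.10,
    min_at: float = 0.65,
) -> MiteCandidate | MiteRejection:
    """Accept a candidate as a MITE iff it passes every structural rule.

    Rules, checked in order (the first failure is reported): element length
    within [100, 800] bp; a terminal inverted repeat of >= 15 bp at <= 10%
    mismatch; an exact 2-10 bp target-site duplication in the flanks; A+T
    fraction strictly > 0.65. Flanks must supply >= 12 bp of context on
    each side.
    """
    left, right = flanks
    if len(left) < 12 or len(right) < 12:
        raise ValueError("need >= 12 bp of flanking context on each side")
    seq = candidate_sequence.upper()
    n = len(seq)
    if not (min_length <= n <= max_length):
        return MiteRejection(f"length {n} out of [{min_length}, {max_length}]")
    tir = _longest_tir(seq, min_tir, tir_mismatch_frac)
    if tir < min_tir:
        return MiteRejection(f"no terminal inverted repeat >= {min_tir} bp")
    tsd = _find_tsd(left.upper(), right.upper())
    if tsd is None:
        return MiteRejection("no TSD")
    at = (seq.count("A") + seq.count("T")) / n
    if not at > min_at:
        return MiteRejection(f"A+T <= {min_at}")
    return MiteCandidate(
        sequence=seq, length=n, tir_length=tir, tsd=tsd, at_fraction=at
    )


# ---------------------------------------------------------------------------
# Copy-number extrapolation


@dataclass(frozen=True)
class CopyNumberEstimate:
    copies: int
    sampling_fraction: float


def estimate_copy_number(
    hit_count: int, sample_bases: float, genome_bases: float
) -> CopyNumberEstimate:
    """Plain sampling-fraction scale-up: copies = hits * genome / sample."""
    if sample_bases <= 0:
        raise ValueError("sample_bases must be > 0")
    if genome_bases < sample_bases:
        warnings.warn(
            "genome smaller than the sampled bases; estimate scales down",
            stacklevel=2,
        )
    fraction = sample_bases / genome_bases
    copies = int(round(hit_count * genome_bases / sample_bases))
    return CopyNumberEstimate(copies=copies, sampling_fraction=fraction)


# ---------------------------------------------------------------------------
# SSR scanning


@dataclass(frozen=True)
class SsrHit:
    sequence_id: str
    motif: str  # canonical (rotation + reverse-complement minimal)
    unit_length: int
    repeat_count: int
    start: int  # 1-based inclusive, trimmed to complete units
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal string among all rotations of the motif
    and of its reverse complement."""
    rc = motif.translate(_COMPLEMENT)[::-1]
    forms = [
        m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))
    ]
    return min(forms)


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _raw_runs(seq: str, unit: int) -> list[tuple[int, int]]:
    """Maximal period-``unit`` runs as (start0, region_length >= 2*unit)."""
    n = len(seq)
    if n < 2 * unit:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    match = arr[unit:] == arr[:-unit]
    runs: list[tuple[int, int]] = []
    idx = np.nonzero(match)[0]
    if idx.size == 0:
        return runs
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        a = int(idx[s])
        b = int(idx[e])  # last matching offset
        L = b - a + 1 + unit  # region [a, b + unit]
        if L >= 2 * unit:
            runs.append((a, L))
    return runs


def scan_ssrs(
    sequences: Sequence[SequenceRecord],
    min_units: int = 4,
    min_length: int = 12,
    mono_min_length: int = 10,
    max_unit: int = 5,
) -> tuple[list[SsrHit], pd.DataFrame]:
    """Find maximal exact tandem runs of 1-5 bp motifs.

    Thresholds: mononucleotide runs need >= ``mono_min_length`` bp; units
    2-5 need >= ``min_units`` complete units and >= ``min_length`` bp.
    Hits are trimmed to complete units; overlapping calls within one
    sequence are resolved longest-first. The summary reports counts per
    unit length and per Mbp scanned.
    """
    hits: list[SsrHit] = []
    total_bases = 0
    for rec in sequences:
        seq = rec.sequence
        total_bases += len(seq)
        candidates: list[SsrHit] = []
        for unit in range(1, max_unit + 1):
            for a, L in _raw_runs(seq, unit):
                motif = seq[a : a + unit]
                if "N" in motif or not _is_primitive(motif):
                    continue
                count = L // unit
                used = unit * count
                if unit == 1:
                    if used < mono_min_length:
                        continue
                else:
                    if count < min_units or used < min_length:
                        continue
                candidates.append(
                    SsrHit(
                        sequence_id=rec.id,
                        motif=canonical_motif(motif),
                        unit_length=unit,
                        repeat_count=count,
                        start=a + 1,
                        end=a + used,
                    )
                )
        candidates.sort(key=lambda h: (-h.length, h.unit_length, h.start))
        taken: list[SsrHit] = []
        for h in candidates:
            if all(h.end < t.start or h.start > t.end for t in taken):
                taken.append(h)
        taken.sort(key=lambda h: h.start)
        hits.extend(taken)

    names = {1: "Mono", 2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta"}
    mbp = total_bases / 1e6 if total_bases else float("nan")
    rows = []
    for unit in range(1, max_unit + 1):
        n = sum(1 for h in hits if h.unit_length == unit)
        rows.append(
            {"unit": names.get(unit, str(unit)), "count": n,
             "per_mbp": n / mbp if total_bases else 0.0}
        )
    rows.append(
        {"unit": "Total", "count": len(hits),
         "per_mbp": len(hits) / mbp if total_bases else 0.0}
    )
    summary = pd.DataFrame(rows).set_index("unit")
    return hits, summary


# ---------------------------------------------------------------------------
# k-mer spectra


@dataclass(frozen=True)
class KmerSpectrum:
    k: int
    histogram: dict[int, int]  # occurrence count -> number of distinct k-mers
    total_kmers: int


_NT4 = np.full(256, -1, np.int8)
for _i, _c in enumerate("ACGT"):
    _NT4[ord(_c)] = _i
_RC4 = np.array([3, 2, 1, 0], np.int64)


def kmer_spectrum(
    reads: Sequence[SequenceRecord], k: int = 20, canonical: bool = True
) -> KmerSpectrum:
    """Exact k-mer occurrence histogram over a read set.

    With ``canonical=True`` each window is counted once under the
    lexicographically smaller of its two strands. Windows containing N are
    skipped. ``k`` must be 2-27 (the counter packs k-mers into 64-bit
    integers).
    """
    if not (2 <= k <= 27):
        raise ValueError("k must be in [2, 27]")
    if not reads:
        raise ValueError("need at least one read")
    chunks: list[np.ndarray] = []
    for rec in reads:
        codes = _NT4[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)].astype(np.int64)
        n = codes.shape[0]
        if n < k:
            continue
        vals = np.zeros(n - k + 1, np.int64)
        rvals = np.zeros(n - k + 1, np.int64)
        bad = np.zeros(n - k + 1, bool)
        for off in range(k):
            w = codes[off : off + n - k + 1]
            bad |= w < 0
            vals = vals * 4 + np.where(w < 0, 0, w)
            wr = np.where(w < 0, 0, _RC4[np.where(w < 0, 0, w)])
            rvals = rvals + (wr << (2 * off))
        keep = ~bad
        v = vals[keep]
        if canonical:
            v = np.minimum(v, rvals[keep])
        chunks.append(v)
    if not chunks or sum(c.size for c in chunks) == 0:
        warnings.warn("k exceeds every read length; empty spectrum", stacklevel=2)
        return KmerSpectrum(k=k, histogram={}, total_kmers=0)
    allv = np.concatenate(chunks)
    _, counts = np.unique(allv, return_counts=True)
    occ, mult = np.unique(counts, return_counts=True)
    histogram = {int(o): int(m) for o, m in zip(occ, mult)}
    return KmerSpectrum(k=k, histogram=histogram, total_kmers=int(allv.size))


# ---------------------------------------------------------------------------
# Gene density vs LTR-retrotransposon density


def gene_te_correlation(
    per_contig_read_labels: Mapping[str, tuple[int, Sequence[str | None]]],
    min_bacs: int = 10,
) -> tuple[float, float, int]:
    """Pearson correlation of per-contig gene-like vs LTR-retro fractions.

    ``per_contig_read_labels`` maps contig id to (BAC clone count, read
    labels). Contigs with fewer than ``min_bacs`` clones are excluded.
    Returns (r, two-sided p, number of contigs used).
    """
    gene_fracs: list[float] = []
    ltr_fracs: list[float] = []
    for _contig, (n_bacs, lab) in sorted(per_contig_read_labels.items()):
        if n_bacs < min_bacs or not lab:
            continue
        n = len(lab)
        gene_fracs.append(sum(1 for x in lab if x == GENE_LABEL) / n)
        ltr_fracs.append(sum(1 for x in lab if x in _LTR_CLASSES) / n)
    if len(gene_fracs) < 3:
        raise ValueError("need >= 3 contigs passing the min_bacs filter")
    g = np.asarray(gene_fracs)
    t = np.asarray(ltr_fracs)
    if g.std() == 0 or t.std() == 0:
        raise ValueError("zero variance in gene or LTR fractions; r undefined")
    r, p = stats.pearsonr(g, t)
    return float(r), float(p), len(gene_fracs)
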