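"""Self-contained local similarity search with Karlin-Altschul statistics.

Implements seeded Smith-Waterman search in nucleotide mode (BLASTN-like)
and translated mode (tBLASTX/BLASTX-like), reporting raw scores, bit
scores and E-values so that pipeline thresholds such as "bit score > 80"
or "E-value <= 1e-10" are exercisable without an external aligner.

Statistics
----------
For a raw score S the E-value is ``E = K * m * n * exp(-lambda * S)``
where m is the query length and n the summed subject length (both in
search units: nucleotides or residues), and the bit score is
``(lambda * S - ln K) / ln 2``. In nucleotide mode lambda is solved from
the Karlin-Altschul identity sum_ij p_i p_j exp(lambda * s_ij) = 1 for the
configured match/mismatch scores and background composition; K defaults to
0.621. In translated mode the ungapped BLOSUM62 defaults (lambda = 0.3176,
K = 0.134) are used. The paper-facing default nucleotide scoring is the
relaxed +5/-4 scheme used for diverged-repeat searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from . import _kernels
from ._kernels import NEG, banded_sw
from .io_formats import HitRecord, SequenceRecord, ValidationError

__all__ = [
    "ScoringScheme",
    "SearchJob",
    "solve_karlin_altschul",
    "local_search",
    "translated_search",
    "TranslatedDatabase",
    "best_hits",
    "smith_waterman_score",
]

# -- alphabets ---------------------------------------------------------------

_NT_ORDER = "ACGTN"
_NT_LOOKUP = np.full(256, 4, np.int8)
for _i, _c in enumerate(_NT_ORDER):
    _NT_LOOKUP[ord(_c)] = _i
    _NT_LOOKUP[ord(_c.lower())] = _i

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ORDER = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_AA_X = _AA_ORDER.index("X")
_AA_STOP = _AA_ORDER.index("*")
_AA_LOOKUP = np.full(256, _AA_X, np.int8)
for _i, _c in enumerate(_AA_ORDER):
    _AA_LOOKUP[ord(_c)] = _i
_AA_LOOKUP[ord("*")] = _AA_STOP
_AA_SUB = np.asarray(_BLOSUM62, dtype=np.int32)

# ungapped BLOSUM62 Karlin-Altschul parameters
_PROT_LAMBDA = 0.3176
_PROT_K = 0.134

DEFAULT_NT_K = 0.621

UNIFORM_COMPOSITION = (0.25, 0.25, 0.25, 0.25)


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _nt_submatrix(match: int, mismatch: int) -> np.ndarray:
    sub = np.full((5, 5), mismatch, np.int32)
    for i in range(4):
        sub[i, i] = match
    sub[4, :] = mismatch  # N scores as a mismatch against everything
    sub[:, 4] = mismatch
    return sub


# -- Karlin-Altschul ---------------------------------------------------------


def solve_karlin_altschul(
    match: int,
    mismatch: int,
    composition: Sequence[float] = UNIFORM_COMPOSITION,
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for the positive lambda.

    ``s_ij`` is ``match`` on the diagonal and ``mismatch`` off it under the
    given background composition. Raises ValueError when no positive root
    exists (expected score >= 0 or no positive match score).
    """
    if match <= 0:
        raise ValueError("match score must be > 0")
    if mismatch >= 0:
        raise ValueError("mismatch score must be < 0")
    p = np.asarray(composition, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("composition must be 4 non-negative values summing to 1")
    p_same = float((p**2).sum())
    p_diff = 1.0 - p_same
    expected = p_same * match + p_diff * mismatch
    if expected >= 0:
        raise ValueError(
            "expected score per aligned pair is >= 0; "
            "no positive Karlin-Altschul lambda exists"
        )

    def f(lam: float) -> float:
        return p_same * math.exp(lam * match) + p_diff * math.exp(lam * mismatch) - 1.0

    hi = 1e-3
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - cannot happen with match > 0
            raise ValueError("failed to bracket lambda")
    lam = brentq(f, 1e-12, hi, xtol=1e-13)
    # refine so the identity residual is < 1e-9
    return float(lam)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus the statistical parameters derived from it.

    ``gap_open`` is the (negative) score of the first gap character,
    ``gap_extend`` of each additional one. In nucleotide mode ``lambda_``
    is solved from the match/mismatch scores when not supplied.
    """

    mode: str = "nucleotide"  # 'nucleotide' | 'translated'
    match: int = 5
    mismatch: int = -4
    gap_open: int = 0  # resolved per mode when left at 0
    gap_extend: int = 0
    substitution_matrix: str = "BLOSUM62"
    composition: tuple[float, float, float, float] = UNIFORM_COMPOSITION
    lambda_: float = 0.0
    k_param: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in {"nucleotide", "translated"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        # Per-mode gap defaults, chosen inside the local-alignment log
        # phase for the default scoring (cheaper gaps make random gapped
        # alignment scores grow linearly and void the E-value statistics).
        if self.gap_open == 0 and self.gap_extend == 0:
            if self.mode == "nucleotide":
                object.__setattr__(self, "gap_open", -12)
                object.__setattr__(self, "gap_extend", -8)
            else:
                object.__setattr__(self, "gap_open", -11)
                object.__setattr__(self, "gap_extend", -1)
        if self.lambda_ <= 0:
            if self.mode == "nucleotide":
                lam = solve_karlin_altschul(self.match, self.mismatch, self.composition)
            else:
                lam = _PROT_LAMBDA
            object.__setattr__(self, "lambda_", lam)
        if self.k_param <= 0:
            object.__setattr__(
                self,
                "k_param",
                DEFAULT_NT_K if self.mode == "nucleotide" else _PROT_K,
            )

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k_param)) / math.log(2.0)

    def e_value(self, raw: float, m: int, n: int) -> float:
        return self.k_param * m * n * math.exp(-self.lambda_ * raw)

    def submatrix(self) -> np.ndarray:
        if self.mode == "nucleotide":
            return _nt_submatrix(self.match, self.mismatch)
        return _AA_SUB


@dataclass
class SearchJob:
    """One all-vs-all search: queries and subjects plus thresholds."""

    queries: Sequence[SequenceRecord]
    subjects: Sequence[SequenceRecord]
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    e_threshold: float = 1e-10
    seed_length: int = 11

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be > 0")
        if self.seed_length < 3:
            raise ValueError("seed_length too small")


# -- seeding -----------------------------------------------------------------


def _kmer_codes(codes: np.ndarray, k: int, n_letters: int, invalid: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, kmer integer values) of valid k-mers in codes."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    vals = np.zeros(n - k + 1, np.int64)
    bad = np.zeros(n - k + 1, bool)
    c = codes.astype(np.int64)
    for off in range(k):
        window = c[off : off + n - k + 1]
        vals = vals * n_letters + window
        bad |= window == invalid
    pos = np.nonzero(~bad)[0]
    return pos, vals[pos]


class _SeedIndex:
    """Sorted-array k-mer index over one encoded sequence."""

    def __init__(self, codes: np.ndarray, k: int, n_letters: int, invalid: int):
        pos, vals = _kmer_codes(codes, k, n_letters, invalid)
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.pos = pos[order]

    def lookup(self, qpos: np.ndarray, qvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return matched (query position, subject position) seed pairs."""
        lo = np.searchsorted(self.vals, qvals, "left")
        hi = np.searchsorted(self.vals, qvals, "right")
        counts = hi - lo
        mask = counts > 0
        if not mask.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        lo, counts = lo[mask], counts[mask]
        q_rep = np.repeat(qpos[mask], counts)
        # vectorized concatenation of the ranges [lo_i, lo_i + counts_i)
        ends = counts.cumsum()
        idx = np.ones(ends[-1], np.int64)
        idx[0] = lo[0]
        if lo.shape[0] > 1:
            idx[ends[:-1]] = lo[1:] - (lo[:-1] + counts[:-1] - 1)
        return q_rep, self.pos[idx.cumsum()]


def _cluster_seeds(
    qpos: np.ndarray,
    spos: np.ndarray,
    diag_pad: int,
    split_gap: int,
    min_seeds: int = 1,
) -> list[tuple[int, int, int, int]]:
    """Group seed pairs into candidate windows.

    Returns (d_min, d_max, s_min, s_max) windows; seeds whose diagonals
    are within ``diag_pad`` of each other and whose subject positions are
    within ``split_gap`` belong to one window. Windows backed by fewer
    than ``min_seeds`` seeds are dropped (the two-hit heuristic).
    """
    if qpos.size == 0:
        return []
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    diag = diag[order]
    sp = spos[order]
    windows: list[tuple[int, int, int, int]] = []
    # first group by diagonal runs
    start = 0
    for i in range(1, diag.size + 1):
        if i == diag.size or diag[i] - diag[i - 1] > diag_pad:
            d_run = diag[start:i]
            s_run = np.sort(sp[start:i])
            # split the run on large subject-position gaps
            sub_start = 0
            for j in range(1, s_run.size + 1):
                if j == s_run.size or s_run[j] - s_run[j - 1] > split_gap:
                    if j - sub_start >= min_seeds:
                        windows.append(
                            (
                                int(d_run.min()),
                                int(d_run.max()),
                                int(s_run[sub_start]),
                                int(s_run[j - 1]),
                            )
                        )
                    sub_start = j
            start = i
    return windows


# -- alignment + traceback ---------------------------------------------------


def _traceback(q, s, sub, go, ge, d_lo, bi, bk, H, E, F):
    """Walk back from the best cell; returns coordinates and alignment stats.

    Returns (q_start, q_end, s_start, s_end, matches, mismatches,
    gap_opens, gap_chars) with 1-based inclusive DP coordinates.
    """
    i, k = bi, bk
    j = i + d_lo + k
    q_end, s_end = i, j
    matches = mismatches = gap_opens = gap_chars = 0
    while i > 0 and j > 0 and H[i, k] > 0:
        h = H[i, k]
        diag = H[i - 1, k] if i - 1 >= 0 else 0
        sc = sub[q[i - 1], s[j - 1]]
        if h == diag + sc:
            if q[i - 1] == s[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            continue
        if k >= 1 and h == E[i, k]:
            gap_opens += 1
            while True:
                gap_chars += 1
                opened = H[i, k - 1] - go
                if E[i, k] == opened:
                    j -= 1
                    k -= 1
                    break
                j -= 1
                k -= 1
            continue
        if k + 1 < H.shape[1] and h == F[i, k]:
            gap_opens += 1
            while True:
                gap_chars += 1
                opened = H[i - 1, k + 1] - go
                if F[i, k] == opened:
                    i -= 1
                    k += 1
                    break
                i -= 1
                k += 1
            continue
        break  # h == 0 start cell
    return i + 1, q_end, j + 1, s_end, matches, mismatches, gap_opens, gap_chars


def smith_waterman_score(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> int:
    """Optimal (unbanded) local-alignment score of two sequences."""
    scheme = scheme or ScoringScheme()
    if scheme.mode == "nucleotide":
        q, s = encode_nt(query), encode_nt(subject)
    else:
        q, s = encode_aa(query), encode_aa(subject)
    if len(q) == 0 or len(s) == 0:
        return 0
    best, *_ = banded_sw(
        q,
        s,
        scheme.submatrix(),
        -scheme.gap_open,
        -scheme.gap_extend,
        1 - len(q),
        len(s) - 1,
    )
    return int(best)


def _align_window(q, s, sub, scheme, d_lo, d_hi):
    best, bi, bk, H, E, F = banded_sw(
        q, s, sub, -scheme.gap_open, -scheme.gap_extend, d_lo, d_hi
    )
    if best <= 0:
        return None
    qs, qe, ss, se, ma, mi, gaps_open, gap_chars = _traceback(
        q, s, sub, -scheme.gap_open, -scheme.gap_extend, d_lo, bi, bk, H, E, F
    )
    aln_len = ma + mi + gap_chars
    return {
        "raw": int(best),
        "q_start": qs,
        "q_end": qe,
        "s_start": ss,
        "s_end": se,
        "matches": ma,
        "mismatches": mi,
        "gap_opens": gaps_open,
        "aln_len": aln_len,
    }


def _dedupe(results: list[dict]) -> list[dict]:
    """Drop hits whose subject interval largely duplicates a better one."""
    results.sort(key=lambda r: -r["raw"])
    kept: list[dict] = []
    for r in results:
        dup = False
        for other in kept:
            lo = max(r["abs_s_lo"], other["abs_s_lo"])
            hi = min(r["abs_s_hi"], other["abs_s_hi"])
            qlo = max(r["abs_q_lo"], other["abs_q_lo"])
            qhi = min(r["abs_q_hi"], other["abs_q_hi"])
            span = r["abs_s_hi"] - r["abs_s_lo"] + 1
            qspan = r["abs_q_hi"] - r["abs_q_lo"] + 1
            if (
                hi - lo + 1 > 0.5 * span
                and qhi - qlo + 1 > 0.5 * qspan
                and r["frame_key"] == other["frame_key"]
            ):
                dup = True
                break
        if not dup:
            kept.append(r)
    return kept


# -- nucleotide search -------------------------------------------------------

_EXHAUSTIVE_NT = 64  # full-DP mode for pairs at or below this length
_DIAG_PAD_NT = 16


def local_search(job: SearchJob) -> list[HitRecord]:
    """Seeded Smith-Waterman nucleotide search of queries against subjects.

    Both query strands are searched; a minus-strand alignment is reported
    with subject_start > subject_end. Every returned hit satisfies
    ``e_value <= job.e_threshold``; hits are sorted by (query id,
    ascending E-value).
    """
    if job.scheme.mode != "nucleotide":
        raise ValueError("local_search requires a nucleotide scheme")
    if not job.queries or not job.subjects:
        return []
    scheme = job.scheme
    sub = scheme.submatrix()
    k = job.seed_length
    n_total = sum(len(s) for s in job.subjects)

    subj_codes = [encode_nt(s.sequence) for s in job.subjects]
    indexes: list[_SeedIndex | None] = [None] * len(job.subjects)

    hits: list[HitRecord] = []
    for query in job.queries:
        m = len(query)
        results: list[dict] = []
        for strand in ("+", "-"):
            qseq = query.sequence if strand == "+" else query.reverse_complement().sequence
            qc = encode_nt(qseq)
            qpos_all, qvals = _kmer_codes(qc, k, 5, 4)
            for si, srec in enumerate(job.subjects):
                sc = subj_codes[si]
                n = sc.shape[0]
                if m <= _EXHAUSTIVE_NT and n <= _EXHAUSTIVE_NT:
                    windows = [(1 - m, n - 1, 0, n - 1)]
                else:
                    if qpos_all.size == 0:
                        continue
                    if indexes[si] is None:
                        indexes[si] = _SeedIndex(sc, k, 5, 4)
                    qp, sp = indexes[si].lookup(qpos_all, qvals)
                    windows = [
                        (d0 - _DIAG_PAD_NT, d1 + _DIAG_PAD_NT, s0, s1)
                        for d0, d1, s0, s1 in _cluster_seeds(
                            qp, sp, _DIAG_PAD_NT, max(200, m)
                        )
                    ]
                for d_lo, d_hi, _s0, _s1 in windows:
                    res = _align_window(qc, sc, sub, scheme, d_lo, d_hi)
                    if res is None:
                        continue
                    e = scheme.e_value(res["raw"], m, n_total)
                    if e > job.e_threshold:
                        continue
                    if strand == "+":
                        q_lo, q_hi = res["q_start"], res["q_end"]
                        s_start, s_end = res["s_start"], res["s_end"]
                    else:
                        q_lo = m - res["q_end"] + 1
                        q_hi = m - res["q_start"] + 1
                        s_start, s_end = res["s_end"], res["s_start"]
                    res.update(
                        subject_id=srec.id,
                        e_value=e,
                        abs_q_lo=q_lo,
                        abs_q_hi=q_hi,
                        abs_s_lo=min(s_start, s_end),
                        abs_s_hi=max(s_start, s_end),
                        rep_q=(q_lo, q_hi),
                        rep_s=(s_start, s_end),
                        frame_key=(srec.id, strand),
                    )
                    results.append(res)
        for r in _dedupe(results):
            hits.append(_to_hit(query.id, r, scheme))
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score, h.subject_id))
    return hits


def _to_hit(query_id: str, r: dict, scheme: ScoringScheme) -> HitRecord:
    pid = 100.0 * r["matches"] / max(1, r["aln_len"])
    return HitRecord(
        query_id=query_id,
        subject_id=r["subject_id"],
        percent_identity=round(pid, 2),
        alignment_length=r["aln_len"],
        mismatches=r["mismatches"],
        gap_opens=r["gap_opens"],
        query_start=r["rep_q"][0],
        query_end=r["rep_q"][1],
        subject_start=r["rep_s"][0],
        subject_end=r["rep_s"][1],
        e_value=r["e_value"],
        bit_score=round(scheme.bit_score(r["raw"]), 2),
        raw_score=r["raw"],
    )


# -- translated search -------------------------------------------------------

_EXHAUSTIVE_TR = 300  # nt length at or below which all frame pairs get full DP
_DIAG_PAD_AA = 8


# vectorized standard-code translation: codon index (4*16+4*4+4) -> aa code
_CODON_AA = np.empty(64, np.int8)
for _i0, _b0 in enumerate("ACGT"):
    for _i1, _b1 in enumerate("ACGT"):
        for _i2, _b2 in enumerate("ACGT"):
            _aa = str(Seq(_b0 + _b1 + _b2).translate())
            _CODON_AA[_i0 * 16 + _i1 * 4 + _i2] = _AA_LOOKUP[ord(_aa)]

_NT4_CODES = np.full(256, -1, np.int64)
for _i, _c in enumerate("ACGT"):
    _NT4_CODES[ord(_c)] = _i


def _translate_codes(nt_codes: np.ndarray, offset: int) -> np.ndarray:
    """Translate encoded nucleotides from ``offset`` into aa codes
    (ambiguous codons become X)."""
    n = (nt_codes.shape[0] - offset) // 3
    if n <= 0:
        return np.empty(0, np.int8)
    c = nt_codes[offset : offset + 3 * n].reshape(n, 3)
    bad = (c < 0).any(axis=1)
    idx = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    aa = _CODON_AA[np.where(bad, 0, idx)]
    aa[bad] = _AA_X
    return aa


def _frames_codes(seq: str) -> list[tuple[int, np.ndarray]]:
    """Six-frame translation as encoded aa arrays; frames +1..+3, -1..-3."""
    fwd = _NT4_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    rev = np.where(fwd[::-1] >= 0, 3 - fwd[::-1], -1)
    out: list[tuple[int, np.ndarray]] = []
    for f in range(3):
        out.append((f + 1, _translate_codes(fwd, f)))
        out.append((-(f + 1), _translate_codes(rev, f)))
    return out


def _aa_to_nt(frame: int, aa_start: int, aa_end: int, nt_len: int) -> tuple[int, int]:
    """Map a 1-based aa interval in a reading frame to ascending nt coords."""
    f = abs(frame) - 1
    if frame > 0:
        return f + 3 * (aa_start - 1) + 1, f + 3 * aa_end
    return nt_len - f - 3 * aa_end + 1, nt_len - f - 3 * (aa_start - 1)


class TranslatedDatabase:
    """Six-frame translations plus one combined seed index over a subject
    set, built once and reusable across many :func:`translated_search`
    calls.

    The six-frame translations of all subjects are laid out in one
    virtual coordinate space (one segment per (subject, frame)); a single
    sorted-array k-mer index over that space turns seeding into one
    lookup per query frame.
    """

    def __init__(self, subjects: Sequence[SequenceRecord], seed_length: int = 5):
        self.subjects = list(subjects)
        self.seed_length = seed_length
        self.n_total = sum(len(s) // 3 for s in self.subjects)
        self.segments: list[tuple[int, int, np.ndarray, int]] = []  # si, sf, codes, base
        base = 0
        all_pos: list[np.ndarray] = []
        all_vals: list[np.ndarray] = []
        for si, srec in enumerate(self.subjects):
            for sf, codes in _frames_codes(srec.sequence):
                self.segments.append((si, sf, codes, base))
                pos, vals = _kmer_codes(codes, seed_length, 24, _AA_STOP)
                all_pos.append(pos + base)
                all_vals.append(vals)
                base += codes.shape[0] + 1  # +1 guard between segments
        self.bases = np.array([seg[3] for seg in self.segments], np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
        vals = np.concatenate(all_vals) if all_vals else np.empty(0, np.int64)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._pos = pos[order]

    def lookup(self, qpos: np.ndarray, qvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query positions, virtual subject positions) of all seed matches."""
        lo = np.searchsorted(self._vals, qvals, "left")
        hi = np.searchsorted(self._vals, qvals, "right")
        counts = hi - lo
        mask = counts > 0
        if not mask.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        lo, counts = lo[mask], counts[mask]
        q_rep = np.repeat(qpos[mask], counts)
        ends = counts.cumsum()
        idx = np.ones(ends[-1], np.int64)
        idx[0] = lo[0]
        if lo.shape[0] > 1:
            idx[ends[:-1]] = lo[1:] - (lo[:-1] + counts[:-1] - 1)
        return q_rep, self._pos[idx.cumsum()]


def translated_search(
    job: SearchJob,
    seed_length: int = 5,
    database: TranslatedDatabase | None = None,
    min_seeds: int = 2,
) -> list[HitRecord]:
    """All-frame protein-level comparison of nucleotide sequences (tBLASTX).

    All 6 x 6 reading-frame pairs are compared at protein level. Hits
    are reported in nucleotide coordinates of both sequences; an alignment
    whose strands differ has subject_start > subject_end. In seeded mode a
    candidate window needs ``min_seeds`` seed matches (two-hit heuristic);
    short sequence pairs are aligned exhaustively in every frame pair.
    A prebuilt :class:`TranslatedDatabase` over ``job.subjects`` may be
    passed to amortize subject translation and indexing.
    """
    if not job.queries or not job.subjects:
        return []
    scheme = job.scheme
    if scheme.mode != "translated":
        scheme = ScoringScheme(mode="translated")
    sub = _AA_SUB
    if database is None:
        database = TranslatedDatabase(job.subjects, seed_length)
    n_total = database.n_total

    hits: list[HitRecord] = []
    for query in job.queries:
        if len(query) < 3:
            continue
        m_aa = max(1, len(query) // 3)
        results: list[dict] = []

        def consider(qf, qc, seg_i, d_lo, d_hi):
            si, sf, saa, _base = database.segments[seg_i]
            srec = job.subjects[si]
            res = _align_window(qc, saa, sub, scheme, d_lo, d_hi)
            if res is None:
                return
            e = scheme.e_value(res["raw"], m_aa, n_total)
            if e > job.e_threshold:
                return
            q_nt = _aa_to_nt(qf, res["q_start"], res["q_end"], len(query))
            s_nt = _aa_to_nt(sf, res["s_start"], res["s_end"], len(srec))
            minus = (qf < 0) != (sf < 0)
            rep_s = (s_nt[1], s_nt[0]) if minus else s_nt
            res.update(
                subject_id=srec.id,
                e_value=e,
                abs_q_lo=q_nt[0],
                abs_q_hi=q_nt[1],
                abs_s_lo=s_nt[0],
                abs_s_hi=s_nt[1],
                rep_q=q_nt,
                rep_s=rep_s,
                frame_key=(srec.id, minus),
            )
            results.append(res)

        exhaustive_subjects = {
            si
            for si, srec in enumerate(job.subjects)
            if len(query) <= _EXHAUSTIVE_TR and len(srec) <= _EXHAUSTIVE_TR
        }
        for qf, qc in _frames_codes(query.sequence):
            if qc.shape[0] < 1 or int((qc != _AA_STOP).sum()) < seed_length:
                continue
            # exhaustive full-band DP for short pairs
            for seg_i, (si, sf, saa, _b) in enumerate(database.segments):
                if si in exhaustive_subjects and saa.shape[0] >= 1:
                    consider(qf, qc, seg_i, 1 - qc.shape[0], saa.shape[0] - 1)
            qpos_all, qvals = _kmer_codes(qc, seed_length, 24, _AA_STOP)
            if qpos_all.size == 0:
                continue
            qp, gp = database.lookup(qpos_all, qvals)
            if qp.size == 0:
                continue
            seg_of = np.searchsorted(database.bases, gp, "right") - 1
            for seg_i in np.unique(seg_of):
                si, sf, saa, base = database.segments[seg_i]
                if si in exhaustive_subjects:
                    continue
                m = seg_of == seg_i
                windows = _cluster_seeds(
                    qp[m], gp[m] - base, _DIAG_PAD_AA, max(100, qc.shape[0]),
                    min_seeds=min_seeds,
                )
                for d0, d1, _s0, _s1 in windows:
                    consider(qf, qc, int(seg_i), d0 - _DIAG_PAD_AA, d1 + _DIAG_PAD_AA)
        for r in _dedupe(results):
            hits.append(_to_hit(query.id, r, scheme))
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score, h.subject_id))
    return hits


# -- best hits ---------------------------------------------------------------


def best_hits(hits: Iterable[HitRecord], min_bit_score: float = 80.0) -> dict[str, HitRecord]:
    """Single best hit per query, kept only if bit score strictly exceeds
    ``min_bit_score``. Ties are broken by lower E-value, then lexicographic
    subject id."""
    by_query: dict[str, HitRecord] = {}
    for h in sorted(hits, key=lambda h: (h.query_id, -h.bit_score, h.e_value, h.subject_id)):
        if h.query_id not in by_query:
            by_query[h.query_id] = h
    return {
        q: h for q, h in by_query.items() if h.bit_score > min_bit_score
    }
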