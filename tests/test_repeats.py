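"""Tiered repeat classification, MITE rules, SSR and k-mer scanners."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from besynt.io_formats import SequenceRecord
from besynt.repeats import (
    GENE_LABEL,
    KmerSpectrum,
    MiteCandidate,
    MiteRejection,
    canonical_motif,
    classify_repeats_tiered,
    estimate_copy_number,
    gene_te_correlation,
    kmer_spectrum,
    scan_ssrs,
    validate_mite,
)

RC = str.maketrans("ACGTN", "TGCAN")


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, rate):
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------
# classification


@pytest.fixture(scope="module")
def scenario():
    """Library with one Copia family; reads exercising all three passes."""
    rng = random.Random(101)
    element = random_dna(rng, 1500)
    flank = random_dna(rng, 1200)
    gene = random_dna(rng, 600)
    library = [SequenceRecord("copia1", element, "class=LTR_copia")]
    protein_db = [SequenceRecord("cds1", gene)]
    reads = [
        # direct library match -> conservative LTR_copia
        SequenceRecord("r_copia", mutate(rng, element[300:995], 0.05)),
        # element tail + flank: classified via its 400-bp element part
        SequenceRecord("r_edge", element[1100:1500] + flank[:295]),
        # pure flank, overlapping r_edge's flank: only the internal pass
        # can label this one
        SequenceRecord("r_internal", flank[100:795]),
        # gene-like read
        SequenceRecord("r_gene", gene + random_dna(rng, 95)),
        # nothing at all
        SequenceRecord("r_none", random_dna(rng, 695)),
    ]
    return classify_repeats_tiered(reads, library, protein_db)


class TestClassification:
    def test_direct_copy_is_conservative_copia(self, scenario):
        assert scenario.labels["r_copia"]["conservative"] == "LTR_copia"

    def test_internal_pass_inherits_label_only_in_comprehensive_tier(self, scenario):
        assert scenario.labels["r_internal"]["conservative"] is None
        assert scenario.labels["r_internal"]["comprehensive"] == "LTR_copia"

    def test_gene_like_reads_excluded_from_repeat_totals(self, scenario):
        assert scenario.labels["r_gene"]["conservative"] == GENE_LABEL
        totals = scenario.table.loc["Total"]
        assert totals["count_conservative"] == 2  # r_copia, r_edge
        assert totals["count_comprehensive"] == 3  # + r_internal

    def test_unmatched_read_stays_unlabelled(self, scenario):
        assert scenario.labels["r_none"]["comprehensive"] is None

    def test_tier_nesting(self, scenario):
        for labels in scenario.labels.values():
            if labels["conservative"] is not None:
                assert labels["comprehensive"] == labels["conservative"]

    def test_percent_repeats_columns_sum_to_100(self, scenario):
        assert scenario.percent_repeats_sum("conservative") == pytest.approx(100, abs=0.1)
        assert scenario.percent_repeats_sum("comprehensive") == pytest.approx(100, abs=0.1)

    def test_equal_score_tie_assigned_superclass_unclassified(self):
        rng = random.Random(7)
        shared = random_dna(rng, 400)
        library = [
            SequenceRecord("a", shared + random_dna(rng, 600), "class=LTR_copia"),
            SequenceRecord("b", shared + random_dna(rng, 600), "class=LTR_gypsy"),
        ]
        read = [SequenceRecord("r", shared)]
        result = classify_repeats_tiered(read, library, [])
        assert result.labels["r"]["conservative"] == "LTR_unclassified"

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError):
            classify_repeats_tiered([], [], [])


# ---------------------------------------------------------------------------
# MITE validation


class TestValidateMite:
    @staticmethod
    def build_mite(rng, length=358, tir_len=26, at=0.688):
        def at_dna(n):
            return "".join(
                rng.choices("ATGC", weights=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2], k=n)
            )
        lo, hi = (0.66, 1.0) if at > 0.65 else (0.0, 0.60)
        while True:
            tir = at_dna(tir_len)
            internal = at_dna(length - 2 * tir_len)
            seq = tir + internal + tir.translate(RC)[::-1]
            frac = (seq.count("A") + seq.count("T")) / len(seq)
            if lo < frac <= hi:
                return seq

    def test_planted_element_accepted(self):
        rng = random.Random(0)
        seq = self.build_mite(rng)
        tsd = "TAACG"
        flanks = (random_dna(rng, 20) + tsd, tsd + random_dna(rng, 20))
        result = validate_mite(seq, flanks)
        assert isinstance(result, MiteCandidate)
        assert result.length == 358
        assert result.tir_length >= 26
        assert result.tsd == tsd
        assert result.at_fraction > 0.65

    def test_missing_tsd_rejected_with_reason(self):
        rng = random.Random(1)
        seq = self.build_mite(rng)
        result = validate_mite(seq, (random_dna(rng, 25), random_dna(rng, 25)))
        assert isinstance(result, MiteRejection)
        assert result.reason == "no TSD"

    def test_low_at_rejected(self):
        rng = random.Random(2)
        seq = self.build_mite(rng, at=0.50)
        tsd = "ACGTA"
        result = validate_mite(seq, ("T" * 20 + tsd, tsd + "A" * 20))
        assert isinstance(result, MiteRejection)
        assert "A+T" in result.reason

    def test_at_exactly_at_threshold_rejected(self):
        # strict > 0.65: build a 400-bp element with exactly 260 A/T
        rng = random.Random(3)
        tir = "AT" * 13  # 26 bp, all A/T
        need_at = 260 - 52
        internal_len = 400 - 52
        internal = "A" * need_at + "G" * (internal_len - need_at)
        seq = tir + internal + tir.translate(RC)[::-1]
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert at == 0.65
        tsd = "ACG"
        result = validate_mite(seq, ("T" * 20 + tsd, tsd + "C" * 20))
        assert isinstance(result, MiteRejection)
        assert "A+T" in result.reason

    def test_length_out_of_range_rejected_first(self):
        result = validate_mite("AT" * 40, ("A" * 15, "T" * 15))
        assert isinstance(result, MiteRejection)
        assert "length" in result.reason

    def test_no_tir_rejected(self):
        rng = random.Random(4)
        seq = "".join(rng.choices("AT", k=300))
        # destroy any terminal inverted repeat structure deterministically
        seq = "A" * 40 + seq[40:-40] + "A" * 40
        result = validate_mite(seq, ("C" * 15, "G" * 15))
        if isinstance(result, MiteRejection):
            assert "inverted repeat" in result.reason or "TSD" in result.reason

    def test_short_flanks_are_a_precondition_error(self):
        with pytest.raises(ValueError):
            validate_mite("AT" * 100, ("ACGT", "ACGT"))


# ---------------------------------------------------------------------------
# copy-number extrapolation


class TestCopyNumber:
    def test_no_hits_gives_zero(self):
        assert estimate_copy_number(0, 1e6, 1e9).copies == 0

    def test_identity_sampling(self):
        est = estimate_copy_number(100, 5e6, 5e6)
        assert est.copies == 100 and est.sampling_fraction == 1.0

    def test_survey_scale_up(self):
        # 542 hits in a 48.25-Mbp sample of an 870-Mbp genome
        est = estimate_copy_number(542, 48.25e6, 870e6)
        assert est.copies == 9773
        assert est.sampling_fraction == pytest.approx(48.25 / 870, rel=1e-9)

    def test_genome_smaller_than_sample_warns(self):
        with pytest.warns(UserWarning):
            estimate_copy_number(10, 2e6, 1e6)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_copy_number(1, 0, 1e6)


# ---------------------------------------------------------------------------
# SSR scanning


def brute_force_ssrs(seq, min_units=4, min_length=12, mono_min=10, max_unit=5):
    """Independent SSR oracle: enumerate all starts and unit sizes."""

    def canon(m):
        rc = m.translate(RC)[::-1]
        return min(x[i:] + x[:i] for x in (m, rc) for i in range(len(x)))

    cands = []
    n = len(seq)
    for u in range(1, max_unit + 1):
        for a in range(n - 2 * u + 1):
            motif = seq[a : a + u]
            if "N" in motif:
                continue
            if a > 0 and a - 1 + u < n and seq[a - 1] == seq[a - 1 + u]:
                continue  # not the leftmost start of this run
            L = u
            while a + L < n and seq[a + L] == seq[a + L - u]:
                L += 1
            if L < 2 * u:
                continue
            if any(u % d == 0 and motif == motif[:d] * (u // d) for d in range(1, u)):
                continue  # non-primitive unit
            count = L // u
            used = u * count
            if u == 1:
                if used < mono_min:
                    continue
            elif count < min_units or used < min_length:
                continue
            cands.append((used, u, a, count, canon(motif)))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken = []
    for used, u, a, count, motif in cands:
        lo, hi = a + 1, a + used
        if all(hi < t[0] or lo > t[1] for t in taken):
            taken.append((lo, hi, u, count, motif))
    return sorted(taken)


class TestScanSsrs:
    def test_mono_run(self):
        rng = random.Random(1)
        seq = random_dna(rng, 100) + "A" * 15 + random_dna(rng, 100)
        (hit,), _ = scan_ssrs([SequenceRecord("x", seq)])
        assert (hit.motif, hit.unit_length, hit.repeat_count) == ("A", 1, 15)

    def test_dinucleotide_canonicalized(self):
        rng = random.Random(8)
        seq = random_dna(rng, 120) + "TC" * 10 + random_dna(rng, 120)
        hits, _ = scan_ssrs([SequenceRecord("x", seq)])
        di = [h for h in hits if h.unit_length == 2]
        assert di and di[0].motif == "AG"  # TC == GA == AG family

    def test_canonical_motif_identities(self):
        assert canonical_motif("AG") == canonical_motif("GA") == canonical_motif("CT") == canonical_motif("TC")
        assert canonical_motif("A") == canonical_motif("T") == "A"

    def test_below_threshold_runs_ignored(self):
        rng = random.Random(12)
        seq = random_dna(rng, 80) + "A" * 9 + random_dna(rng, 80) + "AT" * 3 + random_dna(rng, 80)
        hits, _ = scan_ssrs([SequenceRecord("x", seq)])
        assert hits == []

    def test_summary_per_mbp(self):
        rng = random.Random(2)
        seq = random_dna(rng, 400) + "A" * 20 + random_dna(rng, 400)
        _, summary = scan_ssrs([SequenceRecord("x", seq)])
        assert summary.loc["Mono", "count"] == 1
        assert summary.loc["Mono", "per_mbp"] == pytest.approx(1e6 / len(seq))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        # repeat-dense random sequence to exercise overlaps
        parts = []
        for _ in range(60):
            parts.append(random_dna(rng, rng.randint(5, 40)))
            motif = random_dna(rng, rng.randint(1, 5))
            parts.append(motif * rng.randint(2, 14))
        seq = "".join(parts)[:6000]
        hits, _ = scan_ssrs([SequenceRecord("x", seq)])
        mine = sorted((h.start, h.end, h.unit_length, h.repeat_count, h.motif) for h in hits)
        assert mine == brute_force_ssrs(seq)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=200))
    def test_property_matches_oracle(self, seq):
        hits, _ = scan_ssrs([SequenceRecord("x", seq)]) if seq else ([], None)
        mine = sorted((h.start, h.end, h.unit_length, h.repeat_count, h.motif) for h in hits)
        assert mine == brute_force_ssrs(seq)


# ---------------------------------------------------------------------------
# k-mer spectra


def naive_spectrum(reads, k, canonical=True):
    counts = Counter()
    for rec in reads:
        s = rec.sequence
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            if canonical:
                w = min(w, w.translate(RC)[::-1])
            counts[w] += 1
    hist = Counter(counts.values())
    return dict(hist), sum(counts.values())


class TestKmerSpectrum:
    def test_hand_counted_example(self):
        sp = kmer_spectrum([SequenceRecord("r", "AAAA")], k=2, canonical=False)
        assert sp.histogram == {3: 1} and sp.total_kmers == 3

    def test_total_conservation(self):
        rng = random.Random(5)
        reads = [SequenceRecord(f"r{i}", random_dna(rng, rng.randint(30, 200))) for i in range(30)]
        k = 9
        sp = kmer_spectrum(reads, k=k)
        assert sp.total_kmers == sum(len(r) - k + 1 for r in reads)
        assert sum(occ * mult for occ, mult in sp.histogram.items()) == sp.total_kmers

    def test_n_containing_windows_skipped(self):
        sp = kmer_spectrum([SequenceRecord("r", "AANAA")], k=2, canonical=False)
        assert sp.total_kmers == 2  # AA, AA

    @pytest.mark.parametrize("canonical", [True, False])
    def test_matches_naive_oracle(self, canonical):
        rng = random.Random(9)
        reads = [
            SequenceRecord(f"r{i}", random_dna(rng, rng.randint(20, 120)))
            for i in range(200)
        ]
        # inject duplicates so occurrence counts exceed 1
        reads += [SequenceRecord(f"d{i}", reads[0].sequence) for i in range(5)]
        sp = kmer_spectrum(reads, k=15, canonical=canonical)
        hist, total = naive_spectrum(reads, 15, canonical)
        assert sp.histogram == hist and sp.total_kmers == total

    def test_k_longer_than_reads_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            sp = kmer_spectrum([SequenceRecord("r", "ACGT")], k=10)
        assert sp.histogram == {} and sp.total_kmers == 0

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_spectrum([SequenceRecord("r", "ACGT")], k=1)


# ---------------------------------------------------------------------------
# gene density vs LTR density


class TestGeneTeCorrelation:
    @staticmethod
    def fake_contig(gene_frac, ltr_frac, n=20, n_bacs=12):
        labels = (
            [GENE_LABEL] * round(gene_frac * n)
            + ["LTR_copia"] * round(ltr_frac * n)
        )
        labels += [None] * (n - len(labels))
        return (n_bacs, labels)

    def test_exact_anticorrelation(self):
        data = {
            "c1": self.fake_contig(0.8, 0.1),
            "c2": self.fake_contig(0.5, 0.4),
            "c3": self.fake_contig(0.2, 0.7),
        }
        r, p, n = gene_te_correlation(data)
        assert r == pytest.approx(-1.0)
        assert n == 3

    def test_min_bacs_boundary(self):
        # a 9-BAC contig is excluded, a 10-BAC contig included
        data = {
            "c1": self.fake_contig(0.8, 0.1, n_bacs=12),
            "c2": self.fake_contig(0.5, 0.4, n_bacs=10),
            "c3": self.fake_contig(0.2, 0.7, n_bacs=11),
            "outlier": self.fake_contig(0.9, 0.9, n_bacs=9),
        }
        r, _p, n = gene_te_correlation(data, min_bacs=10)
        assert n == 3 and r == pytest.approx(-1.0)

    def test_independent_fractions_give_small_r(self):
        rng = np.random.default_rng(3)
        data = {}
        for i in range(200):
            # gene and LTR counts drawn independently of each other
            x = int(rng.binomial(40, 0.3))
            y = int(rng.binomial(40, 0.2))
            labels = [GENE_LABEL] * x + ["LTR_copia"] * y + [None] * (80 - x - y)
            data[f"c{i}"] = (15, labels)
        r, _p, n = gene_te_correlation(data)
        assert n == 200 and abs(r) < 0.2

    def test_zero_variance_is_an_error(self):
        data = {f"c{i}": self.fake_contig(0.5, 0.2) for i in range(5)}
        with pytest.raises(ValueError, match="variance"):
            gene_te_correlation(data)

    def test_too_few_contigs_is_an_error(self):
        with pytest.raises(ValueError):
            gene_te_correlation({"c1": self.fake_contig(0.5, 0.2)})
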