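"""Genome-evolution, repeat-landscape and BAC-library simulators."""

import math
from collections import Counter

import numpy as np
import pytest

from besynt.io_formats import Genome
from besynt.repeats import MiteCandidate, scan_ssrs, validate_mite
from besynt.synthetic_data import (
    BRANCHES,
    TAXA,
    BacLibraryPlan,
    EvolutionPlan,
    simulate_bac_library,
    simulate_phylogenomes,
    simulate_repeat_landscape,
)

from conftest import random_dna


class TestPhylogenomes:
    def test_no_evolution_limit(self):
        # all rates zero, full retention: identical gene content everywhere,
        # three homeologous copies per gene in the triplicated clade
        plan = EvolutionPlan(
            seed=1, branch_substitutions={b: 0.0 for b in BRANCHES},
            homeolog_retention=1.0,
        )
        genomes, truth = simulate_phylogenomes(plan, n_blocks=3, genes_per_block=4)
        for anc_id, per_taxon in truth.gene_lineage.items():
            assert set(per_taxon) == set(TAXA)
            for taxon in ("Amborella", "Oryza"):
                assert len(per_taxon[taxon]) == 1
            for taxon in ("Vitis", "Populus", "Arabidopsis"):
                assert len(per_taxon[taxon]) == 3
        # zero substitution: every copy's sequence equals the Amborella copy
        amb = genomes["Amborella"]
        vit = genomes["Vitis"]
        amb_seq = {g.gene_id: amb.gene_sequence(g) for g in amb.genes}
        for g in vit.genes:
            anc = g.gene_id.replace("Vitis_", "").rsplit("_S", 1)[0]
            assert vit.gene_sequence(g) == amb_seq[f"Amborella_{anc}"]

    def test_same_seed_identical_outputs(self):
        a, ta = simulate_phylogenomes(EvolutionPlan(seed=5), 4, 5)
        b, tb = simulate_phylogenomes(EvolutionPlan(seed=5), 4, 5)
        for taxon in TAXA:
            assert a[taxon].chromosomes == b[taxon].chromosomes
            assert a[taxon].genes == b[taxon].genes
        assert ta.block_presence == tb.block_presence

    def test_different_seed_differs(self):
        a, _ = simulate_phylogenomes(EvolutionPlan(seed=5), 3, 4)
        b, _ = simulate_phylogenomes(EvolutionPlan(seed=6), 3, 4)
        assert a["Amborella"].chromosomes != b["Amborella"].chromosomes

    def test_fractionation_truncated_binomial_mean(self):
        # retention 0.5 over ~1,000 post-triplication copies: surviving
        # copies per gene ~ Binomial(3, 0.5) truncated at >= 1, whose mean
        # is (3*0.5) / (1 - 0.5^3) = 12/7
        plan = EvolutionPlan(seed=9, homeolog_retention=0.5)
        genomes, truth = simulate_phylogenomes(plan, n_blocks=42, genes_per_block=8)
        n_genes = 42 * 8
        assert truth.post_triplication_genes == 3 * n_genes
        survivors = [
            len(truth.gene_lineage[anc]["Vitis"]) for anc in truth.gene_lineage
        ]
        assert all(1 <= s <= 3 for s in survivors)
        mean = np.mean(survivors)
        expected = 1.5 / (1 - 0.5**3)
        var = 24 / 7 - expected**2
        se = math.sqrt(var / n_genes)
        assert abs(mean - expected) < 3 * se

    def test_triplication_conservation(self):
        plan = EvolutionPlan(seed=2, homeolog_retention=0.7)
        _, truth = simulate_phylogenomes(plan, 5, 6)
        assert truth.post_triplication_genes == 3 * truth.triplication_entry_genes

    def test_planted_losses_reflected_in_truth(self):
        plan = EvolutionPlan(
            seed=3,
            branch_substitutions={b: 0.0 for b in BRANCHES},
            planted_losses={
                "Oryza": ("B1",),
                "Vitis+Populus+Arabidopsis": ("B2",),
            },
        )
        _, truth = simulate_phylogenomes(plan, 4, 6)
        assert truth.block_presence["B1"] == {
            "Amborella": True, "Oryza": False, "Vitis": True,
            "Populus": True, "Arabidopsis": True,
        }
        assert truth.block_presence["B2"] == {
            "Amborella": True, "Oryza": True, "Vitis": False,
            "Populus": False, "Arabidopsis": False,
        }

    def test_every_gene_keeps_at_least_one_copy_under_extreme_fractionation(self):
        plan = EvolutionPlan(seed=4, homeolog_retention=0.05)
        _, truth = simulate_phylogenomes(plan, 3, 5)
        for anc, per_taxon in truth.gene_lineage.items():
            assert len(per_taxon.get("Vitis", [])) >= 1

    def test_rearrangement_destroys_contiguity(self):
        plan = EvolutionPlan(
            seed=8,
            branch_rearrangements={"Oryza": 3.0},
        )
        _, truth = simulate_phylogenomes(plan, 6, 6)
        absent_in_oryza = sum(
            not truth.block_presence[b]["Oryza"] for b in truth.block_ids
        )
        all_present_elsewhere = all(
            truth.block_presence[b]["Populus"] for b in truth.block_ids
        )
        assert absent_in_oryza > 0 and all_present_elsewhere

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            EvolutionPlan(homeolog_retention=1.5)
        with pytest.raises(ValueError):
            EvolutionPlan(branch_gene_loss={"NotABranch": 0.1})
        with pytest.raises(ValueError):
            simulate_phylogenomes(EvolutionPlan(), n_blocks=0)


class TestRepeatLandscape:
    def test_zero_mix_leaves_genome_unchanged(self):
        rng = np.random.default_rng(1)
        base = Genome("g", {"chr1": random_dna(rng, 50_000)})
        out, truth = simulate_repeat_landscape(
            base, te_mix={}, seed=0, mite_copies_per_family=0, n_ssrs=0
        )
        assert out.chromosomes == base.chromosomes
        assert truth.insertions == [] and truth.ssrs == []

    def test_planted_mites_validate(self, repeat_landscape):
        _, genome, truth = repeat_landscape
        mites = [i for i in truth.insertions if i["kind"] == "MITE"]
        assert mites
        for ins in mites:
            chrom = genome.chromosomes[ins["chrom"]]
            body = chrom[ins["start"] - 1 : ins["end"]]
            flanks = (
                chrom[max(0, ins["start"] - 31) : ins["start"] - 1],
                chrom[ins["end"] : ins["end"] + 30],
            )
            result = validate_mite(body, flanks)
            assert isinstance(result, MiteCandidate), result

    def test_ltr_insertions_have_identical_terminal_repeats(self, repeat_landscape):
        _, genome, truth = repeat_landscape
        ltrs = [i for i in truth.insertions if i["class"].startswith("LTR")]
        assert ltrs
        for ins in ltrs:
            body = genome.chromosomes[ins["chrom"]][ins["start"] - 1 : ins["end"]]
            L = ins["ltr_length"]
            assert L >= 150 and body[:L] == body[-L:]

    def test_planted_ssrs_recovered_by_scanner(self, repeat_landscape):
        _, genome, truth = repeat_landscape
        hits, _ = scan_ssrs(genome.sequence_records())
        hit_spans = {
            (h.sequence_id, s)
            for h in hits
            for s in range(h.start, h.end + 1)
        }
        recovered = 0
        for ssr in truth.ssrs:
            mid = (ssr["start"] + ssr["end"]) // 2
            if (ssr["chrom"], mid) in hit_spans:
                recovered += 1
        assert recovered >= 0.95 * len(truth.ssrs)

    def test_insertions_avoid_genes(self):
        rng = np.random.default_rng(2)
        genes = [
            __import__("besynt.io_formats", fromlist=["GeneModel"]).GeneModel(
                f"g{i}", "chr1", 1 + i * 5000, 900 + i * 5000, "+"
            )
            for i in range(8)
        ]
        base = Genome("g", {"chr1": random_dna(rng, 60_000)}, genes)
        out, truth = simulate_repeat_landscape(base, seed=3)
        # gene sequences preserved verbatim at their shifted coordinates
        for g_old, g_new in zip(base.genes, out.genes):
            assert base.gene_sequence(g_old) == out.gene_sequence(g_new)

    def test_overfull_mix_rejected(self):
        rng = np.random.default_rng(3)
        base = Genome("g", {"chr1": random_dna(rng, 1000)})
        with pytest.raises(ValueError):
            simulate_repeat_landscape(base, te_mix={"LINE": 200.0})


class TestBacLibrary:
    def test_clone_count_and_coverage(self, bac_library):
        genome, _truth, plan, lib = bac_library
        expected = round(plan.coverage * genome.total_length / (plan.insert_mean_kb * 1000))
        assert len(lib.clones) == expected
        genomic = [c for c in lib.clones if not c.is_plastid]
        realized = sum(c.length for c in genomic) / genome.total_length
        assert abs(realized - plan.coverage) / plan.coverage < 0.10

    def test_bes_length_exactly_as_configured(self, bac_library):
        *_, lib = bac_library
        assert {len(r) for r in lib.bes} == {695}

    def test_reverse_bes_is_reverse_complement_of_insert_end(self, bac_library):
        genome, _t, _p, lib = bac_library
        clone = next(c for c in lib.clones if not c.is_plastid)
        rec = next(r for r in lib.bes if r.id == clone.clone_id + "_R")
        tail = genome.chromosomes[clone.chromosome][clone.end - 695 : clone.end]
        rc = tail.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        assert rec.sequence == rc

    def test_plastid_clones_form_one_dedicated_contig(self):
        # many small inserts so the binomial on the plastid fraction is tight
        rng = np.random.default_rng(7)
        base = Genome("g", {"chr1": random_dna(rng, 4_000_000)})
        plan = BacLibraryPlan(
            seed=9, insert_mean_kb=20, insert_sd_kb=2, shotgun_reads=0
        )
        lib = simulate_bac_library(base, plan)
        n_plastid = sum(c.is_plastid for c in lib.clones)
        rate = 100.0 * n_plastid / len(lib.clones)
        assert abs(rate - 1.6) <= 0.8
        assert set(lib.contigs["ctg_plastid"]) == {
            c.clone_id for c in lib.clones if c.is_plastid
        }

    def test_contigs_are_transitive_overlap_closures(self, bac_library):
        _g, _t, plan, lib = bac_library
        clones = {c.clone_id: c for c in lib.clones}
        for contig_id, members in lib.contigs.items():
            if contig_id == "ctg_plastid" or len(members) == 1:
                continue
            # every member reciprocally overlaps some other member
            for cid in members:
                a = clones[cid]
                assert any(
                    cid != other
                    and clones[other].chromosome == a.chromosome
                    and min(a.end, clones[other].end) - max(a.start, clones[other].start) + 1
                    >= plan.min_reciprocal_overlap * min(a.length, clones[other].length)
                    for other in members
                )

    def test_reads_traceable_to_exactly_one_source(self, bac_library):
        *_, lib = bac_library
        for rec in lib.bes + lib.shotgun:
            src = lib.read_sources[rec.id]
            assert src["plastid"] or (src["end"] - src["start"] + 1) == len(rec)

    def test_genome_too_short_rejected(self):
        rng = np.random.default_rng(1)
        base = Genome("g", {"chr1": random_dna(rng, 50_000)})
        with pytest.raises(ValueError):
            simulate_bac_library(base, BacLibraryPlan())

    def test_determinism(self):
        rng = np.random.default_rng(12)
        base = Genome("g", {"chr1": random_dna(rng, 1_500_000)})
        a = simulate_bac_library(base, BacLibraryPlan(seed=4, shotgun_reads=10))
        b = simulate_bac_library(base, BacLibraryPlan(seed=4, shotgun_reads=10))
        assert [c.__dict__ for c in a.clones] == [c.__dict__ for c in b.clones]
        assert [r.sequence for r in a.bes] == [r.sequence for r in b.bes]
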