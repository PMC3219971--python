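"""Seeded desk-scale simulator for everything the analysis consumes.

Three generators, each with full ground truth:

* :func:`simulate_phylogenomes` — five genomes descended from shared
  ancestral gene blocks on the fixed species tree
  ``(Amborella,(Oryza,(Vitis,(Populus,Arabidopsis))))``, with a planted
  whole-genome triplication (the gamma paleohexaploidy) on the stem of the
  eudicot clade followed by fractionation, plus per-branch substitution,
  rearrangement, stochastic gene loss and optional planted synteny-loss
  events.
* :func:`simulate_repeat_landscape` — LTR retrotransposons, LINEs, SINEs,
  DNA transposons, MITEs (with TIRs and target-site duplications) and SSR
  tracts inserted into a genome, together with the repeat library of
  family consensus sequences.
* :func:`simulate_bac_library` — a BAC clone library with fingerprint
  band counts, physical-map contigs from ground-truth clone overlap, BAC
  end sequences (BES), shotgun reads and plastid contamination.

Substitution uses a Jukes-Cantor process with codon-position rate weights
and in-frame stop codons repaired, so protein-level similarity decays
realistically with branch length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, Genome, SequenceRecord, ValidationError

__all__ = [
    "TAXA",
    "BRANCHES",
    "SPECIES_TREE_NEWICK",
    "EvolutionPlan",
    "BacLibraryPlan",
    "PhyloGroundTruth",
    "RepeatGroundTruth",
    "BacLibraryResult",
    "simulate_phylogenomes",
    "simulate_repeat_landscape",
    "simulate_bac_library",
    "DEFAULT_TE_MIX",
]

TAXA = ("Amborella", "Oryza", "Vitis", "Populus", "Arabidopsis")

SPECIES_TREE_NEWICK = "(Amborella,(Oryza,(Vitis,(Populus,Arabidopsis))));"

# Branch ids: terminals carry the taxon name; stems the '+'-joined clade.
BRANCHES = (
    "Amborella",
    "Oryza+Vitis+Populus+Arabidopsis",
    "Oryza",
    "Vitis+Populus+Arabidopsis",
    "Vitis",
    "Populus+Arabidopsis",
    "Populus",
    "Arabidopsis",
)

TRIPLICATION_BRANCH = "Vitis+Populus+Arabidopsis"

# (branch, clade tips) in pre-order; the evolve recursion follows this.
_TREE: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Amborella", ("Amborella",)),
    ("Oryza+Vitis+Populus+Arabidopsis", ("Oryza", "Vitis", "Populus", "Arabidopsis")),
    ("Oryza", ("Oryza",)),
    ("Vitis+Populus+Arabidopsis", ("Vitis", "Populus", "Arabidopsis")),
    ("Vitis", ("Vitis",)),
    ("Populus+Arabidopsis", ("Populus", "Arabidopsis")),
    ("Populus", ("Populus",)),
    ("Arabidopsis", ("Arabidopsis",)),
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Class mix defaults (percent of genome bases per leaf repeat class) follow
# the comprehensive-tier BES frequencies of the survey-read classification.
DEFAULT_TE_MIX: dict[str, float] = {
    "hAT": 2.41,
    "MuDR": 1.04,
    "CACTA": 0.11,
    "Helitron": 0.10,
    "DNA_other": 0.86,
    "LTR_copia": 13.79,
    "LTR_gypsy": 12.09,
    "LTR_unclassified": 4.13,
    "LINE": 11.60,
    "SINE": 0.26,
    "retro_unclassified": 5.82,
}

# (length, TIR length, A+T fraction) of the default planted MITE families,
# mirroring the three high-copy families of the survey.
DEFAULT_MITE_FAMILIES = (
    (358, 26, 0.688),
    (190, 19, 0.687),
    (516, 47, 0.752),
)

DEFAULT_SSR_MIX: dict[str, float] = {
    "A": 20.0,
    "AG": 35.0,
    "AT": 8.0,
    "AC": 5.0,
    "AAG": 6.0,
    "ATC": 4.0,
    "AAAT": 6.0,
    "AATG": 4.0,
    "AAAAG": 6.0,
    "AATGG": 6.0,
}


def _random_dna(rng: np.random.Generator, n: int, at_fraction: float = 0.5) -> str:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random coding sequence over the 61 sense codons, ATG-initiated."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


# codon-position substitution weights (purifying selection proxy)
_CODON_WEIGHTS = np.array([0.6, 0.3, 1.0])


def _mutate_cds(rng: np.random.Generator, seq: str, d: float) -> str:
    """Jukes-Cantor substitution at expected ``d`` subs/site, with
    codon-position rate weights and in-frame stop codons repaired."""
    if d <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.shape[0]
    weights = np.resize(_CODON_WEIGHTS, n)
    scale = weights / _CODON_WEIGHTS.mean()
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * d * scale / 3.0))
    hit = rng.random(n) < p_sub
    idx = np.nonzero(hit)[0]
    if idx.size:
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in idx:
            choices = base_codes[base_codes != arr[i]]
            arr[i] = rng.choice(choices)
    out = arr.tobytes().decode()
    # repair in-frame stops (selection against nonsense changes)
    codons = [out[i : i + 3] for i in range(0, len(out) - len(out) % 3, 3)]
    for ci, c in enumerate(codons):
        if c in _STOPS:
            repl = c
            while repl in _STOPS:
                repl = c[:2] + str(rng.choice(_BASES))
                if repl in _STOPS:
                    repl = str(rng.choice(_BASES)) + c[1:]
            codons[ci] = repl
    tail = out[len(codons) * 3 :]
    return "".join(codons) + tail


def _mutate_neutral(rng: np.random.Generator, seq: str, d: float) -> str:
    if d <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    idx = np.nonzero(rng.random(arr.shape[0]) < p_sub)[0]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in idx:
        choices = base_codes[base_codes != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Phylogenome simulation


@dataclass
class EvolutionPlan:
    """Parameters of the forward genome-evolution simulation.

    Rates are per branch of the fixed species tree (see :data:`BRANCHES`).
    ``branch_substitutions`` is expected substitutions/site;
    ``branch_rearrangements`` expected translocation breakpoints per block;
    ``branch_gene_loss`` the per-gene deletion probability.
    ``homeolog_retention`` is the probability that a post-triplication gene
    copy survives fractionation (at least one copy always survives).
    ``planted_losses`` maps a branch to ancestral block ids whose synteny
    is destroyed (all genes deleted) on that branch — ground truth for the
    parsimony mapping.
    """

    branch_substitutions: dict[str, float] = field(
        default_factory=lambda: {b: 0.05 for b in BRANCHES}
    )
    branch_rearrangements: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BRANCHES}
    )
    branch_gene_loss: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BRANCHES}
    )
    triplication: bool = True
    triplication_branch: str = TRIPLICATION_BRANCH
    homeolog_retention: float = 1.0
    rho_sigma: bool = False  # two extra duplications on the Oryza branch
    rho_sigma_retention: float = 0.3
    planted_losses: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gene_length_codons: int = 250
    spacer_bp: int = 300
    amborella_spacer_bp: int | None = None
    n_chromosomes: int = 3
    min_block_run: int = 4  # contiguous genes needed to score a block present
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.branch_gene_loss,):
            for b, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"gene-loss probability out of [0,1] on {b}")
        if not 0.0 <= self.homeolog_retention <= 1.0:
            raise ValueError("homeolog_retention must be in [0,1]")
        unknown = (
            set(self.branch_substitutions)
            | set(self.branch_rearrangements)
            | set(self.branch_gene_loss)
            | set(self.planted_losses)
        ) - set(BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")


@dataclass
class _GeneCopy:
    anc_id: str
    block_id: str
    subgenome: str | None
    strand: str
    seq: str
    uid: int


@dataclass
class PhyloGroundTruth:
    """Planted truth of the phylogenome simulation."""

    gene_lineage: dict[str, dict[str, list[str]]]
    block_presence: dict[str, dict[str, bool]]
    block_ids: list[str]
    planted_losses: dict[str, tuple[str, ...]]
    triplication_entry_genes: int
    post_triplication_genes: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def simulate_phylogenomes(
    plan: EvolutionPlan,
    n_blocks: int = 12,
    genes_per_block: int = 8,
) -> tuple[dict[str, Genome], PhyloGroundTruth]:
    """Forward-simulate five genomes from shared ancestral gene blocks.

    Returns the genomes keyed by taxon plus ground truth: the surviving
    copies of every ancestral gene per genome, and per-block synteny
    presence (a block counts as present when at least ``plan.min_block_run``
    of its genes remain contiguous on one chromosome).
    """
    if n_blocks < 1 or genes_per_block < 2:
        raise ValueError("need n_blocks >= 1 and genes_per_block >= 2")
    rng = np.random.default_rng(plan.seed)

    # ancestral genome: blocks dealt round-robin onto chromosomes
    block_ids = [f"B{i+1}" for i in range(n_blocks)]
    uid_counter = [0]

    def new_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0]

    chromosomes: list[list[_GeneCopy]] = [[] for _ in range(plan.n_chromosomes)]
    for bi, block in enumerate(block_ids):
        chrom = chromosomes[bi % plan.n_chromosomes]
        for gi in range(genes_per_block):
            anc_id = f"{block}g{gi+1}"
            chrom.append(
                _GeneCopy(
                    anc_id=anc_id,
                    block_id=block,
                    subgenome=None,
                    strand=rng.choice(["+", "-"]),
                    seq=_random_cds(rng, plan.gene_length_codons),
                    uid=new_uid(),
                )
            )

    trip_counts = {"entry": 0, "post": 0}

    def evolve_branch(state: list[list[_GeneCopy]], branch: str) -> list[list[_GeneCopy]]:
        state = [
            [
                _GeneCopy(g.anc_id, g.block_id, g.subgenome, g.strand, g.seq, g.uid)
                for g in chrom
            ]
            for chrom in state
        ]
        # planted synteny-loss events
        for block in plan.planted_losses.get(branch, ()):
            for chrom in state:
                chrom[:] = [g for g in chrom if g.block_id != block]
        # gamma triplication + fractionation
        if plan.triplication and branch == plan.triplication_branch:
            trip_counts["entry"] = sum(len(c) for c in state)
            tripled: list[list[_GeneCopy]] = []
            for sg in ("S1", "S2", "S3"):
                for chrom in state:
                    tripled.append(
                        [
                            _GeneCopy(g.anc_id, g.block_id, sg, g.strand, g.seq, new_uid())
                            for g in chrom
                        ]
                    )
            trip_counts["post"] = sum(len(c) for c in tripled)
            state = _fractionate(tripled, plan, rng)
        if plan.rho_sigma and branch == "Oryza":
            for retention in (plan.rho_sigma_retention,) * 2:
                doubled = [
                    [
                        _GeneCopy(g.anc_id, g.block_id, g.subgenome, g.strand, g.seq, new_uid())
                        for g in chrom
                    ]
                    for chrom in state
                ]
                state = state + doubled
                keep_p = retention
                for ci, chrom in enumerate(state[len(state) // 2 :], len(state) // 2):
                    state[ci] = [g for g in chrom if rng.random() < keep_p]
        # stochastic gene loss
        p_loss = plan.branch_gene_loss.get(branch, 0.0)
        if p_loss > 0:
            for chrom in state:
                chrom[:] = [g for g in chrom if rng.random() >= p_loss]
        # rearrangement: translocate random gene segments between chromosomes
        rate = plan.branch_rearrangements.get(branch, 0.0)
        n_events = rng.poisson(rate * n_blocks) if rate > 0 else 0
        for _ in range(n_events):
            occupied = [ci for ci, c in enumerate(state) if len(c) >= 2]
            if not occupied:
                break
            src = int(rng.choice(occupied))
            chrom = state[src]
            a = int(rng.integers(0, len(chrom)))
            b = int(rng.integers(a + 1, len(chrom) + 1))
            segment = chrom[a:b]
            del chrom[a:b]
            if rng.random() < 0.5:  # inversion
                segment = [
                    _GeneCopy(
                        g.anc_id, g.block_id, g.subgenome,
                        "-" if g.strand == "+" else "+", g.seq, g.uid,
                    )
                    for g in reversed(segment)
                ]
            dst = int(rng.integers(0, len(state)))
            pos = int(rng.integers(0, len(state[dst]) + 1))
            state[dst][pos:pos] = segment
        # substitution
        d = plan.branch_substitutions.get(branch, 0.0)
        if d > 0:
            for chrom in state:
                for g in chrom:
                    g.seq = _mutate_cds(rng, g.seq, d)
        return state

    # walk the pectinate tree: evolve from the root state down each branch
    amb = evolve_branch(chromosomes, "Amborella")
    n1 = evolve_branch(chromosomes, "Oryza+Vitis+Populus+Arabidopsis")
    ory = evolve_branch(n1, "Oryza")
    n2 = evolve_branch(n1, "Vitis+Populus+Arabidopsis")
    vit = evolve_branch(n2, "Vitis")
    n3 = evolve_branch(n2, "Populus+Arabidopsis")
    pop = evolve_branch(n3, "Populus")
    ara = evolve_branch(n3, "Arabidopsis")
    tips = {
        "Amborella": amb,
        "Oryza": ory,
        "Vitis": vit,
        "Populus": pop,
        "Arabidopsis": ara,
    }

    genomes: dict[str, Genome] = {}
    gene_lineage: dict[str, dict[str, list[str]]] = {}
    for taxon, state in tips.items():
        spacer = plan.spacer_bp
        if taxon == "Amborella" and plan.amborella_spacer_bp is not None:
            spacer = plan.amborella_spacer_bp
        chrom_seqs: dict[str, str] = {}
        genes: list[GeneModel] = []
        for ci, chrom in enumerate(state):
            parts: list[str] = []
            pos = 0
            cname = f"{taxon}_chr{ci+1}"
            for g in chrom:
                gap = _random_dna(rng, spacer)
                parts.append(gap)
                pos += len(gap)
                gseq = g.seq if g.strand == "+" else g.seq.translate(_COMPLEMENT)[::-1]
                start = pos + 1
                parts.append(gseq)
                pos += len(gseq)
                gene_id = f"{taxon}_{g.anc_id}" + (f"_{g.subgenome}" if g.subgenome else "")
                if any(x.gene_id == gene_id for x in genes):
                    gene_id = f"{gene_id}_u{g.uid}"
                genes.append(
                    GeneModel(
                        gene_id, cname, start, pos, g.strand,
                        ancestral_block_id=g.block_id, subgenome=g.subgenome,
                    )
                )
                gene_lineage.setdefault(g.anc_id, {}).setdefault(taxon, []).append(gene_id)
            parts.append(_random_dna(rng, spacer))
            chrom_seqs[cname] = "".join(parts)
        genomes[taxon] = Genome(taxon, chrom_seqs, genes)

    block_presence = {
        block: {
            taxon: _block_present(tips[taxon], block, plan.min_block_run)
            for taxon in TAXA
        }
        for block in block_ids
    }
    truth = PhyloGroundTruth(
        gene_lineage=gene_lineage,
        block_presence=block_presence,
        block_ids=block_ids,
        planted_losses=dict(plan.planted_losses),
        triplication_entry_genes=trip_counts["entry"],
        post_triplication_genes=trip_counts["post"],
    )
    return genomes, truth


def _fractionate(
    tripled: list[list[_GeneCopy]], plan: EvolutionPlan, rng: np.random.Generator
) -> list[list[_GeneCopy]]:
    """Delete post-triplication copies, keeping >= 1 copy per gene.

    A block whose genes would all vanish is resampled (and this is rare
    under sensible retention); resampling is done gene-wise via the
    truncated-binomial survival pattern.
    """
    retention = plan.homeolog_retention
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for ci, chrom in enumerate(tripled):
        for gi, g in enumerate(chrom):
            by_gene.setdefault(g.anc_id, []).append((ci, gi))
    keep: set[tuple[int, int]] = set()
    for anc_id, positions in by_gene.items():
        while True:
            mask = rng.random(len(positions)) < retention
            if mask.any():
                break
        for (ci, gi), m in zip(positions, mask):
            if m:
                keep.add((ci, gi))
    return [
        [g for gi, g in enumerate(chrom) if (ci, gi) in keep]
        for ci, chrom in enumerate(tripled)
    ]


def _block_present(state: list[list[_GeneCopy]], block: str, min_run: int) -> bool:
    for chrom in state:
        run = 0
        prev_sg: str | None = None
        for g in chrom:
            if g.block_id == block and (run == 0 or g.subgenome == prev_sg):
                run += 1
                prev_sg = g.subgenome
                if run >= min_run:
                    return True
            elif g.block_id == block:
                run = 1
                prev_sg = g.subgenome
            else:
                run = 0
                prev_sg = None
    return False


# ---------------------------------------------------------------------------
# Repeat landscape


@dataclass
class RepeatGroundTruth:
    """Final-coordinate record of every planted repeat feature."""

    insertions: list[dict]  # chrom, start, end, class, family, kind
    ssrs: list[dict]  # chrom, start, end, motif, units
    library: list[SequenceRecord]

    def true_class(
        self, chrom: str, start: int, end: int, min_overlap: int = 100
    ) -> str | None:
        """Repeat class of a read interval: the class of the planted
        element with the largest overlap, provided that overlap reaches
        ``min_overlap`` bp — the span a homology-based survey counts as a
        read 'matching' that element."""
        best_cov = 0
        best_cls = None
        for ins in self.insertions:
            if ins["chrom"] != chrom:
                continue
            ov = min(end, ins["end"]) - max(start, ins["start"]) + 1
            if ov > best_cov:
                best_cov = ov
                best_cls = ins["class"]
        if best_cov >= min_overlap:
            return best_cls
        return None


_CLASS_LENGTHS: dict[str, tuple[int, int]] = {
    "hAT": (600, 2000),
    "MuDR": (800, 2500),
    "CACTA": (800, 2500),
    "Helitron": (800, 3000),
    "DNA_other": (500, 1500),
    "LTR_copia": (2000, 4500),
    "LTR_gypsy": (2500, 5000),
    "LTR_unclassified": (1500, 3500),
    "LINE": (1500, 4000),
    "SINE": (150, 350),
    "retro_unclassified": (800, 2500),
}


def simulate_repeat_landscape(
    genome: Genome,
    te_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    families_per_class: int = 2,
    max_divergence: float = 0.10,
    mite_families: Sequence[tuple[int, int, float]] = DEFAULT_MITE_FAMILIES,
    mite_copies_per_family: int = 12,
    n_ssrs: int = 60,
    ssr_mix: Mapping[str, float] | None = None,
    allow_gene_overlap: bool = False,
) -> tuple[Genome, RepeatGroundTruth]:
    """Insert a transposable-element / MITE / SSR landscape into a genome.

    ``te_mix`` gives target percentages of (original) genome bases per leaf
    repeat class; the default mirrors the comprehensive-tier class mix of
    the survey reads. LTR elements carry two identical terminal repeats,
    LINEs are 5'-truncated, MITEs get a TIR, a 2-10 bp TSD and A+T-rich
    bodies. Every insertion is recorded in the returned ground truth in
    final genome coordinates, together with the family-consensus repeat
    library.
    """
    te_mix = dict(DEFAULT_TE_MIX if te_mix is None else te_mix)
    if sum(te_mix.values()) > 100.0:
        raise ValueError("te_mix percentages must sum to <= 100")
    ssr_mix = dict(DEFAULT_SSR_MIX if ssr_mix is None else ssr_mix)
    rng = np.random.default_rng(seed)

    # family consensus library
    library: list[SequenceRecord] = []
    families: dict[str, list[dict]] = {}
    for cls, pct in te_mix.items():
        if pct <= 0:
            continue
        lo, hi = _CLASS_LENGTHS.get(cls, (500, 2000))
        fams = []
        for fi in range(families_per_class):
            length = int(rng.integers(lo, hi + 1))
            if cls.startswith("LTR"):
                ltr_len = int(rng.integers(150, 301))
                ltr = _random_dna(rng, ltr_len)
                internal = _random_dna(rng, max(50, length - 2 * ltr_len))
                consensus = ltr + internal + ltr
                fam = {"name": f"{cls}_fam{fi+1}", "consensus": consensus,
                       "ltr_len": ltr_len}
            else:
                consensus = _random_dna(rng, length)
                fam = {"name": f"{cls}_fam{fi+1}", "consensus": consensus}
            fams.append(fam)
            library.append(
                SequenceRecord(fam["name"], fam["consensus"], f"class={cls}")
            )
        families[cls] = fams

    # MITE families (TIR + AT-rich internal); also placed in the truth
    # library. Consensus A+T is rejection-sampled a little above the
    # family target so mutated copies stay on the AT-rich side of the
    # validation threshold.
    mite_fams: list[dict] = []
    for mi, (length, tir_len, at_frac) in enumerate(mite_families):
        while True:
            tir = _random_dna(rng, tir_len, at_fraction=at_frac)
            internal = _random_dna(rng, length - 2 * tir_len, at_fraction=at_frac)
            consensus = tir + internal + tir.translate(_COMPLEMENT)[::-1]
            realized_at = (consensus.count("A") + consensus.count("T")) / len(consensus)
            if realized_at >= max(0.67, at_frac - 0.005):
                break
        mite_fams.append(
            {"name": f"MITE_{mi+1}", "consensus": consensus, "tir_len": tir_len}
        )
        library.append(SequenceRecord(f"MITE_{mi+1}", consensus, "class=MITE"))

    chrom_names = list(genome.chromosomes)
    chrom_lens = genome.chromosome_lengths()
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_names}
    for g in genome.genes:
        genes_by_chrom[g.chromosome].append(g)

    def sample_position(chrom: str, ins_len: int) -> int:
        """0-based insertion point avoiding genes unless allowed."""
        L = chrom_lens[chrom]
        for _ in range(200):
            p = int(rng.integers(0, L))
            if allow_gene_overlap:
                return p
            ok = all(not (g.start - 1 <= p <= g.end) for g in genes_by_chrom[chrom])
            if ok:
                return p
        return int(rng.integers(0, L))

    total_len = genome.total_length
    chrom_p = np.array([chrom_lens[c] for c in chrom_names], float)
    chrom_p /= chrom_p.sum()

    events: list[dict] = []  # chrom, pos (0-based, original), seq, class, family, kind
    for cls, pct in te_mix.items():
        if pct <= 0:
            continue
        target = pct / 100.0 * total_len
        inserted = 0
        while inserted < target:
            fam = families[cls][int(rng.integers(0, len(families[cls])))]
            div = float(rng.uniform(0.0, max_divergence))
            if cls.startswith("LTR"):
                ltr_len = fam["ltr_len"]
                body = fam["consensus"]
                internal = _mutate_neutral(rng, body[ltr_len:-ltr_len], div)
                ltr = _mutate_neutral(rng, body[:ltr_len], div)
                copy = ltr + internal + ltr  # identical terminal repeats
            elif cls == "LINE":
                body = fam["consensus"]
                keep = int(len(body) * rng.uniform(0.3, 1.0))
                copy = _mutate_neutral(rng, body[-keep:], div)  # 5' truncation
            else:
                copy = _mutate_neutral(rng, fam["consensus"], div)
            chrom = str(rng.choice(chrom_names, p=chrom_p))
            pos = sample_position(chrom, len(copy))
            events.append(
                {"chrom": chrom, "pos": pos, "seq": copy, "class": cls,
                 "family": fam["name"], "kind": "TE", "tsd": 0,
                 "ltr": fam.get("ltr_len", 0) if cls.startswith("LTR") else 0}
            )
            inserted += len(copy)

    for fam in mite_fams:
        for _ in range(mite_copies_per_family):
            # young high-copy families: low divergence, TIRs conserved
            div = float(rng.uniform(0.0, 0.02))
            body = fam["consensus"]
            tl = fam["tir_len"]
            copy = body[:tl] + _mutate_neutral(rng, body[tl:-tl], div) + body[-tl:]
            chrom = str(rng.choice(chrom_names, p=chrom_p))
            pos = sample_position(chrom, len(copy))
            tsd_len = int(rng.integers(2, 11))
            events.append(
                {"chrom": chrom, "pos": pos, "seq": copy, "class": "MITE",
                 "family": fam["name"], "kind": "MITE", "tsd": tsd_len}
            )

    motifs = list(ssr_mix)
    motif_p = np.array([ssr_mix[m] for m in motifs], float)
    motif_p /= motif_p.sum()
    for _ in range(n_ssrs):
        motif = str(rng.choice(motifs, p=motif_p))
        units = int(rng.integers(max(5, 12 // len(motif)), 26))
        chrom = str(rng.choice(chrom_names, p=chrom_p))
        pos = sample_position(chrom, units * len(motif))
        events.append(
            {"chrom": chrom, "pos": pos, "seq": motif * units, "class": "SSR",
             "family": motif, "kind": "SSR", "tsd": 0, "units": units}
        )

    # apply insertions per chromosome in ascending original coordinate
    new_chroms: dict[str, str] = {}
    truth_ins: list[dict] = []
    truth_ssr: list[dict] = []
    gene_shift: dict[str, list[tuple[int, int]]] = {}
    for chrom in chrom_names:
        seq = genome.chromosomes[chrom]
        evs = sorted(
            (e for e in events if e["chrom"] == chrom), key=lambda e: e["pos"]
        )
        parts: list[str] = []
        cursor = 0
        out_len = 0
        shifts: list[tuple[int, int]] = []  # (original pos, cumulative added)
        for e in evs:
            p = e["pos"]
            tsd_len = e["tsd"]
            if tsd_len and p + tsd_len <= len(seq):
                target = seq[p : p + tsd_len]
                ins_seq = e["seq"] + target  # duplicates the target site
                cut = p + tsd_len
            else:
                ins_seq = e["seq"]
                cut = p
                tsd_len = 0
            chunk = seq[cursor:cut] if cut > cursor else ""
            parts.append(chunk)
            out_len += len(chunk)
            start_final = out_len + 1  # 1-based start of inserted element
            rec = {
                "chrom": chrom,
                "start": start_final,
                "end": start_final + len(e["seq"]) - 1,
                "class": e["class"],
                "family": e["family"],
                "kind": e["kind"],
                "tsd_length": tsd_len,
                "ltr_length": e.get("ltr", 0),
            }
            if e["kind"] == "SSR":
                truth_ssr.append(
                    {"chrom": chrom, "start": start_final,
                     "end": start_final + len(e["seq"]) - 1,
                     "motif": e["family"], "units": e["units"]}
                )
            else:
                truth_ins.append(rec)
            parts.append(ins_seq)
            out_len += len(ins_seq)
            cursor = max(cursor, cut)
            shifts.append((cursor, out_len - cursor))
        parts.append(seq[cursor:])
        new_chroms[chrom] = "".join(parts)
        gene_shift[chrom] = shifts

    def shifted(chrom: str, coord: int) -> int:
        add = 0
        for pos, cum in gene_shift[chrom]:
            if pos <= coord - 1:
                add = cum
            else:
                break
        return coord + add

    new_genes = [
        GeneModel(
            g.gene_id, g.chromosome, shifted(g.chromosome, g.start),
            shifted(g.chromosome, g.end), g.strand,
            g.ancestral_block_id, g.subgenome,
        )
        for g in genome.genes
    ]
    out = Genome(genome.name, new_chroms, new_genes)
    truth = RepeatGroundTruth(insertions=truth_ins, ssrs=truth_ssr, library=library)
    return out, truth


# ---------------------------------------------------------------------------
# BAC library


@dataclass
class BacLibraryPlan:
    """Parameters of the simulated BAC library and physical map."""

    coverage: float = 5.2
    insert_mean_kb: float = 123.0
    insert_sd_kb: float = 12.0
    bes_length_bp: int = 695
    bands_per_kb: float = 128.0 / 123.0
    band_noise_sd: float = 4.0
    plastid_fraction: float = 0.016
    plastid_length_bp: int = 160_000
    shotgun_reads: int = 500
    min_reciprocal_overlap: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.plastid_fraction < 1.0:
            raise ValueError("plastid_fraction must be in [0, 1)")


@dataclass
class Clone:
    clone_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    bands: int
    is_plastid: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BacLibraryResult:
    clones: list[Clone]
    contigs: dict[str, list[str]]  # contig id -> clone ids
    contig_of: dict[str, str]  # clone id -> contig id
    bes: list[SequenceRecord]
    shotgun: list[SequenceRecord]
    read_sources: dict[str, dict]  # read id -> {chrom,start,end,plastid,clone}
    plastid_contig: str | None

    def bes_by_contig(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        by_id = {r.id: r for r in self.bes}
        for contig, clone_ids in self.contigs.items():
            recs = []
            for cid in clone_ids:
                for suffix in ("_F", "_R"):
                    rid = cid + suffix
                    if rid in by_id:
                        recs.append(by_id[rid])
            out[contig] = recs
        return out

    def write_tables(self, clones_path: str | Path, membership_path: str | Path) -> None:
        with open(clones_path, "w") as fh:
            fh.write("clone_id\tchromosome\tstart\tend\tbands\tis_plastid\tcontig\n")
            for c in self.clones:
                fh.write(
                    f"{c.clone_id}\t{c.chromosome}\t{c.start}\t{c.end}\t"
                    f"{c.bands}\t{int(c.is_plastid)}\t{self.contig_of[c.clone_id]}\n"
                )
        with open(membership_path, "w") as fh:
            fh.write("read_id\tclone_id\tcontig_id\n")
            for r in self.bes:
                cid = r.id.rsplit("_", 1)[0]
                fh.write(f"{r.id}\t{cid}\t{self.contig_of[cid]}\n")


def simulate_bac_library(
    genome: Genome,
    plan: BacLibraryPlan,
    repeat_truth: RepeatGroundTruth | None = None,
) -> BacLibraryResult:
    """Simulate a BAC library, its physical-map contigs, BES and shotgun reads.

    Clone count is ``coverage * genome_length / insert_mean``; clone
    intervals are uniform (the partial-digest chemistry is not modelled).
    Contigs are the transitive closure of >= ``min_reciprocal_overlap``
    reciprocal clone overlap — a ground-truth stand-in for fingerprint
    assembly. A ``plastid_fraction`` of clones derive from a synthetic
    plastid sequence and form one dedicated contig.
    """
    rng = np.random.default_rng(plan.seed)
    insert_mean = plan.insert_mean_kb * 1000.0
    if genome.total_length < 10 * insert_mean:
        raise ValueError("genome too short for the configured insert size")
    chrom_names = [c for c in genome.chromosomes]
    chrom_lens = genome.chromosome_lengths()
    chrom_p = np.array([chrom_lens[c] for c in chrom_names], float)
    chrom_p /= chrom_p.sum()

    n_clones = int(round(plan.coverage * genome.total_length / insert_mean))
    plastid_seq = _random_dna(np.random.default_rng(plan.seed + 7), plan.plastid_length_bp)

    clones: list[Clone] = []
    read_sources: dict[str, dict] = {}
    bes: list[SequenceRecord] = []
    for i in range(n_clones):
        cid = f"clone{i+1:05d}"
        is_plastid = bool(rng.random() < plan.plastid_fraction)
        for _ in range(100):
            length = int(rng.normal(insert_mean, plan.insert_sd_kb * 1000.0))
            length = max(length, 20_000)
            if is_plastid:
                # circular molecule: wrap via doubled sequence
                if length >= plan.plastid_length_bp:
                    length = plan.plastid_length_bp
                start = int(rng.integers(0, plan.plastid_length_bp))
                seq = (plastid_seq * 2)[start : start + length]
                chrom, s1, e1 = "plastid", start + 1, start + length
                break
            chrom = str(rng.choice(chrom_names, p=chrom_p))
            if length > chrom_lens[chrom]:
                continue  # resample
            start = int(rng.integers(0, chrom_lens[chrom] - length + 1))
            seq = genome.chromosomes[chrom][start : start + length]
            s1, e1 = start + 1, start + length
            break
        else:
            raise RuntimeError("could not place clone")
        bands = max(1, int(round(length / 1000.0 * plan.bands_per_kb
                                 + rng.normal(0.0, plan.band_noise_sd))))
        clones.append(Clone(cid, chrom, s1, e1, bands, is_plastid))
        blen = min(plan.bes_length_bp, length)
        fwd = seq[:blen]
        rev = seq[-blen:].translate(_COMPLEMENT)[::-1]
        for suffix, rseq, rs, re_ in (
            ("_F", fwd, s1, s1 + blen - 1),
            ("_R", rev, e1 - blen + 1, e1),
        ):
            rid = cid + suffix
            bes.append(SequenceRecord(rid, rseq))
            src = {"chrom": chrom, "start": rs, "end": re_, "plastid": is_plastid,
                   "clone": cid, "true_class": None}
            if repeat_truth is not None and not is_plastid:
                src["true_class"] = repeat_truth.true_class(chrom, rs, re_)
            read_sources[rid] = src

    # contigs: union-find over reciprocal overlap (genomic clones only)
    parent = list(range(len(clones)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_chrom: dict[str, list[int]] = {}
    for idx, c in enumerate(clones):
        if not c.is_plastid:
            by_chrom.setdefault(c.chromosome, []).append(idx)
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: clones[i].start)
        for a_pos, ia in enumerate(idxs):
            ca = clones[ia]
            for ib in idxs[a_pos + 1 :]:
                cb = clones[ib]
                if cb.start > ca.end:
                    break
                ov = min(ca.end, cb.end) - cb.start + 1
                if ov >= plan.min_reciprocal_overlap * ca.length and (
                    ov >= plan.min_reciprocal_overlap * cb.length
                ):
                    union(ia, ib)

    groups: dict[int, list[int]] = {}
    for idx, c in enumerate(clones):
        if c.is_plastid:
            continue
        groups.setdefault(find(idx), []).append(idx)
    contigs: dict[str, list[str]] = {}
    contig_of: dict[str, str] = {}
    for gi, (_root, members) in enumerate(
        sorted(groups.items(), key=lambda kv: -len(kv[1]))
    ):
        name = f"ctg{gi+1:04d}"
        contigs[name] = [clones[i].clone_id for i in sorted(members)]
        for i in members:
            contig_of[clones[i].clone_id] = name
    plastid_contig = None
    plastid_members = [c.clone_id for c in clones if c.is_plastid]
    if plastid_members:
        plastid_contig = "ctg_plastid"
        contigs[plastid_contig] = plastid_members
        for cid in plastid_members:
            contig_of[cid] = plastid_contig

    # shotgun reads
    shotgun: list[SequenceRecord] = []
    for i in range(plan.shotgun_reads):
        chrom = str(rng.choice(chrom_names, p=chrom_p))
        L = min(plan.bes_length_bp, chrom_lens[chrom])
        start = int(rng.integers(0, chrom_lens[chrom] - L + 1))
        rid = f"sgs{i+1:05d}"
        shotgun.append(
            SequenceRecord(rid, genome.chromosomes[chrom][start : start + L])
        )
        src = {"chrom": chrom, "start": start + 1, "end": start + L,
               "plastid": False, "clone": None, "true_class": None}
        if repeat_truth is not None:
            src["true_class"] = repeat_truth.true_class(chrom, start + 1, start + L)
        read_sources[rid] = src

    return BacLibraryResult(
        clones=clones,
        contigs=contigs,
        contig_of=contig_of,
        bes=bes,
        shotgun=shotgun,
        read_sources=read_sources,
        plastid_contig=plastid_contig,
    )
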