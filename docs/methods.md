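# Methods

`besynt` implements the comparative-genomics workflow used to analyse a
survey-sequenced plant genome from a BAC-based physical map: reads are
classified against a repeat library in two tiers, non-repetitive BAC-end
sequences (BES) are anchored to annotated reference genomes through a
two-pass protein-level search, anchored contigs are scored for synteny,
losses of synteny are mapped onto a fixed species tree by Dollo
parsimony, and the distribution of best matches over post-triplication
subgenomes is used to time an ancient hexaploidy. Because survey data of
this kind are never accompanied by usable ground truth, the package
ships a forward simulator that generates every input the pipeline
consumes, with the truth of every planted feature retained.

## Local similarity search

All searches run on a built-in seeded Smith–Waterman engine
(`besynt.homology`) so that the pipeline's score and E-value thresholds
are exercisable without an external aligner. The engine is deliberately
narrow — queries are survey reads, subjects are libraries, genomes or
tracts — and sits behind a small interface so a production aligner could
be substituted.

**Nucleotide mode** seeds on exact 11-mers, clusters seeds by diagonal,
and runs banded affine-gap Smith–Waterman (band padding 16) around each
cluster; both query strands are searched, with minus-strand alignments
reported as `subject_start > subject_end`. Default scoring is the
relaxed +5/−4 match/mismatch used for diverged-repeat detection; gap
costs are open −12 / extend −8 (first gap character −12, each further
−8). Pairs of at most 64 bp are aligned by exhaustive full-band DP, so
at that scale the engine *is* exact Smith–Waterman.

**Translated mode** (tBLASTX-like) compares all 6 × 6 reading-frame
pairs at protein level with BLOSUM62, seeding on exact residue 5-mers
with a two-hit rule (a candidate window needs two seed matches), and
reports hits in nucleotide coordinates of both sequences. All six-frame
translations of a subject set are laid out in one virtual coordinate
space with a single sorted k-mer index (`TranslatedDatabase`), which can
be built once and reused across many searches. Gap costs are −11/−1
(BLOSUM62 convention). Pairs of at most 300 bp are aligned exhaustively
in every frame pair. Frames consisting (almost) entirely of stop codons
are skipped.

**Statistics.** Raw score S converts to E-value `K·m·n·exp(−λS)` and bit
score `(λS − ln K)/ln 2`, with m the query length and n the summed
subject length in search units. For nucleotide scoring, λ is the unique
positive root of the Karlin–Altschul identity
`Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1` under the background composition (uniform by
default), solved by Brent's method to residual < 1e-9; K defaults to
0.621. Translated mode uses the ungapped BLOSUM62 constants λ = 0.3176,
K = 0.134. The gap defaults matter: cheaper extensions (e.g. −2 with
+5/−4 matches) put the scoring system outside the logarithmic phase of
local alignment — random gapped alignment scores then grow linearly with
sequence length and the E-values lose meaning. The defaults here were
chosen inside the log phase; when overriding them, keep the expected
per-column score of a random gapped extension negative.

## Tiered repeat classification

`classify_repeats_tiered` reproduces the three-pass survey strategy:

1. reads vs. the class-annotated repeat library, nucleotide mode,
   +5/−4, E ≤ 1e-10; a read takes the leaf class of its best hit. This
   closes the **conservative** tier.
2. reads without a repeat hit vs. a coding-sequence database at protein
   level, E ≤ 1e-5 → labelled gene-like and excluded from the repeat
   denominators of both tiers.
3. still-unlabelled reads vs. the union of reads labelled in passes 1–2,
   nucleotide mode, E ≤ 1e-10, inheriting the matched read's label. This
   "internal" expansion runs for a single round — iterating it to
   transitive closure would let labels percolate without bound through
   chains of marginal similarity — and closes the **comprehensive**
   tier.

Ties between equal-scoring classes map to the nearest unclassified bin
(`LTR_unclassified`, `retro_unclassified`, `DNA_other`) and are logged.
Note that pass 3 can propagate a label through *positional* overlap
(two reads sharing a genomic locus of which only part is repetitive):
that is inherent to the internal-search design, and is one reason the
comprehensive tier is described as "possibly more permissive".

MITE validation accepts a candidate iff its length is within
[100, 800] bp, it carries a terminal inverted repeat of ≥ 15 bp at
≤ 10 % mismatch, an exact 2–10 bp target-site duplication is present in
the flanks (≥ 12 bp of context required per side), and the A+T fraction
strictly exceeds 0.65; the first failed rule is reported. Copy numbers
extrapolate by the plain sampling fraction,
`copies = round(hits × genome_bp / sampled_bp)`.

SSR scanning reports maximal exact tandem runs of primitive 1–5 bp
motifs (mononucleotide ≥ 10 bp; unit 2–5: ≥ 4 complete units and
≥ 12 bp), trimmed to complete units, with overlaps resolved
longest-first and motifs canonicalized to the minimal rotation over the
motif and its reverse complement (so AG ≡ GA ≡ CT ≡ TC). k-mer spectra
count canonical (strand-minimal) k-mers exactly, skipping windows that
contain N; k defaults to 20 and must be ≤ 27 (64-bit packing).

## Two-pass synteny anchoring

Pass 1 searches a contig's repeat-filtered BES against a reference
genome in translated mode and keeps per-BES best hits with bit score
strictly > 80. Any two hits from *distinct* BES whose subject loci
(subject-interval start coordinates) lie strictly less than 500 kb apart
on one chromosome seed a 4-Mbp tract centred on the midpoint of the pair
union, clipped to the chromosome; overlapping tracts of one contig are
merged (merged tracts may exceed 4 Mbp and are flagged). Pass 2
re-searches all the contig's BES against each tract; a qualifying hit is
a unique (BES, gene) pair with E ≤ 1e-4 whose subject interval overlaps
an annotated gene — multiple local alignments between one BES and one
gene count once — and the contig anchors iff it has ≥ 4 qualifying hits
to ≥ 3 distinct genes. Contig eligibility defaults to ≥ 39 clones
(configurable; the desk-scale scenarios below use smaller contigs and
disable the floor).

The subgenome-distribution test takes, per BES, the best protein-level
hit (E ≤ 1e-6) to a reference gene carrying an ancestral-block
assignment, and reports contigs matching ≥ 2 distinct genes together
with the set of distinct post-triplication subgenomes hit. Under
independent fractionation the probability that g independently retained
genes all present their best copy on the same subgenome falls off
geometrically (≈ 3^(1−g) at retention ½), which is why contigs with
≥ 5 gene matches essentially always span ≥ 2 subgenomes when the
triplication predates the outgroup divergence — and exactly 1 when the
reference was never triplicated.

## Block chaining

`chain_blocks` groups alignment blocks by (contig, reference chromosome),
sorts by reference start and single-links blocks whose reference-axis
gap (next start minus running maximum end; negative when overlapping) is
at most 100 kb; a chain is syntenic iff its summed score strictly
exceeds 100,000. Gaps are measured on the reference axis only, and
strand-mixed chains are allowed (inversions inside a syntenic region are
expected) but flagged. For small inputs the chains provably equal the
transitive closure of the pairwise gap relation; the test suite checks
this by brute force.

## Dollo parsimony of synteny loss

Each block (an Amborella physical-map contig) is assumed present in the
root ancestor; synteny, once destroyed, is not regained, so character
change is loss-only. For a given absence pattern the minimum loss set is
the set of stems of the maximal all-absent clades — each such stem
explains its clade with one loss, and no smaller set exists. This
placement is unique and automatically as deep as possible; note the
minimal loss *count* is not monotone under adding presences (making one
taxon of an all-absent clade present can split one stem loss into
several terminal losses).

## The synthetic-data generator

`simulate_phylogenomes` evolves ancestral gene blocks (default 8 genes
of 250 codons, separated by regenerated-random intergenic spacers) down
the fixed tree `(Amborella,(Oryza,(Vitis,(Populus,Arabidopsis))))`.
Substitution is Jukes–Cantor with codon-position rate weights
(0.6/0.3/1.0) and in-frame stop codons repaired — a cheap proxy for
purifying selection that keeps protein-level similarity informative at
the default 0.05 substitutions/site/branch (≈ 0.2 between the outgroup
and any ingroup tip). On the stem of (Vitis,(Populus,Arabidopsis)) every
block is triplicated into subgenomes S1–S3 and then fractionated: each
post-triplication copy survives with the homeolog-retention probability,
resampled so every gene keeps ≥ 1 copy. Optional extra duplications on
the Oryza branch are off by default. Rearrangement translocates random
gene segments between chromosomes (Poisson per branch, rate ×
block count); stochastic gene loss deletes genes independently; planted
synteny-loss events delete whole blocks on a named branch and are the
ground truth for the parsimony mapping. A block counts as present in a
tip when ≥ 4 of its genes remain contiguous (same subgenome copy) on one
chromosome. Intergenic spacers are regenerated independently per
lineage, i.e. treated as saturated — no conserved non-coding sequence is
modelled.

`simulate_repeat_landscape` inserts class-typical elements to target
percentages of genome bases (default mix follows the comprehensive-tier
class frequencies of the motivating survey, ≈ 52 % in total): LTR
elements with two *identical* terminal repeats (150–300 bp), LINEs as
5′-truncated bodies, MITEs with conserved TIRs, AT-rich bodies and an
exact 2–10 bp target-site duplication, plus SSR tracts drawn from an
AG-rich motif mix. Copies diverge from their family consensus by up to
10 % (MITEs ≤ 2 %, young-family assumption). Every insertion is recorded
in final coordinates. A read's ground-truth class is the class of the
planted element it overlaps most, provided the overlap is at least
100 bp — the span a homology survey scores as a read "matching" that
element.

`simulate_bac_library` draws `coverage × G / insert_mean` clones
uniformly (5.2×, 123 ± 12 kb by default; partial-digest chemistry is not
modelled), gives each a fingerprint band count
`round(kb × 128/123) + N(0, 4)`, forms contigs as the transitive closure
of ≥ 30 % reciprocal clone overlap (a ground-truth stand-in for
fingerprint assembly, which is out of scope), emits 695-bp BES from both
insert ends (reverse end reverse-complemented) and uniform shotgun
reads, and contaminates the library with clones drawn from a synthetic
160-kb circular plastid at fraction 0.016, all of which land in one
dedicated contig.

## Desk-scale scenarios

The acceptance script and the end-to-end tests run on scenarios sized so
each pipeline stage operates in the intended power regime while staying
at desk scale: structure recovery uses 108 blocks × 8 genes on 6
chromosomes (≈ 2 Mb outgroup genome, ≈ 80 clones, ≈ 6 contigs of 9–20
clones, ~14 anchor-competent BES per contig; references ≈ 0.9 Mb
untriplicated / 2.7 Mb triplicated); the subgenome test uses 72 blocks
at homeolog retention ½; repeat classification uses a 1.5-Mb host genome
carrying the default landscape (≈ 300 survey reads). Whole runs complete
in a few minutes on one CPU.

## What passing does and does not show

The generator plants exactly the structures the pipeline is built to
detect, under the stated idealizations: no indels within genes, no
conserved non-coding sequence, uniform clone coverage, ground-truth
contigs rather than fingerprint assembly, no sequencing error, and no
chimeric reads. Recovery and calibration results on it therefore
demonstrate internal correctness (thresholds, bookkeeping, statistics,
orientation handling) — not performance on real survey data, where
repeat libraries are incomplete, coverage is biased and physical maps
contain assembly errors.

## Known limitations

- E-values use ungapped Karlin–Altschul constants with gapped
  alignments; they are calibrated for ranking and thresholding at desk
  scale, not for literal expectation counts.
- The seeded search can miss homologies with no two seed matches in a
  window (translated mode) or none (nucleotide mode); exhaustive DP
  below the size caps is exact.
- The copy-number operation is the plain sampling-fraction scale-up; any
  family-level normalization beyond that must be applied by the caller.
- Dollo parsimony assumes a single origin at the root and is computed on
  the fixed five-taxon topology; arbitrary trees are supported by the
  implementation but only the fixed topology is exercised.
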