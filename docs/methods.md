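# Methods

This note documents the models, conventions and numerical choices behind
`lacfam`, and what the synthetic fixtures do and do not establish.

## Coordinates and formats

Gene models use GFF3 conventions: 1-based closed intervals, strand `+`/`-`.
These coordinates are stored verbatim on `GeneModel`; conversion to Python
slice indexing happens at a single point in each sequence-touching routine
(promoter extraction, site planting), which keeps the off-by-one surface
minimal. FASTA I/O goes through Biopython; motifs use the MEME minimal
format (read with `Bio.motifs`, written by `lacfam.io.write_meme`);
GFF3 here is gene-only with `ID=` attributes and is handled by a small
dedicated parser. All writers emit deterministically ordered rows, so a
fixed config yields byte-identical files.

## Identification funnel

Candidates are protein ids with ≥ 1 domain hit at e ≤ 0.001 (HMM stage),
unioned with query ids hitting a reference laccase at e ≤ 10⁻⁵ (similarity
stage). **All e-value thresholds are inclusive** (≤), uniformly. Redundancy
means isoforms of one locus: the longest isoform is kept (ties break
lexicographically by protein id). Near-identical copies at *different* loci
are retained deliberately — they are the duplication signal the downstream
analysis studies. Architecture verification requires a sub-cutoff hit for
every required domain; the default set is the three Cu-oxidase domains
characteristic of plant laccases. Naming ranks chromosomes by a
configurable order (default lexicographic), then start position, then gene
id; unplaced contigs sort after all named chromosomes.

## Physicochemical properties

Molecular weight is the average-isotopic sum of residue masses plus one
water (18.01524 Da), the ProtParam convention. pI solves
net-charge(pH) = 0 with Henderson–Hasselbalch terms for the two termini and
D, E, C, Y (acidic) and H, K, R (basic) side chains. The charge is strictly
decreasing in pH, so bisection on [0, 14] to 10⁻⁴ pH units finds the unique
root regardless of bracketing order. Default pK set is EMBOSS
(Nterm 8.6, Cterm 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1);
a commonly tabulated Bjellqvist set is selectable. Published pI/MW tables
for real proteomes depend on the exact tool and pK constants, so property
values are convention-dependent and not treated as a reproduction surface.

## Duplication criteria

Two member genes are tandem-linked iff they share a chromosome, at most 5
annotated genes (of any family — the standard MCScanX-style reading) lie
strictly between them in positional rank, and the containing fragment
(upstream gene start → downstream gene end) is ≤ 100 kb. Arrays are
connected components of this symmetric relation; ids `TA1, TA2, …` follow
(chromosome, leftmost start) order.

Segmental pairs require a global Needleman–Wunsch alignment (BLOSUM62, gap
open 10, extend 1, via Biopython's pairwise aligner) with coverage > 0.75
and similarity > 0.75, both **strict**, mirroring the "> 75 %" criteria;
e-value cutoffs, by contrast, are inclusive, mirroring "≤". Similarity is
identical columns over alignment columns with terminal-gap columns
excluded; coverage is the shorter sequence's aligned span as a fraction of
the longer (for a global alignment, the length ratio — which also provides
a cheap pre-filter that skips alignments that cannot pass). Tandem-linked
pairs are excluded from the segmental class. Requiring co-membership in a
detected collinear block is available but **off by default**: the two
stated criteria alone define the class, and block support is an optional
stricter mode.

Collinear blocks are maximal chains of anchor pairs, strictly monotone in
both genomes (ascending or descending), with inter-anchor gaps ≤ 25 gene
ordinals on both sides, found by longest-chain dynamic programming and
extracted greedily (longest chain first; ties break toward the
lexicographically smallest index sequence over anchors sorted by position).
Chains shorter than 5 anchors are discarded. For ≤ 12 anchors the DP is
tested against exhaustive chain enumeration.

Reciprocal best hits filter both directions at e ≤ 10⁻⁵ and break ties by
lower e-value, then higher identity, then subject id. Intersection counts
are Venn-style (exclusive) by default.

## Clade typing

Distances are p-distances over columns where neither sequence has a gap,
with the Kimura correction d = −ln(1 − p − 0.2 p²); saturated pairs (the
log argument ≤ 0) raise rather than silently truncating. Tree inference is
classical neighbor joining (Saitou–Nei Q-criterion, standard branch-length
and distance updates, deterministic smallest-(i, j) tie-breaking). NJ is
exact on additive matrices — the tests and the acceptance script verify
recovery of random additive tree metrics to < 10⁻⁹. NJ was chosen over
likelihood methods for desk-scale determinism: type assignment needs only
the topology, and bootstrap support is out of scope.

Typing midpoint-roots the tree (the published display is rooted but no
outgroup is stated), takes for each anchored type the smallest clade
containing all its anchors, and labels each member by the smallest
enclosing anchor clade; members inside none form the anchor-free type I.
Labels therefore partition the member set by construction.

## Expression and qPCR

The FPKM filter drops rows with mean **over all samples** < threshold
(mean exactly 1 is kept — the published rule deletes "< 1"); a per-year
grouping is available but not the default, since the filter is stated
without grouping. Heat-map standardization is a per-row z-score with sample
sd (n−1); the published figure does not state its scaling, so z-scoring is
recorded here as this package's choice. Constant rows map to zeros with a
warning. Peak-stage classification averages replicates and years within
stages and labels a gene `pre` iff its stage-mean argmax falls strictly
before the véraison stage, ties toward the earlier stage. 2^−ΔΔCt follows
the standard identities: the calibrator sample's fold change is exactly 1,
and one cycle less than the calibrator doubles the fold change.

## PWM scanning and exact p-values

Log-odds scores are log₂((p + c·bg)/((1 + c)·bg)) in bits with pseudocount
c = 0.1 spread proportionally to the background (FIMO convention). Scores
are rounded to a lattice of 10⁻³ bits; the exact distribution of the
lattice score of a background word is a width-fold convolution of 4-point
distributions, giving p(s) = P(score ≥ s) in O(w · range). On the lattice
the DP is *exact*: tests compare it to brute-force enumeration of all 4^w
words for w ≤ 6. Survival values are clipped at 1 so α = 1 always accepts
every window. Scanning scores both strands (the reverse-complement matrix
gets its own distribution, so non-symmetric backgrounds stay exact),
reports all overlapping hits at p ≤ α (default 10⁻⁵, the published
threshold, applied to p-values — FIMO's native semantics), and emits
reverse-strand hits at the forward window offset. No multiple-testing
correction is applied, matching FIMO defaults.

## Networks

Correlation edges carry Pearson r over matched samples and a two-sided p
from t = r√((n−2)/(1−r²)) with n−2 df; constant rows are dropped with a
warning. The correlation network keeps |r| ≥ 0.8 and p ≤ 0.05 by default —
the source analysis says only "significantly correlated", so these
thresholds are configurable package choices — with node weight = degree
(connectivity). The TF network takes the best p-value per (TF, target),
weighs edges by −log₁₀(p) (matching "line thickness by prediction
threshold"), optionally filters to differentially expressed TFs, and sets
node weight to the mean of incident edge weights ("average node weight").
Node weights recompute exactly from the edge table; there is no hidden
state.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the classifiers
assume: evidence tables with planted domain architectures and decoys,
chromosomes with planted tandem arrays (intra-array spacing 5 kb by
default) and isolated genes separated by ≥ 150 kb (safely beyond the
100-kb window), segmental partners built by substituting residues at rate
0.15 (identity ≈ 85 %, a deliberate margin above the 75 % threshold),
Gaussian-bump stage profiles with multiplicative log-normal noise
(sd 0.25) peaking before or after véraison, an exact planted fraction of
sub-threshold (mean < 1 FPKM) genes, metabolites built as
m = r·z_g + √(1−r²)·ε so the sample correlation converges to the target,
and consensus motif sites written at recorded promoter offsets/strands on
i.i.d. background. Default study sizes follow the published composition
arithmetic where one exists (115 of 119 candidates verified; 34 of 47
genes tandem; 30 of 46 segmental; 64 of 115 in clade III — the published
per-type counts sum to 118, so the fixture keeps the 64/115 clade-III
anchor and trims type II to 22).

Each fixture type draws from its own RNG stream derived from the seed by a
fixed offset, so adding one fixture never shifts another's draws, and a
fixed config yields byte-identical output files.

Not emulated: codon structure, introns/UTRs, realistic base or amino-acid
composition, evolutionary divergence processes, inter-gene expression
correlation structure, batch effects. Passing tests therefore demonstrate
the correctness of the classifiers and estimators under their stated
definitions — not robustness to annotation noise or to real genomes'
compositional quirks.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to keep the suites
quick while preserving the published arithmetic: 17 × 2.2-Mb chromosomes
for the identification funnel, one 6-Mb chromosome for the tandem fixture,
46 proteins of 480–600 residues (≈ 1000 pairwise alignments) for the
segmental fixture, 50 random additive matrices of 4–8 taxa for NJ, 20
random PWMs of width ≤ 6 against full enumeration, and 200 replicates of
the n = 300 correlation recovery (coverage pooled over all planted pairs,
checked against the 95 % Fisher-z band with a ≥ 93 % pass criterion).
Numerical tolerances: NJ metric recovery 10⁻⁹; PWM DP vs enumeration 10⁻⁹
on matched lattices; pI bisection 10⁻⁴ pH; z-score checks 10⁻¹².

## Known limitations

* Coverage for near-identical-length proteins equals the length ratio;
  alignments with large internal deletions are still counted by length
  ratio, which can overstate coverage in pathological cases.
* The Kimura-corrected distance is undefined for p ≳ 0.85; highly diverged
  alignments need a different correction.
* Greedy block extraction does not guarantee a globally optimal chain
  *partition* (it matches the exhaustive greedy oracle, not an ILP).
* The pI model ignores charge-state interactions and terminal-residue
  specific pK adjustments used by some tools.
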