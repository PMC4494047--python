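# Methods

This note documents the models and procedures `strainphy` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Assembly statistics

For each assembly the contigs are sorted by descending length; L50 is the
size of the shortest prefix whose summed length reaches half the assembly,
and N50 the length of the last contig in that prefix (ties in length are
kept in input order; they cannot change either value). The fragmentation
index is

    N50 ratio = ((n_contigs − L50) / L50) × n_contigs,

rounded to the nearest integer with halves away from zero. The index is 0
for a complete single-contig genome and grows with fragmentation; it is
reported as a dimensionless integer.

## Pangenome analysis

The ortholog matrix has one row per ortholog group and one column per
strain, each cell holding the number of CDS that strain contributes to the
group. Ortholog assignment itself is out of scope: the matrix comes from
the simulator's truth tables or from a user-supplied table produced by any
clustering tool.

A group present (count ≥ 1) in every strain is core, in exactly one strain
cloud, otherwise shell; pan = core + shell + cloud, an identity the report
object enforces at construction. The "total genes" of a group is its
maximum per-strain CDS count, so a family duplicated in some genome counts
its largest copy number once rather than a sum across strains — summing
across strains would inflate totals with the number of strains, while the
maximum reproduces the small, stable excess of genes over groups that
paralogs create.

Rarefaction draws, for every subset size i from 1 to N, up to 49 distinct
strain combinations (sampling with a seen-set so no combination repeats;
when fewer distinct combinations exist they are enumerated instead, and at
i = N the single combination is computed once) and records core and pan
sizes of the column-restricted matrix. Within any nested chain of subsets
core is non-increasing and pan non-decreasing, which the tests verify
against exhaustive enumeration at small N.

Strain clustering uses the Canberra distance between ortholog-count
columns, Σ |x−y|/(|x|+|y|) with 0/0 terms contributing nothing, and
complete-linkage agglomeration. Canberra is sensitive to presence/absence
differences regardless of copy-number magnitude, which is what
gene-content clustering is after.

## SNP calling

Whole genomes are compared through k-mer anchors: 21-mers that occur
exactly once in the reference and once in the query (k = 21 makes random
collisions negligible at megabase scale; k must be odd). The longest
collinear chain of anchors is kept per contig pair, and consecutive
anchors on the same diagonal merge into gap-free blocks whose inter-anchor
segments are compared position by position. Segments whose lengths differ
between the genomes contain indels and are excluded entirely — the
analysis is substitutions-only, so no attempt is made to call or anchor
across indels. Positions whose reference base is N are skipped; a strain
with no covering block at a position records a missing allele. The SNP
matrix is the union over strains of mismatch positions, each strain
contributing its own allele, so multi-allelic positions arise naturally.

The outermost 5 bases of every block are excluded from calling. A block
edge abuts an indel or a sequence end, and the bases at a deletion
junction can coincide with the first bases of the removed sequence — left
in, such a base masquerades as the allele of a locus the strain does not
carry and can fabricate a strain-specific SNP at a deleted gene's first
position. The trim converts those bases to missing data at a negligible
coverage cost (10 bp per block). Variants within one anchor length of a
contig end are likewise uncovered. Together these effects leave recall
slightly below 1 (~0.998 on the default simulation) at precision 1.0.

Pseudo-sequences concatenate each strain's alleles in position order
(missing → N), giving equal-length artificial sequences with one column
per SNP; these feed the distance-based phylogenetics.

## Effect classification

Each (position, non-reference allele) pair is classified against the CDS
annotation under bacterial translation table 11, strand-aware: outside
every CDS → noncoding; equal amino acids → synonymous; any non-synonymous
change in the annotated start codon → start lost; reference stop changed
away → stop lost; premature stop created → stop gained, with truncation
fraction = codon index / total codons; otherwise nonsynonymous. CDS whose
length is not a multiple of 3 are skipped with a warning. The test suite
checks the classifier against an oracle that translates the whole protein
before and after each of >1,000 random substitutions and diffs the result.

In per-group reports, a group whose uniform allele is the reference itself
is tabulated as synonymous by convention — relative to a reference drawn
from that group the site carries no change — while the classifier proper
always works per non-reference allele.

## Entropy-based group-specific markers

For a group G and one SNP position, H = −Σ p(xᵢ) log₂ p(xᵢ) over the
alleles of G's members is zero exactly when G is monomorphic there. H = 0
alone cannot make a marker diagnostic (a species-wide monomorphic site has
H = 0 in every group), so specificity additionally requires the group's
uniform state to occur in no strain outside G. Missing data anywhere at
the position disqualifies the call — a conservative choice: an unobserved
allele could always be the counterexample. Orthologs are treated
identically with CDS counts in place of alleles, thresholded to
presence/absence for the specificity call (copy-number entropy is still
reported); an ortholog can be specific-present (all of G, none outside) or
specific-absent (none of G, all outside).

## Distance methods and trees

**K2P.** With P and Q the transition and transversion fractions over sites
where both sequences have an unambiguous base (pairwise deletion),
d = −½ ln((1 − 2P − Q)√(1 − 2Q)). When the argument of either logarithm is
non-positive the pair is saturated; matrix construction aborts naming the
pair rather than imputing, since silent imputation would distort trees.

**Neighbor joining.** Saitou–Nei agglomeration on the Q-criterion with a
deterministic tie-break (lexicographically smallest pair of cluster
labels); negative intermediate branch lengths are clamped to zero; output
is unrooted with a final trifurcation. NJ is exact on additive matrices,
which the tests verify with an exhaustive least-squares topology oracle at
n = 5 and random additive matrices to n = 8.

**Bootstrap.** Alignment columns are resampled with replacement; each
replicate gets its own K2P + NJ tree; the support of an internal edge of
the full-data tree is the percentage of replicates containing the same
leaf bipartition. Replicates whose matrix saturates are skipped and
counted; more than 50 % failures aborts. Supports are reproducible under a
fixed seed.

**Tetranucleotide signatures.** Overlapping 4-mer counts are taken over
every contig plus its reverse complement (making the signature exactly
strand-symmetric), expected counts come from the maximal-order Markov
estimate E[w₁w₂w₃w₄] = n(w₁w₂w₃)·n(w₂w₃w₄)/n(w₂w₃) with the standard
variance approximation, and the 256 z-scores are compared between strains
by Pearson correlation (distance = 1 − r). Words containing N are skipped.
Signatures below ~50 kb of sequence draw a warning.

**Fragment ANI.** One genome is cut into consecutive 1,020 bp fragments
(a terminal piece shorter than 100 bp is dropped as uninformative). Each
fragment is placed on the other genome by k-mer seeding (15-mers every
8 bp voting for a diagonal; both strands tried), aligned end-free to the
seeded window with edlib, and the alignment path is rescored with +1
match, −1 mismatch, −2 per gap base; the maximal-scoring contiguous run of
columns is the fragment's local hit. Fragments are retained at ≥ 30 %
identity and ≥ 70 % query coverage of that hit; directional ANI is the
mean identity of retained fragments and the reported ANI averages both
directions. The local-rescoring step matters: plain edit-distance identity
over the whole fragment systematically underestimates ANI whenever a
fragment straddles a gene gained or lost in the other genome, whereas the
local hit either keeps the good side only (and the coverage filter drops
the straddler) or, for a region with no true counterpart, finds no
positive-scoring run at all. With it, measured ANI tracks the closed-form
expectation 100·(1 − p) of a p-divergent pair to within ±0.1 at 200 kb.
ANI > 95 % flags two genomes as conspecific, the conventional species
boundary.

**Tree comparison.** Robinson–Foulds distance = size of the symmetric
difference of internal-edge leaf bipartitions (canonicalized to the side
excluding a fixed reference leaf); 0 iff isomorphic.

## The synthetic-data generator

The generator produces the statistical structure the analyses assume: a
small number of named strain groups, each a clade, within-group divergence
below between-group divergence, gene content varying by gain and loss, and
a known set of group-diagnostic SNPs.

**Tree.** Group clades are random ultrametric bifurcating trees of height
0.3 × `tree_depth`, attached to a left-laddered backbone whose joins sit
between 0.55 × and 1 × `tree_depth` from the leaves; every root-to-leaf
path has the configured expected substitutions per site. Defaults: groups
of 10/6/1 strains (two major groups and one basal singleton — the shape a
two-group-plus-outlier strain collection presents), depth 0.02
substitutions/site. The depth is deliberately modest so that ANI between
groups stays above the 95 % species line while every tree method still
separates the groups cleanly; real within-species collections do not come
with published calibration values for this quantity, so the default is a
design choice, not an estimate.

**Genome.** A single-contig ancestor of 200 genes (~1 kb each, multiples
of 3, ATG start, no internal stop, table 11, random strand) separated by
intergenic spacers at GC 0.38 — desk-scale (~220 kb) rather than the
~1.8 Mb of a real genome, with the same relative structure. Substitutions
along each branch follow the K2P closed-form site probabilities at
transition/transversion ratio κ = 2. Gene loss removes a CDS and its
sequence from all descendants; gene gain inserts a novel de-novo CDS
(present in all descendants, appended after an N spacer so no spurious
SNPs arise at the insertion point); both run at 2 events per gene per unit
branch length, which on the default tree yields a clear core/shell/cloud
split (~70 % core). Optional within-genome duplication events exercise
paralog counting; the default rate is 0. There are no indels within
retained CDS, no recombination, no rate heterogeneity and no plasmids —
so passing recovery tests demonstrates correctness of the analysis logic
under the model's assumptions, not robustness to mechanisms the model
omits.

**Diagnostic SNPs.** 25 per group, injected after sequence evolution at
third positions of fourfold-degenerate codons of genes present in every
strain, at sites where all strains still agree at all three codon
positions; the group's members get the transition of the shared base.
Each marker is therefore synonymous, monomorphic inside its group and
absent outside it by construction, and the truth tables record all of
them together with the full aligned allele table.

**Reference.** The emitted reference is the simulated ancestor itself
(with its GFF). Anchoring at the ancestor keeps every truth coordinate
exact; analyses of real data would map against one strain instead, which
only relabels the reference allele at each position.

**Truth audit.** `TruthTables.group_fixed_positions` lists every variant
position whose fixation in a group the true alignment supports: uniform
among the group members that carry the site, and the allele absent from
all outside strains that carry it. Strains whose gene was lost constrain
nothing — the detector may legitimately observe a junction base at a
deletion boundary where the truth table has no allele, and such a call is
consistent with, not contradicted by, the truth. Detection results are
compared as: injected ⊆ detected (sensitivity 1) and detected ⊆ audit
(no contradicted calls).

## Pipeline and reproducibility

Stages run in the order simulate → stats → pangenome → snps → effects →
entropy → tetra → ani → tree → compare, each writing plain-text outputs
and an entry in the run log. Every stochastic stage derives its generator
from the global seed and the stage name (CRC-mixed, < 2³¹), so re-running
a single stage from saved intermediates reproduces the full run's output
bit for bit, and toggling one stage never perturbs another. The default
test suite and the acceptance script use reduced problem sizes (60-gene /
8-strain collections for most unit tests, the 200-gene / 17-strain default
for recovery checks, ANI on a 7-strain subset) — sizes chosen so the whole
validation cycle stays in the minutes range on a single core while every
statistical check retains comfortable margins.

## Known limitations

- The SNP caller assumes mostly collinear genomes; rearrangements would
  fragment chains and shrink coverage (reported as missing data, never as
  wrong calls).
- Ortholog inference is not performed; the pangenome stages are only as
  good as the supplied ortholog table.
- Tetra signatures are weak discriminators at low divergence; on the
  default simulation within-group correlations exceed between-group ones
  on average, but individual pairs overlap — matching the method's known
  behavior within a species.
- Saturated distance pairs abort tree construction by design; extremely
  diverged inputs need a different distance model, not a workaround.
- CDS annotations are assumed non-overlapping (true of the generator's
  output and typical bacterial tables); an overlapping annotation would
  have only its first-by-coordinate gene consulted per position.
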