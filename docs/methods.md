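# Methods notes

This note records the models, numerical choices and deliberate
simplifications behind each module, and what the synthetic-data generators
do and do not emulate.

## ANIb

ANIb follows the canonical fragment recipe: non-overlapping 1,020-base
windows (terminal remainder kept if ≥100 bases, dropped otherwise), best
local alignment of each fragment against the subject on either strand, hit
filter of ≥30% identity over ≥70% of the fragment length, one-way value =
mean identity of kept hits, pairwise value = arithmetic mean of the two
one-way values. Identity is counted over alignment columns *including* gap
columns, matching BLAST semantics; ambiguous bases (N and other IUPAC codes)
never count as identical. A one-way computation with no qualifying fragment
returns an explicit "no alignable fraction" marker (`None`), never 0, and
propagates as NaN in the all-vs-all matrix.

Searching each fragment against a whole genome with full Smith–Waterman is
quadratic and wasteful; the implementation first locates the candidate
subject window with exact 13-mer seeds (diagonals clustered within a 40-base
tolerance, window padded by 60 bases) and then runs Smith–Waterman (match
+1, mismatch −1, gap open −5, gap extend −2) on the window only. A fragment
sharing no 13-mer with the subject has no hit; for unrelated genomes stray
seeds produce only short local hits that the 70%-alignable filter removes.
The alignment backend sits behind a small internal module and can be swapped.

Genomospecies clustering uses single linkage (transitive closure of the
pairwise ≥95% rule) — the weakest partition consistent with a pairwise
species criterion; the threshold and linkage are explicit parameters. The
dendrogram uses distance 1 − r (Pearson correlation between ANI-matrix rows)
with average linkage; a genome whose row has zero variance makes the
correlation undefined and is reported by name.

## Pan-genome clustering

The 70/70 rule is evaluated on one BLOSUM62 local alignment (gap open −11,
extend −1) per unordered protein pair, emitted as two symmetric directed
hits; BLAST's slight query/subject asymmetry is not emulated. A shared-4-mer
prefilter (default ≥4 shared 4-mers, configurable, 0 disables) skips
hopeless pairs: at the 70% identity floor two proteins share ~35 expected
4-mers, so the prefilter cannot remove a qualifying pair.

Best hits are ranked by (score, identity, lexicographically smaller protein
id) for determinism. BDBH builds one cluster per reference protein from its
bidirectional best hits. COG-triangles forms mutually-consistent BBH
triangles across three genomes and merges triangles sharing an edge
(union–find). OMCL runs Markov clustering on the similarity graph with edge
weights min(score_ab, score_ba) — a simplification of OrthoMCL's
between-species normalization that preserves partition behaviour when
families are identity-separated. MCL numerics: self-loops set to the
per-column maximum weight, column normalization, expansion (matrix square) /
inflation (element-wise power, default 1.5) iterations, pruning below 1e-5,
convergence when the matrix changes by <1e-6 (cap 100 iterations, warning on
non-convergence); clusters are connected components of the limiting nonzero
structure, so the procedure is fully deterministic.

The pan-genome is the set of clusters with *identical member sets* in the
COGT and OMCL clusterings (the strictest reading of an intersection); the
consensus core additionally requires BDBH agreement and exactly one protein
per genome. Compartments: core = all genomes, soft-core = ≥95% of genomes
(and not core), cloud = one or two genomes, shell = the rest; the labels
partition the cluster set by construction.

Pathway profiling accepts a hit at ≥30% amino-acid identity; a coverage
requirement of ≥50% of the seed length is added to suppress domain-only
hits (set it to 0 for the bare identity rule). Pathway completeness is
purely set-theoretic over the seed list; gene-neighborhood inspection and
pseudogene calling are out of scope.

## Discovery curves

`sample_gene_discovery` draws random genome orderings (seeded NumPy
generator) and accumulates core/pan sizes with vectorized boolean scans.
Core fits use per-g means ("tettelin" tag); the "willenbrock" variant uses
per-g medians weighted by 1/var(g). At g = G every permutation gives the
same core and pan value, so the standard deviation is floored at 1e-3 before
being used as `curve_fit` sigma. Fit initialization: Ω₀ = last observed
value, κ₀ = first − last, τ₀ = G/3; bounds keep τ > 0 and the offset ≥ 0.
A constant curve short-circuits to κ=0, Ω=constant and is flagged
degenerate. New-gene fits exclude g = 1 (the first genome's "new genes" are
the whole genome, a core quantity the discovery model does not contain).
Pan extrapolation is cumulative: P(N) = P(G) + Σ_{g=G+1..N} n_new(g);
evaluating a core fit at any n is direct model evaluation, and the target n
is the caller's choice (absolute genome count).

## Phylogenetics

Neighbor joining is the standard Saitou–Nei agglomeration with the Q
criterion; ties are broken by the smallest (i, j) pair in the current
working matrix, negative branch lengths are clamped to zero with a warning,
and the final three nodes form a trifurcating root. On additive inputs the
tree reproduces the input distances exactly (tested against a
tree→distance→tree round trip and cross-checked against scikit-bio's NJ).
Jukes–Cantor distances skip columns where either sequence has a gap or an
ambiguous base and refuse p ≥ 0.75. Bootstrap resamples columns with
replacement; replicates with undefined distances are redrawn (capped at 10×
the replicate count); supports are matched by bipartition (canonical side =
the side not containing the lexicographically smallest taxon) and written as
internal-node labels.

Alignment trimming is a three-rule stand-in for Gblocks: keep columns with
non-gap fraction ≥0.5 and majority-residue fraction ≥0.5 (among non-gap
residues), then drop kept runs shorter than 5 columns; kept blocks are
recorded. Exact Gblocks reproduction is a non-goal. Multiple alignments are
inputs throughout: the synthetic paths emit gap-free equal-length panels and
the pairwise needs are served by the built-in global aligner, so no
multiple-alignment heuristic is bundled.

## 16S screening

Step-1 identity and coverage are computed from a local alignment of the
query against the fixed reference region (default positions 50–650, 1-based
inclusive): identity over alignment columns (gap-inclusive), coverage = the
fraction of region positions aligned to a query base. The region-relative
coverage convention is used because the screening query is the fixed
reference fragment; it is configurable. The identity boundary is inclusive
(≥99.6). Signature positions are mapped through a semi-global pairwise
alignment of the query to the full reference; a position aligned to a query
gap, beyond the query ends, or carrying an ambiguity code counts as
uncovered. Any covered mismatch → non-member; full coverage with all matches
→ member; otherwise not classifiable — the classifier deliberately prefers
missing strains to false positives. Queries shorter than 200 bases are not
classifiable. Genome-level reconciliation of disagreeing multi-copy 16S
genes is left to the caller; verdicts are per sequence.

The signature profile ships as an editable TSV (positions in the reference
record's own 1-based coordinates; any external numbering scheme is free-text
metadata). The species-specific 37-position profile is not reprinted here;
tests and demos use generator-planted profiles.

## Synthetic data

Generators are pure functions of (parameters, seed); each scenario derives
its own named RNG stream from the master seed, so adding a scenario never
perturbs another, and every generator serializes ground truth sufficient to
score its consumer.

*Genome pairs* are i.i.d.-uniform ancestors with substitutions-only
divergence (each substitution changes the base), keeping per-fragment
mismatch counts exact; there are no indels, rearrangements or compositional
structure, so passing ANIb tests demonstrates identity bookkeeping and
filter logic, not robustness to real genome architecture.

*Pan-genome occupancy* is exchangeable across genomes: Ω core clusters in
every genome; θ strain-specific clusters per genome; and M = κ/q shell
clusters with i.i.d. Bernoulli(q) membership, q = 1 − exp(−1/τ). Under any
random ordering the expected new-gene curve is then exactly
κ·e^{−(g−1)/τ} + θ and the expected core curve decays to Ω (shell clusters
are kept below full occupancy so core(G) = Ω exactly). This was chosen over
a sequential "new genes + retention" construction because the latter's
permutation-resampled new-gene curve flattens at (number of singleton
clusters)/G rather than θ, making the generating rate unrecoverable by the
very model the curves module fits. Defaults for the recovery study: Ω=3000,
θ=25, κ=2000, τ=3, 40 genomes, 100 permutations. The process carries no
phylogenetic correlation of gene content; only the asymptotics Ω and θ are
contractually meaningful.

*Protein families* mutate a random ancestor at per-site rate (1−w)/2 per
member, giving expected pairwise identity ≈ w within a family and random
background (~5%) between families; a declared separation gap (within-family
identity at least 0.2 above background) is enforced so clustering tests are
well-posed. Sequence length defaults to 150–180 residues — long enough for
stable alignment statistics, short enough to keep all-vs-all runs fast.

*16S panels* plant n signature positions in the 50–650 region of a random
~1.5-kb reference. In-group sequences mutate at most two non-signature
region sites (region identity stays above the 99.6% threshold); out-group
sequences diverge at ~3% of non-signature region sites, always miss one
designated position (so exactly one position is in-group-exclusive), miss
others at random, and every non-designated position is carried by at least
one out-group sequence. Real 16S features (secondary structure, hypervariable
region architecture, chimeras, multi-copy heterogeneity) are not modelled.

## Problem sizes in tests

The bundled tests and the acceptance script run at desk scale by design:
102-kb genome pairs for ANIb accuracy, a 113-genome planted ANI matrix, 5–31
proteome sets with 150–180-residue proteins, 40-genome occupancy matrices
with 100 orderings, 4–10-taxon trees, and 18-sequence 16S panels. These
sizes exercise every code path with exact ground truth; they do not
benchmark throughput on real assemblies.
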