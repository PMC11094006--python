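# Methods

This note documents the models and procedures `thermarch` implements,
the defaults that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
underlying workflow left them open.

## Marker identification and clustering

Candidate rpS3 genes arrive with an upstream search score (a
dimensionless bit-score-like value; the HMM search itself is out of
scope) and are screened in three ordered steps: score ≥ 40, translated
length ≥ 60 amino acids (frame 1, standard code; both thresholds keep
the boundary value), and confirmation by best pairwise identity ≥ 0.60
against the supplied labelled reference set. Confirmation by reference
identity replaces a BLASTp-versus-nr lookup so the pipeline has no
external-database dependency; the keep/drop contract is unchanged.

Pairwise identity is matches divided by all columns of an optimal
Needleman–Wunsch global alignment with match +1, mismatch −1 and gap −2
(gap columns count as mismatches). The alignment itself is computed by
`Bio.Align.PairwiseAligner`; among co-optimal alignments the first is
taken, and the test suite checks the returned identity against a
dynamic-programming oracle that enumerates every optimal alignment.

Clustering is greedy and length-sorted, mirroring centroid clusterers
run with exhaustive comparison (no accept/reject shortcuts): records are
processed by decreasing length, ties broken by lexicographic gene id for
reproducibility, and each record joins the earliest-founded centroid
with identity at or above the threshold (default 0.99) or founds a new
cluster. Under the planted separation used in tests (within-cluster
identity ≥ 0.995, between-cluster ≤ 0.90) this coincides with
single-linkage clustering, which is the test oracle. Clustering runs in
the space of the sequences provided (nucleotide here); the module
records the threshold on each cluster.

## Taxonomy

The classifier is the canonical RDP recipe: 8-mer words, naive-Bayes
scoring with word priors (n + 0.5)/(N + 1) and per-reference
conditionals (m + prior)/(M + 1), 100 bootstrap replicates each scoring
⌈W/8⌉ words drawn with replacement from the query's W distinct words.
Per-rank confidence is the fraction of replicates agreeing with the
full-data winner at that rank; because reference lineages form a tree,
confidence is non-increasing from domain to species, and the reported
lineage stops at the deepest rank meeting the threshold (default 0.60).

Database curation applies, in order: a strict length floor (> 300 bp),
exact-duplicate collapse (first id wins), a leave-one-out
self-consistency screen, and 99%-identity clustering to species-level
representatives. The self-consistency screen classifies each sequence
with itself withheld and discards it if any rank assigned with
confidence ≥ 0.60 disagrees with its recorded lineage. Two choices here
were genuinely open:

- Leave-one-out avoids the trivial self-match of classifying a sequence
  against a database that still contains it.
- The comparison runs over domain through genus only. With one
  representative per species, an assign-back can never return the
  withheld species label, so including the species rank would discard
  every entry whose nearest neighbour is confidently resolved. A
  consequence worth knowing: a *correctly* labelled reference that is
  the sole member of its genus can still be discarded when the
  classifier confidently places it in a sibling genus; the screen is
  conservative by design, which matches its purpose of removing
  questionable references. Curation is intended for dirty reference
  sets; clean, programmatically labelled catalogs can be loaded directly
  into `CuratedReferenceDB`.

Queries whose phylum confidence falls below the threshold fall back to
the top-k (default 5) hits by global-alignment identity, assigned at the
deepest rank where all hits concord. Fewer than k references means all
are used; identity ties at the k-th position include every tied hit,
the conservative (shallower) choice. The fallback runs in nucleotide
space; a protein-space fallback could rank hits slightly differently for
very divergent queries, which is untested here.

## Genome quality and dereplication

Depth outliers are scaffolds outside Q1 − 1.5·IQR or Q3 + 1.5·IQR of the
bin's scaffold depths. Quartiles use linear interpolation between order
statistics (the common default in scientific software; the convention is
recorded so results are auditable). When IQR = 0 the fences collapse and
nothing is removed.

Completeness is 100 × (distinct expected single-copy markers present) /
(markers expected); contamination is 100 × (extra copies) / (markers
expected). DPANN-like bins are scored against a reduced 48-gene set —
streamlined episymbiotic genomes lack many standard markers and would
otherwise look incomplete — and all others against a standard
archaeal-sized 122-gene set. The shipped marker-id lists are generic
placeholders: marker definitions are inputs, and the simulator plants
inventories directly. The contamination formula is a deliberate
simplification of lineage-aware tools (same monotone behaviour, no
reference-tree machinery). Tiers follow the MIMAG convention (high:
> 90% / < 5%; medium: > 50% / < 10%); the retention gate is the medium
bar with strict inequalities.

ANI is estimated alignment-free from k = 21 k-mer sets via
max-containment c = |A ∩ B| / min(|A|, |B|) and the Mash-style transform
ANI = 1 + ln(c)/k, clipped to [0, 1]. Max-containment makes the estimate
symmetric and insensitive to unequal bin completeness. Dereplication is
greedy at 99% ANI over bins sorted by completeness − 5 × contamination
(the dRep default weighting), so each cluster's representative is its
highest-quality member; dereplicating the representatives again is a
no-op. An optional curation flag (`GenomeBin.markers` copy counts) lets
callers drop scaffolds bearing multiple copies of a single-copy marker;
the manual rule this approximates is not precisely recoverable.

## Abundance and linkage

rMAG abundance is mapped reads / total reads per sample, with entries at
or below the 0.01% floor zeroed ("more than 0.01%" is strict). The table
is *not* re-normalised afterwards, so column sums may fall short of 1;
this is documented rather than hidden because downstream totals depend
on it. Marker abundance is coverage-based (coverage = reads / gene
length; relative abundance = coverage share per sample); a sample with
zero marker coverage is reported missing with a warning rather than
silently dropped. Linkage metrics treat a representative as "captured"
by the genome catalogue when any member of its cluster occurs among a
MAG's genes, and report capture by representative count and by coverage
weight. FPKM is count / (length_kb × library_size / 10⁶).

## Ecology statistics

Group boundaries are as printed in the spring-survey convention:
pH 5.5 and 8.5, temperatures 60 °C and 80 °C, each boundary going to the
upper class. Bray–Curtis is Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) over per-sample
profiles. PCoA is classical scaling: Gower double-centring of squared
distances, symmetric eigendecomposition, coordinates from positive
eigenvalues only. Negative eigenvalues (expected for non-Euclidean
inputs like Bray–Curtis) are dropped, not corrected, and their
magnitudes are reported; for Euclidean inputs the coordinates
reconstruct the distances to 10⁻⁸. ANOSIM uses midranks for ties,
R = (mean between-group rank − mean within-group rank)/(M/2), and a
label-permutation p with the add-one estimator (1 + hits)/(1 + B), so p
is never exactly zero and bottoms out at 0.001 for 999 permutations. The
permutation count is configurable with default 999. Pearson tests use
the two-sided t-distribution p with n − 2 degrees of freedom.

## Function profiles

A pathway is a flat KO list (editable TSV; the bundled set covers a few
well-known energy-metabolism gene sets and is configuration, not a
biology claim — KEGG-module boolean logic is out of scope). Per archaeal
order: *complete* if at least one reliable rMAG (fewer than 200
scaffolds, strict) carries every required gene; *partial* if any
required gene occurs in any reliable rMAG of the order; *absent*
otherwise. "Partial" deliberately does not require co-location of the
genes in one genome. The MW-score of function f in sample s sums the
relative abundances of the genomes encoding f and normalises across all
functions to 100% per sample; a genome encoding several functions
contributes to each numerator. This is a documented simplification of
the score produced by annotation suites: the contract — relative
contribution, normalised across functions — is preserved.

## SparCC networks

Correlations between relative abundances are distorted by the unit-sum
constraint, so the network engine implements SparCC: log-ratio variances
t_ij = var(log x_i/x_j) (scale-invariant by construction), the
approximate linear system M·w = t for basis variances under sparsity,
correlations ρ_ij = (w_i + w_j − t_ij)/(2√(w_i w_j)), and iterative
exclusion of the strongest pair above |ρ| = 0.1 (up to 10 iterations,
re-solving each time). Components whose excluded-pair count reaches
d − 3 are capped from further exclusion, keeping the system
non-singular (with a least-squares fallback as a final guard). Counts
are smoothed by sampling fractions from the Dirichlet(counts + 1)
posterior; the final matrix is the entrywise median over 20 draws,
symmetrised, clipped to [−1, 1] with unit diagonal. These internals are
the method's published defaults.

Two deliberate refinements:

- Dirichlet draws are keyed to each sample's count content rather than
  its column position, so permuting sample order leaves the matrix
  exactly unchanged.
- Exact invariance to rescaling one sample's counts is impossible under
  posterior smoothing (deeper samples have tighter posteriors); the
  property holds to within posterior-sampling noise and is tested at
  tolerance 0.02.

Pseudo-p values follow the original release semantics: 100 null
datasets built by permuting each feature's counts across samples
independently (destroying covariance, keeping margins), correlations
recomputed, two-sided add-one p = (1 + #{|r_null| ≥ |r_obs|})/(1 + 100).
Edges require |r| > 0.6 and p < 0.05, both strict; nodes without edges
are kept as flagged isolates. Module detection is not part of edge
inference; a connected-components summary is provided as an optional
convenience.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, with ground
truth emitted alongside, and is byte-reproducible for a fixed seed.

**Sequence evolution.** Sequences evolve down the taxonomy by a
Jukes–Cantor "scatter" move: along a branch with retention λ each site
is redrawn uniformly from ACGT with probability 1 − λ. Retentions
compose multiplicatively, and the expected identity of two leaves whose
last common ancestor has leaf-retention λ is exactly ¼ + ¾λ², so the
per-rank sibling-identity targets (defaults: species 0.995, genus 0.97,
family 0.93, order 0.89, class 0.85, phylum 0.80, domain 0.74) are
inverted analytically and realized identities land within a few points
of target at every depth, homoplasy included. No indels are introduced
by default (an `indel_rate` option exercises gapped alignment); the
alphabet is uppercase ACGT only, ambiguity codes are rejected.

**Communities and reads.** The default spring scenario plants disjoint
acid- and alkaline-associated species pools with Dirichlet-drawn
compositions concentrated on each sample's pool, pH and temperature
drawn inside the class boundaries, and an archaeal fraction that rises
toward the pH extremes. Marker read counts are multinomial with
probabilities proportional to abundance × gene length (lengths equal by
default, so expected marker relative abundance equals the planted
composition; at the default 10⁵ reads the binomial error is within two
percentage points). Each sample also carries planted decoy candidates —
short ORFs, sub-threshold scores, and off-target random sequences — so
the screens have real work to do.

**Bins.** Marker inventories realize the specified completeness and
contamination exactly by inclusion/exclusion and duplication of
single-copy markers (planted percentages are rounded to the marker-set
granularity and the realized values recorded as truth). Scaffold depths
are drawn tightly around a bin-level mean with planted outliers far
outside the Tukey fences; a rejection loop guarantees that on the
combined vector exactly the planted scaffolds are outliers. Genome
sequences are evolved per species with the same rank structure, so
same-species bins sit above the 99% ANI threshold and cross-species
bins below it.

**Networks.** Compositional count tables draw log-basis abundances from
a multivariate normal with planted pairwise correlations, close them to
fractions, and sample multinomial counts (default depth 5 × 10⁴).

**Not emulated:** read-level errors and FASTQ simulation, assembly and
binning artefacts, chimeras, strain mixtures within a sample, uneven
gene lengths, and real taxon name distributions. Passing tests
demonstrate that the *procedures* recover planted structure under the
stated models; they do not certify performance on real assemblies,
where binning noise and database incompleteness dominate.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale, chosen as the
package's own defaults: 12-sample two-group surveys with 24 species for
the end-to-end statistics, 30 species for taxonomy recovery, 30 features
by 200 samples for network inference with 20 replicate studies for the
specificity check, 1000 random vectors for the quantile-fence oracle,
and the n = 8 two-group design for exhaustive ANOSIM enumeration. Basis
variances are clipped below at 10⁻¹²; PCoA drops eigenvalues below
10⁻¹² of the leading magnitude; equal-length clustering ties and
equal-score dereplication ties break on lexicographic ids. All
stochastic steps take explicit seeds, and fixed seeds give bit-identical
results across runs.

## Known limitations

- The self-consistency screen can discard correct singleton-genus
  references (see above).
- The ANI estimator is a k-mer containment stand-in for alignment-based
  ANI; it is accurate in the 95–100% range that matters for strain
  dereplication but not calibrated below ~90%.
- MW-scores and pathway presence take annotations as given; no HMM
  searching or KEGG-module logic is performed.
- SparCC p-values inherit the resolution of the null (minimum 1/101 at
  the default 100 shuffles).
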