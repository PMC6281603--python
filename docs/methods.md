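# Methods

This note documents the models, conventions and numerical choices behind
`spatialeqtl`, and what the synthetic studies used in its tests do and do
not establish about real data.

## Coordinates and the digest

Fragments and gene regions are 0-based half-open `[start, end)`; SNP
positions are 1-based on input (the convention of variant tables) and
converted at ingest.  The digest places a cut at the 5′ start of every
recognition-site occurrence (MboI `^GATC`); per chromosome the fragments
tile `[0, L)` exactly, zero-length terminal fragments are dropped, and
indices are per-chromosome ordinals from 0.  Overlapping site occurrences
(possible for general sites, not for GATC) all cut.  Gene models are
collapsed to the union span of their isoforms — introns and inter-isoform
gaps included — and a gene annotated on two chromosomes is an error
rather than a guess.  A SNP landing exactly on a cut site has no defined
fragment; the generator never produces one and real input raises.

Distance for cis/trans classification is the gap from the SNP to the
nearest edge of the collapsed gene region (0 inside it), computed exactly
in 0-based coordinates.  The anchor (region edge rather than TSS) is a
package choice: gene regions here are isoform unions, so a TSS is not
well defined.  The cis window is 1 Mb and configurable; a ±1 bp
convention difference at the edge is immaterial at that scale.

## Spatial pair counting

Both ends of every read pair are treated symmetrically.  Each
(record, SNP-end, overlapping-gene) triple is one supporting interaction;
a partner fragment overlapping k genes contributes one observation to
each of the k pairs, because overlap is defined per composite gene region
and no exclusivity rule exists.  All pairs with ≥ 1 supporting
interaction are retained and their support counts carried forward; a
minimum-support filter exists but defaults to off, since the support
distribution itself is analysed downstream (the enrichment Z-test
partitions pairs into support = 1 vs support > 1).  Identical rows in
different replicate files are counted separately — deduplication across
files would require read-name bookkeeping the input dialect does not
guarantee.

## FDR family

Benjamini–Hochberg runs once, jointly, over all (SNP, gene, tissue) rows
that survive the spatial join; spatial pairs never tested for eQTL
association are excluded *before* adjustment so they do not dilute the
family.  Significance is `p_adjusted ≤ 0.05` (threshold configurable).
The adjustment itself is delegated to `statsmodels` and cross-checked in
the tests against an independently coded step-up formula.

## Sharing matrices and the permutation null

The sharing ratio `a_ij = |S_i ∩ S_j| / |S_i|` is asymmetric; the
identity `a_ij·n_i = a_ji·n_j = |S_i ∩ S_j|` is asserted as an invariant.
Composite phenotype labels are the sorted member traits joined by `|`,
which makes labels deterministic.  The minimum-eGene filter (default 4)
applies to a phenotype's own eGene count; a pairwise-common-count variant
of the threshold is expressible by filtering on the matrix instead.

The null reassigns pooled eGenes to phenotypes with per-phenotype counts
preserved, drawing without replacement *within* a phenotype and
independently *across* phenotypes — a gene may serve several phenotypes,
as in the observed data.  This choice yields the closed-form expectation
`E[a_AB] = n_B/N` (the intersection is hypergeometric), which the tests
verify to within 3 Monte-Carlo standard errors at 1000 replicates.

## Convex biclustering

The objective is
`F_γ(U) = ½‖X−U‖²_F + γ[Σ w_ij‖U_·i−U_·j‖₂ + Σ w̃_kl‖U_k·−U_l·‖₂]`.
Weights are Gaussian kernels `exp(−φ‖·‖²)` (φ = 0.5) restricted to
union-symmetrised k-nearest neighbours (k = 5), each edge set normalised
to unit total mass so that the γ grid 10⁰–10³ spans weak smoothing to
full fusion for sharing matrices of typical scale.  If a kNN graph is
disconnected, k escalates with a warning: connectivity is required for a
unique fully-fused limit (the grand mean).  "100 equally spaced γ from
10⁰ to 10³" is implemented as equal spacing in log₁₀ (endpoints are
quoted as powers of ten); linear spacing is available by flag.

The solver is majorisation–minimisation on the ε-smoothed penalty
`sqrt(‖d‖² + ε²)` (ε = 10⁻⁶): each step solves the Sylvester system
`U + γ(L_r U + U L_c) = X` exactly via eigendecomposition of the two
weighted Laplacians.  The smoothed objective is monotone non-increasing
by construction (tests allow 10⁻⁸ relative floating-point noise);
termination is relative objective change < 10⁻⁶ (10⁻¹⁰ in oracle
comparisons).  γ = 0 short-circuits to X.  On instances up to 6×6 the
returned objective sits within 10⁻⁴ (measured: ~10⁻⁸) of a generic
smooth convex optimiser (L-BFGS on the ε = 10⁻⁹ smoothed objective).
Matrices in this problem are small (tens of phenotypes), so the
per-iteration eigendecompositions are negligible.

Validation holds out a seeded 10% of entries, replaces them by the mean
of the observed entries, solves the path warm-started in increasing γ,
and scores each γ by the mean squared error on the held-out truth;
the final smoothing re-solves on the full matrix at the argmin γ*.
Clusters are connected components of columns (rows) whose pairwise
distance is ≤ `tol_cluster × range(U*)` with `tol_cluster = 0.02`
(a tolerance relative to the smoothed matrix's value range, since
fusion is numerically approximate at finite ε).

Fusion paths of convex clustering are not guaranteed agglomerative, and
with a fixed extraction tolerance the cluster count can transiently rise
mid-path before full fusion; the coarsening property is therefore tested
on well-separated instances and on the path segment up to γ*, where it
holds.

## The synthetic studies

Defaults (chosen once as the study conditions): 4 chromosomes of 300 kb,
GATC spacing ~ Exp(1 kb) floored at 8 bp, 15 genes per chromosome
(1–3 kb, non-overlapping, some with 2 isoforms whose union equals the
gene span), 12 traits in 3 planted clusters, core loci of 4 *adjacent*
genes (one per cluster, on rotating chromosomes), 3 private eGenes per
trait drawn disjointly, one composite SNP per cluster, 2 cell lines × 2
replicates, 50 background contacts per replicate file, true eQTL
p-values ~ U(0, 10⁻⁸) with |NES| ∈ [0.2, 1], 2 null eQTL rows per SNP
with p ~ U(0,1), 2 tissues.  Recognition sites are *planted* into random
non-GATC background (accidental occurrences are rejection-fixed), so
digest expectations are analytic; SNPs are placed strictly inside
fragments, never on a cut site; each true pair is guaranteed ≥ 1 contact
between its SNP fragment and a gene-overlapping fragment, with
~Poisson-distributed extra support spread over replicates.  Outputs are
byte-identical given identical configurations.

What this emulates: the evidence structure the pipeline consumes —
fragment-mediated contacts, tissue-resolved eQTL tests, pleiotropic
sharing through a contiguous core locus.  What it does not: Hi-C
distance decay and coverage biases, LD between SNPs, realistic gene
density or sequence composition, correlated eQTL effects across tissues.
Passing tests therefore demonstrate correctness of the algorithms and
recoverability of planted structure under controlled noise, not
performance on genome-scale data.

Exact recovery of planted eQTL pairs at FDR ≤ 0.05 is asserted with
noise off (no background contacts, no null eQTL rows): with uniform-null
rows present, BH admits occasional false positives *by design* — that is
the quantity FDR controls — so exact set equality is only a theorem in
the noise-free configuration.  Cluster-recovery runs keep the noise on.

Problem sizes throughout the tests and the acceptance script (300 kb ×
4-chromosome genomes, ≤ 100-point γ paths, 1000-replicate nulls, five
end-to-end studies) were chosen so the whole suite completes in well
under a minute while keeping every statistical check at the replicate
counts stated above.

## Known limitations

* The solver targets small phenotype × phenotype matrices; hundreds of
  phenotypes would want a sparse/dual solver with fusion-event tracking.
* Hold-out validation imputes with the observed-entry mean; structured
  imputation could shift γ* on matrices with strong row/column effects.
* Deduplication of identical read pairs across replicate files is not
  attempted (counted per row, as noted above).
* The OMIM-style summary reports annotation fractions and mapping-method
  distributions only; it does not model penetrance or inheritance.
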