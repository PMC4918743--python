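# Methods

This note documents the models and procedures `sigscar` implements, the
choices made where the design was open, and what the synthetic-data tests
do and do not demonstrate.

## The 96-channel mutation alphabet

Single-base substitutions are classified by the six pyrimidine-referenced
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) joined with the bases
immediately 5' and 3' of the mutated base, giving 96 channels. A
substitution reported on the purine strand is reverse-complemented: ref and
alt are complemented and the two flanks are complemented and swapped, so
every channel is reachable from exactly two strand representations of the
same event. Channel order follows the COSMIC convention (substitution
class, then 5' flank, then 3' flank, each A/C/G/T), so signature TSVs
interoperate with COSMIC-style matrices.

Coordinates are 1-based and fully closed everywhere, matching VCF. SNVs at
a contig edge, or whose ±1 bp window contains an ambiguity code, or whose
stated reference base disagrees with the FASTA, are excluded from the
catalogue and reported with a reason, so the catalogue sum plus the
exclusion count always equals the number of input SNVs. Multi-allelic VCF
records are split one variant per alt; MNVs are carried but never counted
in the 96 channels.

## Variant filtering

Two removal rules run before cataloguing. (1) Germline: any variant whose
(chrom, pos, ref, alt) appears in a user-supplied germline site list.
(2) Panel of normals: any variant whose precomputed site evidence shows the
alternate allele in at least 2 well-mapping reads in each of at least 2
normal samples — a recurrent-artifact signature. The panel is consumed as a
site/read-count table; read mapping quality is assumed already applied by
whatever produced the table. Filtering is idempotent, and variants with no
panel entry are kept.

## Exome-to-genome signature normalization

A signature estimated from exomes reflects exonic trinucleotide abundances.
To compare against whole genomes each channel value is multiplied by the
genome/exome abundance ratio of its trinucleotide context (32
pyrimidine-centric trinucleotides, reverse-complement collapsed) and the
vector is renormalized to sum to 1. The operation is its own inverse with
the frequency arguments swapped. Mutation prevalence is reported as
mutations per megabase of the territory actually callable (a haploid
genome or exome footprint supplied by the user).

## De novo extraction

The cohort catalogue matrix M (96 × samples) is factorized as M ≈ W·H with
W, H ≥ 0 under the Frobenius objective, using multiplicative updates with
seeded uniform initialization. The update rule guarantees a monotone
non-increasing objective, which the test suite asserts on every trace;
convergence stops when the relative objective decrease falls below 1e-9 or
at 2,000 iterations. Columns of W are normalized to densities with the
mass absorbed into H.

Sampling noise is handled by bootstrap: each sample's catalogue is redrawn
as a multinomial of its own total from its empirical channel distribution
(totals preserved exactly). For each candidate rank k, the k signatures
from each of B bootstrap factorizations are pooled (k·B draws) and reduced
to k consensus signatures by average-linkage agglomerative clustering under
cosine distance; the consensus is the renormalized centroid.

Rank selection operationalizes "the minimal set of signatures that
reproducibly explains the catalogues" as: choose the largest k such that

1. mean silhouette of the pooled draws under cosine distance ≥ 0.8
   (`stability_floor`, configurable);
2. no two consensus centroids have cosine similarity > 0.85 (a split
   signature indicates over-factorization);
3. every consensus cluster contains draws from at least half the
   bootstraps — a signature that appears in only a few resamples is a
   noise component, not a reproducible mutational process.

Rule 3 matters in practice: at one rank above the truth the spurious NMF
component tends to land in a sparse or singleton cluster while the mean
silhouette can remain above 0.8.

## Exposure refitting

For a sample with catalogue m and total mutation count N, and a candidate
set Q = {s₁…s_q} of signature densities, the exposure vector E solves

    min_E ‖ m − Σᵢ Eᵢ sᵢ ‖₂   s.t.  Eᵢ ≥ 0,  Eᵢ ≤ N,  Σᵢ Eᵢ = N.

The constraints say exposures are mutation counts: non-negative, no larger
than the sample total, and jointly accounting for every mutation. This is
a convex quadratic program; it is solved by non-negative least squares on
the system augmented with a heavily weighted row encoding the sum
constraint, followed by an exact rescaling onto {ΣE = N} (rescaling
preserves non-negativity, and the per-signature cap is implied by the
other two constraints). The solver is deterministic; the test suite checks
it against exhaustive enumeration of integer exposure splits on small
problems and finds it never beaten (tolerance 1e-6).

Candidate-set selection mirrors how curated signature catalogues are used:
Q starts from the registry of signatures known operative in the sample's
cancer type, then any signature carrying a biological feature flag
(indels at repeats, indels with microhomology, transcriptional strand
bias, dinucleotide mutations, hypermutation) is dropped unless the sample
itself shows that feature — defaults: ≥ 10 indels of the relevant class,
≥ 5 dinucleotides, booleans passed through. All thresholds are exposed in
`FeatureThresholds`.

A binary presence call for a signature requires both an absolute exposure
(default 10 mutations) and a relative one (default 5% of the sample
total). These defaults are this package's convention, not a published
rule, and should be tuned to cohort depth.

## Microhomology-deletion scars

For a deletion of sequence d with upstream flank u and downstream flank w
(each at least |d| long, read from the reference), the microhomology
length is max(p, q) where p is the longest common prefix of d and w and q
the longest common suffix of d and u, capped at |d| − 1. A full-length
match means the deletion removed one unit of a tandem repeat — a
polymerase-slippage event — and is flagged `at_repeat` and excluded from
microhomology counts. The measure is strand-symmetric (reverse-complement
all three sequences and swap the flanks).

A deletion counts toward the per-sample microhomology burden iff it is
longer than 3 bp (strictly), has microhomology ≥ 1 bp (configurable; the
burden report can also be produced at ≥ 2 bp), and is not a repeat event.
Insertions are annotated but never counted. Structural-variant counts are
consumed as integers (TSV or BEDPE row counts); no SV calling is done.

## Association statistics

Fisher's exact test on 2×2 tables uses the two-sided probability-mass
convention: the p-value sums the probabilities of all tables with the same
margins whose hypergeometric probability does not exceed the observed
table's. A zero margin returns p = 1. This convention reproduces the
published gastric-histology p-values (0.0003 discohesive growth, 0.0058
intestinal-vs-rest, 0.0015 diffuse-vs-rest) at their printed precision
from the printed 2×2 tables.

The Mann-Whitney U test computes U from rank sums with midranks. Exact
mode enumerates all C(n+m, n) group assignments — valid with ties, since
midranks are used throughout — and is the default for n + m ≤ 16 without
ties; otherwise the normal approximation with tie and continuity
corrections is used. Exact-mode p agrees with the closed-form exact null
distribution on every tie-free case tested.

Contingency tables are built after excluding samples with unknown
annotation levels; a stratifier collapses named levels into the
factor-present row (e.g. intestinal vs diffuse+mixed). Report formatting:
p ≥ 0.001 to four decimals, otherwise scientific with three significant
digits. No multiple-testing correction is applied.

## The synthetic-data generators

The generators emulate the statistical structure the analysis assumes, and
their defaults describe the study conditions used throughout the tests:

- **Cohorts**: 100 samples; per-sample totals log-normal with median
  10,000 mutations and σ = 0.5 (whole-genome-like burdens spanning an
  order of magnitude); exposures Dirichlet over the active signatures;
  channel counts multinomial (optionally Poisson) around the mixed
  spectrum. The signature of interest is active in 12% of samples, and
  when active contributes a Beta(2, 4)-distributed share (mean ≈ 1/3) of
  the sample's mutations: a tumour genuinely carrying the
  homologous-recombination-deficiency process displays it at a
  substantial fraction, not at trace level.
- **References and SNVs**: uniform-random sequence with planted SNVs whose
  expected 96-vector is computed directly from the planted tuples; the
  catalogue builder must reproduce it exactly.
- **Indels**: true microhomology deletions (4–15 bp) are placed by
  rejection-sampling loci whose downstream flank shares a ≥ 1 bp prefix
  with the deleted sequence (tandem-repeat loci rejected), at Poisson rate
  170 per negative sample and 4 × 170 per positive sample — the 4:1
  contrast observed between signature-positive and -negative genomes.
  Filler indels (short deletions, insertions, zero-homology large
  deletions) are constructed to be uncountable, so recovery is exact by
  construction.
- **Annotations**: a binary growth-pattern annotation with base rate 7%
  whose log-odds shift by log(15) in positive samples, and a ternary
  Lauren histology with the intestinal class receiving the same shift —
  the magnitude of association seen in the published histology tables.

What passing these tests shows: the estimators recover what the generators
plant under the noise models stated above. What it does not show: behaviour
under real-data pathologies the generators deliberately omit — mutation
calling errors beyond the modelled panel filter, copy-number-driven
burden structure, correlated signatures (e.g. flat spectra that are near
collinear), sequencing-platform batch effects, and subclonal mixtures.
Real flat signatures are far harder to separate than Dirichlet(0.2) draws
at pairwise cosine ≤ 0.3; refitting accuracy on real catalogues is
correspondingly lower.

## Problem sizes and numerical choices

Simulation-based tests run at 50–100 samples with 5,000–10,000 mutations
per sample, 20 bootstraps and candidate ranks 1–4; the microhomology power
analysis uses 100 cohorts of 100 samples on a 200 kb reference. These
sizes were chosen as the smallest at which the planted effects are
comfortably identifiable, keeping the full suite fast enough to run on
every change. NMF uses tolerance 1e-9 and at most 2,000 iterations; the
refit penalty weight is 1e4 on data scaled to unit maximum, with the sum
constraint then enforced exactly by rescaling. Degenerate inputs are
defined: a zero-mutation sample refits to all-zero exposures with zero
residual; a zero-margin contingency table yields p = 1; a single
consensus cluster has stability 1 by convention. Ties among equally
optimal exposure splits (exactly collinear signatures) resolve to the
deterministic active-set NNLS solution.

## Known limitations

- No transcriptional-strand (192-channel) catalogues and no indel (ID-83)
  channel set; indels feed only the microhomology scar analysis.
- The per-cancer-type signature registry ships empty; users supply their
  own registry sidecar (the tests construct COSMIC-style examples).
- Exposures carry no confidence intervals.
- The rank-selection thresholds (silhouette 0.8, centroid similarity
  0.85, half-bootstrap recurrence) are heuristics exposed as
  configuration; on cohorts with genuinely overlapping processes they can
  under-select.
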