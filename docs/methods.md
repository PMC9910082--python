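# Methods

## Model

A whole-genome-shotgun metagenome is a multiset of reads sampled from a
microbial community in proportion to species abundance. `cgrfractal`
summarizes such a read set by the multifractal structure of its chaos
game representation (CGR).

**CGR mapping.** The unit square has corners A=(0,0), C=(0,1), G=(1,0),
T=(1,1). Each read is traversed independently from the center:

    x_0 = (0.5, 0.5),    x_k = x_{k-1} + 0.5 (P(s_k) - x_{k-1})

where `P(s_k)` is the corner of the k-th nucleotide. One point is
emitted per A/C/G/T symbol; the first 10 points of every read are
discarded so that the arbitrary starting position does not leak into
the counts (`discard_prefix`, default 10). Symbols outside {A, C, G, T}
(N, ambiguity codes) emit no point and leave the position unchanged —
the minimal-perturbation choice, which keeps the retained point count
exactly `sum_reads max(0, #ACGT - discard_prefix)`. Reads are used as
given (forward strand, no reverse complement). Because the map is a
contraction of the square starting at its center, every point lies
strictly inside (0,1)^2.

The level-ℓ grid of CGR point counts coincides with the k-mer count
table for k = ℓ (the last ℓ symbols determine the cell), which is why
box counts at fine levels track the k-mer space a community covers.

**Box counting.** Points are binned once on the finest dyadic grid
(2^L × 2^L cells, `max_level` L = 13 by default, cell `(⌊y·2^L⌋,
⌊x·2^L⌋)`, the 1.0 boundary clamped inward defensively); coarser grids
are exact 2×2 block sums, which equals independent recounting at every
resolution. Internally the occupied cells are counted sparsely and
scattered into dense grids; a histogram of cell values per level is
cached, since partition sums depend only on it.

**Generalized dimensions.** With M_i the count in cell i, M_0 the
total, and ε = 2^-ℓ, the partition value per level is

    q ≠ 1:  ln Σ_{M_i>0} M_i^q        (0^0 treated as 0; at q = 0 each
                                       occupied cell contributes 1)
    q = 1:  Σ (M_i/M_0) ln(M_i/M_0)

The spectrum is estimated by unweighted ordinary least squares of the
partition value against ln ε over a ladder of levels, with

    D(q) = slope / (q - 1)   (q ≠ 1),     D(1) = slope.

This is the standard Rényi convention: a uniform filling of the square
gives D(q) = 2 exactly, D(0) is the box dimension of the support, D(1)
the information dimension, D(2) the correlation dimension, and D(q) is
non-increasing in q. (The printed form of the defining equation divides
by ln ε directly and would flip signs for ε < 1; the slope transform is
what the log–log fitting procedure actually estimates, and makes the
q = 0/1 limits agree with the box/information dimensions.) The squared
correlation r² of each fit is reported so users can detect scaling
breakdown; a constant partition sequence is a perfect zero-slope fit
(r² = 1). Two branches of the q grid are distinguished with a 1e-9
tolerance around q = 1.

**Defaults.** q from 0 to 15 in steps of 0.2 (76 values) and the
seven-level ε ladder 2^-6, 2^-7, 2^-8, 2^-10, 2^-11, 2^-12, 2^-13
(2^-9 omitted, matching the fitting protocol the analysis follows).
Negative q is refused by default: on sampled point clouds the spectrum
is dominated there by nearly-empty boxes and is unstable across
replicate samples; `allow_negative_q=True` overrides for exploration.

**Choosing the ladder for small samples.** The default ladder presumes
~10^8 points (100 K reads × 1,000 bp). For smaller clouds the fine
levels saturate — occupied-box counts plateau at the number of points —
biasing D(0) down, while low mean occupancy inflates high-q moments.
Guideline used throughout the tests: keep the finest level's mean
occupancy per occupied box at roughly 50 or more (e.g. levels 4–7 for
10^6 points). This is an analysis-parameter choice; generator settings
are never adapted to it.

## Alpha diversity

Richness counts strictly positive abundances; Shannon is −Σ p ln p
(natural log); Simpson is reported as Gini–Simpson 1 − Σ p², chosen
because it orients the index the same way as D(2) (larger = more
diverse), which is what the positive D(q)–Simpson correlations require;
the inverse form 1/Σ p² is available by flag. Profiles must sum to 1
within 1e-6 and are renormalized exactly on ingest.

## Simulator

The simulator emulates the simulation design of the study: a community
of ~10 species with fixed relative abundances; each metagenome draws a
species per read from the profile, then an error-free read of fixed
length from a uniform start on that species' linear genome (forward
strand only; the design describes error-free sampling — an optional
uniform substitution rate, default 0, supports robustness experiments).
Defaults are 100,000 reads × 1,000 bp. Species and start positions are
drawn before any error draws, so activating the error model perturbs
bases, not fragments. Abundance profiles are sampled by independently
zeroing each species with probability 0.1 (one survivor forced) and
giving survivors symmetric-Dirichlet(1) weights — reproducing the
sparse, strongly uneven profiles of real communities. Synthetic genomes
are i.i.d. (or first-order Markov with composition-preserving
persistence) rather than real bacterial sequences.

What the synthetic genomes do and do not show: reads stay much shorter
than genomes, and the k-mer space covered grows with richness, which is
the mechanism linking D(q) to diversity — so the correlation and
monotonicity experiments are meaningful. They lack repeat structure,
GC skew, shared homology between related species, and sequencing-error
profiles; passing tests therefore demonstrate the estimator and the
workflow, not the exact correlation magnitudes expected on real
genomes.

## Desk-scale experiments

`experiments.richness_gradient_cohort` re-runs the diversity-correlation
study at desk scale: 50 communities, richness cycling 2–10, uniform
profiles over subsets of a shared 10-genome pool, 10 K reads × 200 bp,
genomes 50 kb. Genome length was fixed once at 50 kb so that (a) reads
are ≪ genome, (b) each genome's distinct k-mer count (~5×10^4) is small
against the finest grids, keeping richness the dominant driver of
occupied-box counts, and (c) one cohort runs in about a minute on one
CPU. With the default ladder the cohort reproduces the qualitative
finding: r(richness, D(q)) peaks at q = 0 (r ≈ 0.98 at these sizes),
r(Shannon, ·) near q ≈ 0.4–1, and r(Simpson, ·) near q ≈ 5.
`sampled_profile_cohort` (20 samples, 5 K reads × 200 bp) is used for
spectrum-shape checks; D(q) is non-increasing on every sample well
within the 0.05 tolerance.

Full-scale replication (real genome accessions, 100 K × 1,000 bp, or
the infant-cohort SRA data) is supported through the CLI but takes
hours and requires downloads; it is deliberately outside the test
surface.

## Statistics

Group comparisons use Welch's unequal-variance t-test with the
one-sided "less" alternative (pooled-variance Student form by flag);
p-values are reported raw, without multiple-testing correction,
matching the workflow this package follows. Classification uses
Gaussian LDA with class-proportion priors on the 76 D(q) features;
the pooled covariance is shrunk toward a scaled identity with the
Ledoit–Wolf analytic intensity (sklearn `lsqr`/`shrinkage="auto"`) so
the fit stays well-posed when features approach the per-class count;
`shrinkage=None` requests the unregularized estimator and raises on a
singular pooled covariance. Accuracy is reported by back-substitution
(confusion matrix of the training samples) and by leave-one-out
cross-validation. Longitudinal pairing of samples is not modeled; tests
are unpaired.

## Numerical notes

- Partition sums are computed as log-sum-exp over the histogram of
  occupied-cell values — numerically safe at q = 15 and exact to
  floating precision against the naive sum.
- The batch CGR path evaluates the recursion position-wise across reads
  with elementwise float operations identical to the per-read path;
  both produce bit-identical coordinates (asserted in tests).
- Integer counts are stored as int32 when totals permit (< 2^31).
- Degenerate inputs: empty sequences, all-discarded reads and empty
  point clouds raise informative errors rather than returning NaN;
  constant inputs to Pearson/Welch raise (the statistics are undefined).

## Known limitations

- max_level is capped at 16 and levels ≥ 14 are memory-hungry (dense
  grids); the sparse internal representation keeps the defaults cheap.
- The first retained point of a homopolymer read sits exactly on a cell
  boundary at level = discard_prefix + 2 (e.g. 2^-12 for poly-A with
  the default discard), so "all points in the corner cell" holds for
  levels ≤ 11.
- The simulator does not model paired ends, indels, quality scores,
  copy-number variation or strandedness.
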