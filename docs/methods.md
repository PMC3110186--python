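# Methods

This note documents the models, statistics and numerical choices behind
`adjx`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several defensible options existed.

## Study design and data model

The pipeline targets the design of a two-treatment mucosal stimulation
study: each treatment group has a matched vehicle control, tissue is
profiled at 4, 24 and 48 hours, with four biological replicates per
group and timepoint (48 arrays for two treatment/control pairs). The
in-memory unit is a gene × sample matrix of log2 intensities plus a
per-sample design record (group, timepoint in hours, replicate).
Gene identifiers are opaque strings — no symbol/probe normalization is
attempted, so the pipeline works in whatever identifier space the user
supplies consistently across matrix, gene sets and edge list.
Timepoints are numeric hours rather than categories so contrasts
generalize to other kinetic designs.

## Preprocessing

**Log2.** `log2_transform` applies log2(x + offset), offset default 1,
for inputs arriving on the linear scale. All downstream statistics
assume log2.

**Quantile normalization.** Each sample's sorted values are replaced by
the across-sample mean of sorted values. Ties within a sample receive
the mean of the reference values their positions span — the common
dialect; it is stated explicitly because tie conventions differ between
implementations. Consequence worth knowing: with ties, the column-wise
sorted vectors are identical only up to tie-block averaging; without
ties they are exactly equal, and the operation is idempotent either
way. Quantile normalization exists to remove array-level intensity
distortions. Applied to data whose distributional differences are
biological (e.g. a strong, mostly one-directional transcriptional
response), it compresses true fold changes and induces compensatory
shifts in null genes; on simulated data (which has no array-level
distortion) we measured empirical FDR rising from 0.045 to 0.21 and a
−0.25 log2FC bias when it is applied. It therefore remains the default
for real-array workflows but is omitted in the synthetic analysis of
`scripts/acceptance.py`.

**SVD sample QC.** The gene-centered matrix X (rows to mean zero) is
decomposed X = U S Vᵀ; sample coordinates are V S, so pairwise sample
distances in full component space equal distances between centered
sample columns. Variance fractions are σ_k²/Σσ². Singular-vector signs
are fixed deterministically (largest-|loading| gene entry positive) so
coordinates are reproducible across runs and BLAS builds. On a
simulated two-group dataset with planted effects ≥ 1 log2 unit, treated
and control arrays separate on the first two coordinates (positive
silhouette), mirroring the sample-consistency check this projection is
used for.

## Differential expression

Per contrast (treatment vs matched control at one timepoint):
two-sample pooled-variance Student's t, df = n₁+n₂−2, chosen over
Welch as the primary statistic because equal-variance replicates per
arm is the design assumption; Welch is available via `welch=True`.
One-sided p-values (upper/lower t tails) are retained because the
reporter algorithm scores direction separately; they satisfy
p_up + p_down = 1 and p_two = 2·min(p_up, p_down). Genes with zero
pooled variance get t = 0, p = 1, p_up = p_down = 0.5 and a flag,
rather than being dropped — preserving the gene universe for
enrichment. BH adjustment runs per contrast (family = all genes of
that contrast), matching per-timepoint testing that avoids conflating
kinetic differences. The step-up formula is implemented directly
(reverse cumulative minimum on sorted p) and cross-checked in tests
against both a literal enumeration oracle and statsmodels.

Power at the strict Q ≤ 0.001 cutoff is materially below 1 under the
default noise model: the self-consistent noncentral-t calculation
(df = 6, effect 2.0, σ = 0.25, 10% non-null) gives ≈ 0.79, reaching
0.997 only at effect 3.0. The power test asserts agreement with this
oracle rather than a fixed high percentage.

"Commonly up-regulated by both treatments" is defined as: up-significant
(Q ≤ threshold, log2FC > 0) in at least one timepoint for each
treatment. The rule is configurable; this union-based convention is the
least restrictive reading consistent with per-timepoint testing.

## Reporter enrichment

Gene scores are Z_g = Φ⁻¹(1 − p_dir), with p clamped to
[1e-15, 1−1e-15] to keep scores finite. Set score Z_raw = ΣZ_g/√k over
the k members present in the scored universe. The background is
size-matched Monte Carlo: n draws (default 10,000) of random k-subsets
without replacement from all scored genes; μ_k and σ_k are cached per k
so all sets of one size share one null — this both saves time and makes
equal-size sets exactly comparable. Z_corr = (Z_raw − μ_k)/σ_k,
p = 1 − Φ(Z_corr). The Monte-Carlo moments estimate the population
(ddof = 0) moments of the subset-score distribution; the test suite
verifies them against exhaustive enumeration on a small universe.
σ_k ≤ 1e-12 (all gene scores equal) is treated as an error. All genes
are scored, not only significance-filtered ones — the enrichment then
uses the full ranking information.

Direction fractions (the "arrow angle") count the proportion of a set's
scored members with log2FC > 0; exact zeros are excluded from the
denominator, and a set with no scored members reports NA.

The significance matrix keeps sets with reporter p ≤ 0.001 in at least
one condition, stores −log10 p, and orders rows and columns by
average-linkage hierarchical clustering on Euclidean distance. Inputs
are pre-sorted by label so leaf order is deterministic. Distance and
linkage are fixed choices (configurable), since nothing deeper than
display order depends on them.

## Co-expression modules

Gene selection: union of genes with Q ≤ 0.01 at any timepoint of the
treatment. Correlation is computed across all arrays of the treatment
arm (treatment + matched control, all timepoints pooled) — co-expression
over time, not within a single condition.

Adjacency is unsigned by default, a_ij = |r_ij|^β, with the signed
variant ((1+r)/2)^β behind a flag. β is selected as the smallest
candidate whose connectivity distribution fits a scale-free law at
R² ≥ 0.8 (log-binned regression of log frequency on log connectivity),
falling back to the best-fitting candidate with a warning.

TOM: TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj, computed as a matrix product (the zeroed
diagonal makes the exclusion of u ∈ {i,j} automatic), symmetrized and
clipped to [0,1]; verified against a triple-loop oracle to 1e-12.

Module detection is a static height cut of the average-linkage
dendrogram of 1 − TOM: clusters below `min_module_size` become label 0,
the rest are labeled 1..M by decreasing size with ties broken by the
smallest member gene id. The static cut is simple and deterministic; a
known limitation is that the appropriate height depends on network
density (TOM values shrink as the universe grows), so the cut is a
per-analysis choice rather than a universal constant.

**Refinement (`refine_modules`).** At small sample sizes the plain
recipe has two failure modes we measured directly: (i) with ~24 arrays,
independent module factors realize chance correlations up to |r| ≈ 0.5,
and the *unsigned* network then treats anti-correlated genes as
co-expressed, misplacing genes and occasionally merging modules;
(ii) average-linkage chaining strands borderline genes. The refinement
operation addresses both with the field-standard recipe: compute each
module's eigengene (first PC of its standardized expression, oriented
positively), merge modules whose eigengenes correlate above `merge_r`
(default 0.8), reassign every gene to the module with its highest kME
(gene–eigengene correlation; signed by default so anti-correlation is
not absorbed), and leave genes below `kme_min` (default 0.3) unassigned.
Iterate to convergence (default cap 5), then drop modules below the
final size floor. On planted 3-module data (r² = 0.6, 30 genes/module,
24 samples) the signed network (β = 10) with a fine seed cut (height
0.93, seed size 10) plus refinement recovers modules with ARI ≥ 0.9 in
60/60 simulations across six disjoint 10-seed sets, where the plain
unsigned static-cut recipe managed ~70%.

Module function: hypergeometric upper-tail p of the module–set overlap
given the supplied universe, BH-adjusted across all module × set tests.
The hypergeometric test is discrete and hence conservative under the
null; tests assert sub-uniformity, not exact uniformity.

## Interaction hubs

Degree is counted within the subgraph induced by the significant genes
(default Q ≤ 0.01, up-regulated) — "interactions with other significant
genes" — with the full-graph degree exported as a secondary column.
Ranking is by descending degree, ties broken lexicographically; rank 1
is the main interactor. Edge semantics are collapsed to a single
undirected type; weights, if present in the input, are binarized.

## Synthetic-data generator

Per gene g and sample s, on the log2 scale:

    x_gs = μ_g + σ·(√r²·f_{m(g),s} + √(1−r²)·ε_gs) + δ_{g,c(s)}

with μ_g ~ N(8, 2) basal levels, σ the residual SD (default 0.25),
f the standard-normal latent factor of g's planted module (pure noise
for unassigned genes), and δ the planted signed effect of the sample's
(treatment, timepoint) cell. The latent-factor construction makes the
expected within-module pairwise correlation exactly r² (default 0.6) —
chosen because it is analytically controllable and hence property-
testable. Note the realized mean correlation of one module fluctuates
with the factor's realized variance (SD ≈ 0.07 at 24 samples);
calibration checks therefore average over modules and replicates.

Differential expression is planted per treatment from a response pool
1.5× the largest per-timepoint count, so consecutive timepoints overlap
as sustained responses do. A configurable fraction of each pool
(`shared_fraction`, default 0.5) is drawn from a cross-treatment core
whose per-gene sign and magnitude are fixed globally — emulating the
shared innate program two stimuli of the same tissue engage, and making
the cross-treatment "commonly up-regulated" count a meaningful
quantity. Effect magnitudes are |N(effect, effect_sd)| with the sign
set by `up_fraction` (default 0.8 upward). Kinetic presets:
"rapid_broad" (10/13.5/7% of the genome at 4/24/48 h) and
"delayed_transient" (0.9/1.7/1.0%), i.e. roughly 2,000/2,700/1,400 and
180/340/200 genes on a 20k genome — order-of-magnitude mirrors of a
strong TLR9-type response vs a weak iNKT-type response.

Gene sets: enriched sets draw `enriched_purity` (default 0.8) of their
members from the first treatment's up-perturbed genes, the rest
uniformly; background sets are uniform. The interaction graph is
preferential attachment (Barabási–Albert, m = 2) over all genes with a
designated hub — drawn from the first treatment's up-perturbed genes —
additionally wired to `graph_hub_degree` perturbed partners, so it
dominates connectivity within that treatment's significance-induced
subgraph.

**What the generator does not emulate:** probe-level effects, array
spatial artifacts or intensity-scale distortions (hence no technical
need for quantile normalization on synthetic data), batch effects,
count-based noise, correlated replicate structure, or gene-length/GC
biases. Passing tests therefore demonstrate the statistical machinery
under its own assumptions (Gaussian log2 noise, independent
replicates), not robustness to real-array artifacts.

## Problem sizes and determinism

Default test and acceptance problem sizes are desk-scale by design:
4,000-gene genomes for the study-design reproduction, 5,000-gene nulls
for calibration checks, 10,000 Monte-Carlo null draws for reporter
scores (200,000 where compared against exhaustive enumeration). These
sizes give standard errors comfortably inside the asserted tolerances.
Every stochastic component takes an explicit seed; the pipeline splits
one root seed into independent per-stage streams, so a run is fully
reproducible from (config, seed), and rerunning with the same seed
yields identical stage counts.

## Known limitations

* The static dendrogram cut needs density-appropriate heights; use
  `refine_modules` on fine-cut seeds when sample sizes are small.
* BH Q-values assume independence or positive dependence across genes;
  planted module structure induces mild dependence that the FDR checks
  absorb empirically but that has no finite-sample guarantee.
* Reporter p-values are Monte-Carlo-resolved; below ~1/n_samples they
  are extrapolated through the normal approximation of Z_corr.
* The hub statistic is plain degree; weighted or typed edge semantics
  are out of scope.
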