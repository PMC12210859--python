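# Methods

This note documents the models and procedures amplistat implements, the
defaults it ships, the numerical choices that would otherwise be
invisible, and what the synthetic-data generator does and does not
emulate.

## Feature tables and filtering

The core container is a taxa × samples matrix of read counts (or
per-sample proportions, flagged explicitly). Validation enforces unique
identifiers, non-negative finite values, and unit column sums for
relative tables. Feature retention follows common amplicon practice: a
taxon is kept when its total count is ≥ 10 reads **and** it is detected
(≥ 1 read — the detection threshold used consistently throughout the
package) in ≥ 2 samples. Sample retention uses a per-kingdom depth floor,
defaults 14,000 reads (16S) and 19,500 reads (ITS), inclusive. The depth
filter deliberately leaves all-zero taxon rows in place: dropping taxa is
a separate, auditable call. When collapsing to a rank, taxa with an empty
value at that rank are pooled under `unclassified_<deepest assigned
parent>`, which keeps labels unique and conserves per-sample totals
exactly. TSVs default to taxa-as-rows; reading a samples-as-rows file
requires the explicit orientation flag, because silently transposed
tables are a classic failure mode.

The oral-microbiome fraction is the share of a sample's bacterial reads
assigned to taxa flagged as oral-cavity residents. It is computed per
sample and averaged per group by default; a pooled mode (pool counts,
then divide) exists because the two conventions differ on uneven depths.

## Diversity

α-diversity is the Hill family `D_q = (Σ pᵢ^q)^(1/(1−q))` with zeros
excluded from the sums. q=1 uses the exact entropy limit
`exp(−Σ pᵢ ln pᵢ)` rather than an ε-perturbed exponent — the general form
is numerically unstable near q=1 and the limit is exact. Group contrasts
use two-sided Wilcoxon rank-sum tests (scipy's exact distribution when
sample sizes permit and there are no ties).

β-diversity follows Hellinger transform → Bray-Curtis → classical metric
scaling. PCoA eigendecomposes the double-centred −D²/2 matrix and reports
*all* eigenvalues; negative ones (non-Euclidean input) are never silently
dropped, and proportion explained is relative to the positive spectrum.
PERMANOVA partitions squared distances (total SS = Σd²/n; within-group SS
summed per group) into R² and a pseudo-F; ANOSIM ranks all pairwise
distances once and compares between- to within-group mean ranks. Both use
seeded label permutations and the add-one estimator
`p = (1 + #{stat* ≥ stat}) / (1 + n_perm)`, which bounds p below by
1/(n_perm+1) and avoids p = 0. Pairwise group contrasts are run on
sub-distance-matrices (a Bray-Curtis distance between two samples does
not depend on other samples) and Benjamini-Hochberg adjusted within the
family of pairs. Both statistics are always labelled explicitly in
output, since summary tables in the field sometimes carry an R² column
under an "ANOSIM" heading and the two are not interchangeable.

## Spatial heterogeneity (Taylor power law)

For each sample, M and V are the mean and variance (n−1 denominator) of
per-taxon abundances across the taxa *detected in that sample*; per
group, `ln V = ln a + b ln M` is fitted by OLS across samples, and the
slope b indexes aggregation. Zero-inclusion and the variance convention
are recorded in every fit object; an include-zeros mode exists and
changes b systematically, so the flag travels with the result. Counts are
the default input; a relative-abundance mode exists. Degenerate points
(V = 0 or M = 0, e.g. a sample with all-equal counts) are excluded with a
warning; a fit requires ≥ 3 points and non-constant ln M.

Group contrasts pool the two groups' samples, reassign membership at the
original sizes, and compare permuted |Δb| (and |Δ ln a|) to the observed
value with the add-one estimator. Letter summaries use the
insert-and-absorb compact-letter-display algorithm over the pairwise
significance matrix.

## Shared species and the permutation null

The shared count between two disjoint sample groups is the number of taxa
detected in at least one sample of each. The primary null ("A2-labels")
reshuffles sample-to-group labels at fixed group sizes; a second variant
("A2-reads") additionally redistributes each pseudo-group's pooled reads
across its samples by multinomial draws at the original depths, which
also perturbs within-group presence patterns. Both are reported by name;
the two-sided p folds the null around its mean. The p-value is exactly
valid but discrete: when the null SD is only a couple of taxa the p
distribution is lumpy, which is inherent to an integer statistic, not an
implementation artifact.

## Biomarker screen and ROC

The screen mirrors the LEfSe recipe without claiming numeric parity with
the original program (recovery of planted differential taxa is the
contract). Per taxon: a Kruskal-Wallis test across all groups
(tie-corrected; for exactly two groups the exact rank-sum distribution is
used instead of the χ² approximation, which is anti-conservative at small
n); with more than two groups, a one-against-all consistency check
requires the top group to beat every other group in pairwise direction.
Abundances are scaled to 10⁶ per sample; for each enriched-vs-rest split,
30 bootstraps of ⌈2n/3⌉ samples per class fit a two-class Fisher
discriminant whose pooled covariance is shrunk 10% toward its diagonal
(singular covariances are routine at these sample sizes); the per-feature
effect is `0.5·(|Δ raw class means| + |Δ discriminant-projected class
means|)` averaged over bootstraps, and the score is `log10(1 + effect)`.
Thresholds: Kruskal-Wallis p < 0.05 and score ≥ 3.0.

AUC is the Mann-Whitney probability with ties counted ½, computed by
direct pairwise enumeration (the sample sizes involved make this exact
and cheap). Two markers are combined by a logistic discriminant on
standardised features, fitted with a small L2 ridge (10⁻⁶) at tolerance
10⁻⁸: the ridge makes the problem strictly convex and deterministic, and
under perfect separation the solution concentrates weight on the
separating feature so a dominant marker keeps AUC = 1; the result carries
a `separable` flag. (A rank-sum fallback was considered and rejected: it
can destroy the separation a single feature already achieves.) The
combined score is fitted and evaluated in-sample, so a small optimistic
bias is inherent at small n — calibration tests quantify it.

A marker for a species set (the "functional group") is the per-sample sum
of the members' relative abundances — order-invariant and conserved under
species-level collapsing.

## SparCC networks

SparCC estimates taxon-taxon correlations from compositional counts. Per
iteration, fractions are drawn from Dirichlet(counts + 1); the log-ratio
variance matrix `t_ij = Var ln(xᵢ/xⱼ)` is computed; basis variances ω
solve the sparsity approximation `Σ_j t_ij ≈ d_i ω_i + Σ_{j∈inc(i)} ω_j`;
correlations follow as `ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_i ω_j))`,
clipped to [−1, 1]. The most-correlated pair above the exclusion
threshold (default 0.1) is removed from the system and it is re-solved,
up to 10 exclusion rounds, at most D−3 exclusions per taxon, and never
letting a taxon's included degree drop below 3. Two stability choices
depart from the oldest reference behaviour, both prompted by
small-taxon-count calibration: an excluded pair's correlation is frozen
at the iteration that excluded it (later solves no longer constrain that
pair, and letting it float can amplify it to |ρ| ≈ 1 on null data), and a
taxon whose basis variance comes out non-positive has its correlations
set to 0 rather than reported as clipped ±1 artifacts. The final estimate
is the median over iterations (default 20; a no-resampling single-pass
mode exists and is what the three-taxon closed form checks).

Edge significance: the null permutes each taxon's counts across samples
independently and re-estimates SparCC; the two-sided per-edge p is the
add-one fraction of null |ρ*| ≥ |ρ|, BH-adjusted over the upper triangle.
Bootstrap resampling (samples with replacement) optionally quantifies
estimate stability as a per-edge SD. Edges are kept at q < 0.05 and
|ρ| > 0.4 — the magnitude filter is strict, so ρ = 0.40 exactly is
dropped. Note the resolution limit this null implies: at 10–13 samples
per group, even a true latent correlation of 0.8 yields p ≈ 0.001–0.03
against a fat small-sample null, which survives BH only when many true
edges share the small-p ranks. Group networks at cohort sizes are
therefore meaningful when co-occurrence structure is pervasive, and the
package's network benchmarks run at n = 35 per group.

Dense cores use MCODE-style vertex weighting (highest k-core of the
closed neighbourhood × its density) with greedy seed expansion (node
score cutoff 0.2, degree cutoff 2, k-core 2 — the defaults of the
original plug-in, since nothing else is specified in common practice);
cluster members are `core`, their non-member neighbours `peripheral`.
The backbone is the maximum spanning forest on |ρ| per connected
component. The functional-group procedure intersects unordered edges of
the healthy and dysplasia networks (sign ignored by default — a
sign-strict mode exists, but a pair that flips sign between stages still
represents an interaction), collects endpoint species, and keeps those
present as carcinoma-network nodes.

## Clinical statistics

The r × c exact test is the Freeman-Halton generalisation: with margins
fixed, the two-sided p sums the probabilities of every table no more
probable than the observed one (within 10⁻¹² slack for floating-point
ties). This is the convention that reproduces the published cohort's
printed p-values. Enumeration is recursive over row compositions and is
exact for the cohort-sized tables it targets. One-way ANOVA accepts raw
vectors or `(n, mean, sd)` summaries; the summary route reconstructs
between- and within-group sums of squares algebraically, so printed group
summaries are enough to verify a published p-value. The report renderer
rounds p to three decimals; machine output keeps full precision.

## The synthetic cohort generator

The generator emulates a five-group biopsy cohort: group sizes 13 (HC),
10/10 (ESIN and adjacent), 12/12 (ESCC and adjacent); bacterial and
fungal kingdoms sequenced separately; a scaled-down default of 200
bacterial and 60 fungal taxa (the full-size profile, 2314/573, is one
call away — the scaled default keeps test suites fast at equal
structure).

Counts arise hierarchically. Per taxon, a base log-abundance ~
N(0, 1.6²) sets a realistic rare tail. Per sample, one latent *activity*
variable u drives both the library size (log-normal, mean 30,000/25,000
reads, σ = 0.4) and a dispersion multiplier `exp(0.35·u)` on the group's
dispersion parameter σ_g; the per-sample taxon noise is σ_s·z with z
drawn from a block covariance (planted correlation blocks; equicorrelated
blocks are validated as positive semi-definite, and block strength may
differ by group so carcinoma-style groups can carry weaker coupling).
Counts are multinomial at the sample's library size, per kingdom.
Planted log2 fold changes enter as group effects on the latent scale.

The activity coupling is what makes the Taylor law behave like real
amplicon data: "hot" samples are both deeper and more dominated, so the
per-sample (M, V) points line up along one tight power-law curve per
group (fit correlations ≈ 0.97–0.99), and the group dispersion parameter
moves the slope monotonically — the generator's b(σ_g) map spans roughly
2.1–3.3 over σ_g ∈ [0.4, 1.0] at the defaults. Without the coupling,
depth and unevenness push points along different directions, fits loosen
to R ≈ 0.87–0.9, and the permutation contrast loses most of its power.
The default dispersion map places the dysplasia group highest
(σ: HC 0.5, ESINA 0.6, ESIN 1.0, ESCCA 0.7, ESCC 0.45), so ESIN is the
most spatially heterogeneous group, and carcinoma the least.

Clinical covariates are realised to the configured contingency counts
*exactly* (which samples carry a "yes" is randomised by seed), adjacent-
tissue groups mirror their patient group sample-for-sample, and ages are
drawn from the configured group `mean (sd)`. All randomness flows from
one integer seed through fixed-offset sub-streams; identical configs
yield byte-identical tables.

What the generator does **not** emulate: sequence-level error and
chimeras, taxonomy misclassification, phylogenetic structure (taxa are
exchangeable up to their parameters), batch effects, and the saturating
presence patterns of very deep sequencing are only reproduced when the
taxon count is large relative to depth (use the full-size profile when
patchy presence matters, e.g. for shared-species analyses). Passing tests
on this generator therefore demonstrates correct statistical machinery
and recoverability of planted effects under realistic compositional
noise — not performance on any particular real cohort.

## Problem sizes and calibration designs

The test and acceptance workloads choose sizes where each estimator has
resolving power while the suites stay quick: p-value calibrations use
250–300 replicates against exchangeable nulls (Kolmogorov-Smirnov at
α = 0.01); the shared-species calibration uses patchy presence (≈ 500
taxa occupying ~15% of 12 samples) so the integer null spreads over
enough values for a uniformity test to be meaningful; network FDR
calibration uses 20 shuffled-column datasets; the Taylor contrast
benchmark runs two groups of 30 samples over 1000 taxa with planted
dispersions 0.35 vs 1.0 (fitted b ≈ 2.3 vs ≈ 3.0); biomarker recovery
plants a 3-log2 taxon in groups of 12 over 100 seeds; and network
recovery plants ρ = 0.8 at 200 samples for single-edge detection or
n = 35 per group for the three-network functional-group chain.

## Known limitations

* The pooled-permutation slope contrast is conservative when the two
  groups' (M, V) clouds occupy different abundance ranges; its power
  depends on tight within-group fits.
* SparCC edge significance at n ≲ 15 cannot separate single strong edges
  from its small-sample null at FDR 0.05; this is a property of the
  per-edge permutation design, not of the estimator.
* The LDA effect-size score matches the published recipe's structure but
  is not bit-compatible with the original LEfSe program.
* Freeman-Halton enumeration is exponential in table size; it is intended
  for cohort-scale tables (total n in the hundreds, few cells).
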