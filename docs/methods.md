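# Methods

## The question the pipeline answers

A genus-by-sample abundance table, classified by most-abundant genus, often
shows *Bacteroides*- and *Prevotella*-dominated samples in separate regions
of an ordination plot. Two generative stories are compatible with that
picture: (a) discrete community types, each with its own supporting cast of
genera; or (b) a one-dimensional abundance gradient between two inversely
related dominant taxa, with everything else exchangeable. The package
implements the diagnostics that distinguish them — a leave-dominant-taxa-out
re-ordination, and association screens that ask whether *any* other taxon
reliably travels with either dominant genus — together with generators for
both stories so each diagnostic can be validated against known truth.

## Data model and preprocessing

Tables are taxon-by-sample matrices in either `relative` (proportions) or
`count` mode. Preprocessing follows the conventions of genus-level
meta-analysis:

- **Low-abundance filter** (default threshold 1e-4 = 0.01 %): a genus is
  kept iff its maximum relative abundance over all samples is strictly
  greater than the threshold. Retained proportions are *not* renormalized —
  the Prevotella ratio and all downstream distances are meant to be read on
  the original proportion scale, and the removal diagnostic depends on
  un-rescaled columns. Whether equality should pass is unspecified in common
  usage; we use strict inequality.
- **Age filter** (default 13 years): child guts are compositionally distinct
  (*Bifidobacterium*-dominated under breast-feeding), so adult-only analyses
  drop younger samples. Samples with unknown age are retained, since age is
  typically recorded for only some cohorts.
- **Merging studies** takes the union of taxa (exact string match after
  whitespace trimming; no taxonomy reconciliation), zero-fills, and prefixes
  sample IDs with the study label.
- **Pseudo-counts** for count-only methods: `round(relative × 10000)` with
  round-half-to-even (deterministic, unbiased). Depth 10,000 is chosen so
  every genus surviving the 1e-4 filter maps to at least one count.

## Dominance, ratio, summaries

Dominance is the argmax over genus rows; exact ties are broken
lexicographically with a logged warning so results are deterministic and
auditable. The Prevotella ratio P/(P+B) is undefined (NaN, never 0) when
both abundances are zero; undefined values are excluded from quantile
curves with their count reported. Quantile curves pair sorted ratios with
i/(n−1) so cohorts of different sizes can be overlaid. Taxon summaries
report quartiles, prevalence, and occupancy of the abundance bands
[0, 5 %), [5, 10 %), [10, 40 %), [40, 80 %), [80, 100 %] — the cuts that
separate background genera from blooming dominants.

## Distances and ordination

- Bray-Curtis is evaluated on columns *as given*. After taxon removal the
  columns sum to less than one and the denominator Σ(xᵢ+yᵢ) < 2; this is
  deliberate, so that removing taxa changes the geometry only through the
  taxa removed.
- Morisita-Horn and Jensen-Shannon renormalize each pair of columns to unit
  sum (both are defined on probability vectors). JSD uses log base 2 and the
  square root, so all three metrics live on [0, 1].
- PCoA: Gower double-centering and a symmetric eigendecomposition. Negative
  eigenvalues (non-Euclidean input) are reported but excluded from the
  variance-explained denominator, matching the common default of ecological
  ordination software; no Cailliez/Lingoes correction. Axis signs are fixed
  by making the largest-magnitude coordinate on each axis positive.
- NMDS: SMACOF with monotone (isotonic) regression of disparities on
  configuration distances, disparities rescaled to the configuration norm
  each iteration; best of 20 restarts (the first initialized from PCoA,
  the rest random from the seed), tolerance 1e-6, 500 iterations. Reported
  stress is Kruskal stress-1 of the returned configuration. These settings
  are ours; stress for a clean 2-D configuration is < 0.01.

## Group ellipses and the removal diagnostic

Each dominance group with ≥ 3 samples gets a mean and *unbiased* sample
covariance on axes 1–2; the ellipse boundary is Mahalanobis distance
`n_sd` (default 2) from the mean. For bivariate Gaussian data the 2-SD
Mahalanobis ellipse contains 1 − e⁻² ≈ 86.5 % of points (χ²₂ at 4) — note
this differs from the ~95 % that "2 SD" suggests in one dimension; the
geometric construction (axes along covariance eigenvectors, semi-axes
2·√eigenvalue) is what is implemented. Boundary points count as inside.
Degenerate (collinear) groups are flagged and handled via the pseudo-inverse
in the nondegenerate subspace. A robust covariance option is not provided by
default; the plain estimator keeps the diagnostic interpretable.

The removal diagnostic computes, before and after deleting the dominant
genera (without rescaling), the variance explained by axes 1–2 and the
fraction of every group's samples inside every other group's ellipse, with
labels frozen at their original values. Collapse = containment jump plus
variance drop. On the default gradient simulation the
Prevotella-in-Bacteroides containment rises from 0.00 to ≈ 0.8; on the
discrete simulation with secondary structure it stays at 0.

## Association screens

All screens target the question "does any other genus travel with a
dominant genus?", within the subset of samples that genus dominates.

- **Spearman + BH**: midrank-tied Spearman of every other genus against
  the target, BH-adjusted across the screened genera (per-study by default;
  the pooled alternative is a caller choice).
- **SparCC** (reimplemented from its published algorithm): per resampling
  round, per-sample fractions are drawn from Dirichlet(counts + 1); the
  variation matrix t = var log(fᵢ/fⱼ) is formed; basis variances ω solve
  ((D−2)I + 11ᵀ)ω = t·1 under the sparsity assumption; ρᵢⱼ = (ωᵢ+ωⱼ−tᵢⱼ)/
  (2√(ωᵢωⱼ)), clipped to [−1, 1]. The strongest pair with |ρ| above 0.1 is
  iteratively excluded from the linear system (up to 10 times; ρ is always
  computed from the original variation matrix); the estimate is the
  elementwise median over 20 rounds. Pseudo p-values permute each taxon's
  counts across samples independently (destroying covariation, preserving
  marginals), with add-one smoothing over 100 bootstraps. Defaults follow
  the published tool's documented defaults and are all exposed in
  `SparccConfig`.
- **φ proportionality**: zeros replaced by Uniform(1e-8, 2e-8) draws under
  an explicit seed; φ(x|y) = var(log x − log y)/var(log x). The matrix is
  asymmetric; both the full matrix and the min-symmetrized view are
  returned, and the φ < 0.01 flag is evaluated on the symmetrized view
  (the conservative orientation-free choice). Constant taxa yield undefined
  rows, flagged.
- **Negative-binomial two-group test**: an intentionally simple Wald test —
  median-of-ratios size factors (all-nonzero reference taxa, falling back to
  ≥ 90 %-prevalent taxa), pooled method-of-moments dispersion
  (var = μ + αμ², floored at 1e-8), delta-method standard error on the log2
  fold-change, normal two-sided p, BH adjustment. No dispersion shrinkage,
  no variance-stabilizing transform, no independent filtering; it trades
  power for transparency and is calibrated (type-I error ≈ 0.025–0.05 at
  n = 50 per group in the test suite).

A finding is kept only if it is both statistically significant (positive
association with adjusted p ≤ 0.05, or φ < 0.01) and biologically
significant (mean relative abundance ≥ 0.02 and prevalence ≥ 0.75 counted
at ≥ 0.01 abundance). All boundaries are inclusive. Cross-study consistency
reports, per taxon, the set of studies where it passed, with a flag when
that set covers all studies.

## Synthetic communities

The generators encode the two hypotheses; their defaults are the study
conditions under which the diagnostics are validated.

**Gradient model** (logistic-normal → multinomial). 50 genera (named gut
genera at the head of the inventory, numbered fillers after), 200 samples,
depth 10,000. Latent g ~ Uniform(0, 1). Log-mean of *Bacteroides* is
3.7 − 3g, of *Prevotella* 0.7 + 3g — a symmetric see-saw whose log-ratio
spans ±3 — and the tail follows the power-law 1.6 − 1.9·log(1 + rank), so
only the two key genera routinely exceed 40 % relative abundance.
Per-taxon log-noise SD is 0.5: large enough that mid-gradient samples are
sometimes dominated by a tail genus ("Other" labels occur), small enough
that the Prevotella ratio tracks g with Spearman ≥ 0.9 at n = 200.
The resulting ratio distribution spans [0, 1] with ≈ half the samples in
(0.2, 0.8). Planted correlates overwrite a tail taxon's log weight as
`intercept + slope · (target's log weight) + noise` *before* softmax;
planting on the post-closure composition would be cancelled by the shared
normalizer and leave the pair uncorrelated. The default intercept (−2.3)
puts the planted taxon's mean relative abundance at ≈ 0.05 within the
target-dominated subset — squarely above the biological-significance floor.

**Discrete model** (Dirichlet-multinomial mixture). Three components with
weights (0.45, 0.35, 0.20), dominated by *Bacteroides*, *Prevotella* and
*Faecalibacterium* respectively; concentration 50. Each component's mean
puts 0.35 on its dominant genus, 0.004 on the other components' dominants
(dominance groups are nearly mutually exclusive), and — with
`secondary_structure` on — 0.08 on each of three component-specific
secondary genera, the "genuine community" signal that survives dominant-
taxon removal. Under these defaults dominance labels recover the two
key-taxon components with ≥ 95 % accuracy and the ratio distribution is
bimodal (< 5 % of samples in (0.2, 0.8)).

**Multi-study collections** concatenate per-study simulations sharing one
inventory, applying per-study log-composition offsets (pᵢ ∝ pᵢ·exp(oᵢ))
before redrawing counts — a crude but controllable batch effect.

What the generators do *not* emulate: phylogenetic correlation among
genera, overdispersion beyond the logistic-normal/Dirichlet variance,
rarefaction artifacts, time-series structure within subjects, and realistic
per-study taxonomic incompatibilities. Passing diagnostics on these data
therefore show that the machinery detects the targeted structural
difference under clean conditions, not that it is robust to every artifact
of real surveys.

## Numerical conventions

- Dominance ties: lexicographic, logged.
- Undefined Prevotella ratios: excluded from curves, never imputed.
- PCoA sign: largest-|coordinate| positive per axis.
- SparCC: nonpositive basis variances mark a taxon's correlations
  undefined; components excluded from nearly all pairs are dropped from the
  system.
- Bootstrap p-values use (1 + exceedances)/(1 + n) smoothing.
- All stochastic operations take an explicit seed; derived seeds stay below
  2³¹.
- Problem sizes in the validation suite (n = 200 samples, 30–50 taxa,
  50 screen replicates, 100 bootstraps) are the defaults of the study
  conditions; they keep each check well-powered while the full suite runs
  in well under a minute of compute.

## Known limitations

- The NB test is deliberately plain; with strong dispersion heterogeneity
  it will be conservative relative to shrinkage-based estimators.
- Bray-Curtis is not a metric in general; triangle-inequality violations
  are possible (JSD, as implemented with the square root, is a metric).
- SparCC's sparsity assumption fails when many taxa are strongly coupled;
  the exclusion heuristic mitigates but does not remove the bias.
- The removal diagnostic compares summary statistics (containment,
  variance explained), not full distributions; borderline generative
  regimes (weak secondary structure) can fall between its two verdicts.
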