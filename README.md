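# entgrad

Gradient-vs-cluster diagnostics for dominant-taxon structure in gut
microbiome genus tables.

Human gut samples are often sorted into "enterotypes" — putatively discrete
community types dominated by *Bacteroides* or *Prevotella* — on the strength
of apparent clusters in ordination plots. But because these two genera reach
far higher relative abundances than any other gut genus and tend to be
inversely related, they dominate every pairwise dissimilarity, and a smooth
two-taxon abundance gradient produces the same visual separation as genuine
community types. `entgrad` packages the analyses needed to tell the two
apart in any genus-by-sample table, and ships synthetic-community generators
for both competing hypotheses so the whole pipeline is testable end to end.

## What it computes

**Dominance classification and the Prevotella ratio.** Each sample is
labelled by its most abundant genus (`Prevotella`, `Bacteroides`, `Other`).
The Prevotella ratio, P/(P+B), replaces the binary label with a continuous
coordinate: 0 = all *Bacteroides*, 1 = all *Prevotella*.

**Ordination.** Bray-Curtis (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)), Morisita-Horn, and the
square-root Jensen-Shannon divergence (base 2, so d ∈ [0,1]), embedded by
classical PCoA (Gower double-centering, B = −½ J D² J) or nonmetric MDS
minimizing Kruskal stress-1.

**The removal diagnostic.** Fit a 2-standard-deviation Mahalanobis ellipse
to each dominance group on axes 1–2, then delete the two dominant genera
*without rescaling* the remaining proportions and re-ordinate with the
original labels. If the groups were gradient endpoints, they collapse: the
cross-group ellipse containment jumps and the leading axes lose variance.
Genuine multi-taxon communities keep their separation.

**Compositional association screens.** Spearman + Benjamini-Hochberg within
each dominated subset; SparCC (log-ratio variance inference of basis
correlations with Dirichlet resampling and permutation-bootstrap pseudo
p-values); Lovell φ proportionality, var(log x − log y)/var(log x), with
Uniform(1e-8, 2e-8) zero replacement; and a simplified negative-binomial
two-group Wald test. A hit must be *statistically* significant (positive
association, adjusted p ≤ 0.05, or φ < 0.01) and *biologically* significant
(mean abundance ≥ 2 %, prevalence ≥ 75 % at ≥ 1 % abundance).

## Worked example

```python
from entgrad import *
from entgrad.simulate import GradientModelConfig

# 200 samples from the two-taxon gradient model (no discrete structure)
table, meta = simulate_gradient(GradientModelConfig(n_samples=200, seed=1))
rel = to_relative(table)

labels = classify_dominance(rel)
print("dominance:", labels["label"].value_counts().to_dict())

report = dominance_removal_diagnostic(rel, labels)
print(f"varexp axes 1-2 before: {sum(report.varexp_before):.3f}")
print(f"varexp axes 1-2 after:  {sum(report.varexp_after):.3f}")
print(f"containment P-in-B before: {report.containment_before[('Prevotella','Bacteroides')]:.3f}")
print(f"containment P-in-B after:  {report.containment_after[('Prevotella','Bacteroides')]:.3f}")

ords = ordinate(rel)
r, p = axis_taxon_correlation(ords, rel, "Bacteroides", axis=1)
print(f"Bacteroides vs axis 1: r={r:.3f} (p={p:.2g})")
```

prints

```
dominance: {'Bacteroides': 96, 'Prevotella': 94, 'Other': 10}
varexp axes 1-2 before: 0.822
varexp axes 1-2 after:  0.580
containment P-in-B before: 0.000
containment P-in-B after:  0.819
Bacteroides vs axis 1: r=0.983 (p=5.1e-147)
```

Read bottom-up: *Bacteroides* abundance alone explains the first ordination
axis (r = 0.983). Before removal the *Prevotella*-dominated samples sit
entirely outside the *Bacteroides* group's 2-SD ellipse (containment 0.000) —
the classic "enterotype" picture. After deleting the two dominant genera,
82 % of them fall inside it (0.819) and the leading axes lose a quarter of
their variance: the apparent clusters were carried by the two taxa alone.
Running the same diagnostic on the discrete generative model (distinct
secondary genera per community) leaves containment unchanged.

The same pipeline runs from the shell on a YAML config:

```bash
entgrad run --config config.yaml --seed 1 --outdir out/
```

writing dominance labels, ratio quantile curves, the top-20 taxon summary,
ordination coordinates, the removal-diagnostic JSON, per-screen association
tables, plots, and a `run.json` manifest of every threshold and seed used.

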