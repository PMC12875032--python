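# Methods

This note documents the statistical models implemented in `sepsisprot`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Study design assumed by the pipeline

A case-control cohort with repeated measures: healthy controls contribute
one plasma sample each; sepsis subjects contribute paired samples on
intensive-care days 1 and 3. Protein abundances arrive as a normalized
samples × proteins table on an arbitrary log2 scale (the package makes no
assumption about the upstream assay's units). Clinical metadata carries a
per-day PELOD-2 organ-dysfunction score, a 0/1 mortality outcome, and
nuisance covariates (sex, age, comorbidity and support flags, lengths of
stay).

## Moderated-t differential expression

Per protein g the contrast fit gives an effect β̂_g, a residual variance
s²_g on d degrees of freedom, and the unscaled variance v of β̂:

* unpaired (D1 vs control): β̂ = mean(A) − mean(B), pooled two-sample
  variance, d = n_A + n_B − 2, v = 1/n_A + 1/n_B;
* paired (D3 − D1): one-sample analysis of within-subject differences,
  d = n_pairs − 1, v = 1/n_pairs. The paired form is the default for the
  D1/D3 comparison because the samples share subjects; an unpaired variant
  is available for sensitivity analysis.

The hierarchical model takes s²_g ~ s₀²·d₀/χ²(d₀). The prior is estimated
by moment matching on z = log s²: Var(z) = ψ′(d/2) + ψ′(d₀/2) and
E[z] = log s₀² + ψ(d/2) − log(d/2) − (ψ(d₀/2) − log(d₀/2)), with the
trigamma inversion done by Newton iteration (relative tolerance 1e-8).
When the observed dispersion of log-variances does not exceed the sampling
dispersion ψ′(d/2), the prior is degenerate: d₀ = ∞ and every posterior
variance equals the moment-consistent scale s₀² = exp(mean z)·exp(log(d/2)
− ψ(d/2)). The second factor is the finite-d bias correction of the
log-scale estimator (it tends to 1 as d grows); the same convention is used
by the standard R implementation of this model. Proteins with s² = 0 are
excluded from prior estimation but still tested with the shrunken variance.

The moderated statistic is t = β̂ / √(s̃²v) with
s̃² = (d₀s₀² + d·s²)/(d₀ + d), referred two-sided to t(d₀ + d); d₀ = 0 is
accepted as the explicit no-shrinkage limit (ordinary t) and d₀ = ∞ gives
the fixed-variance normal form. P-values are BH-adjusted (step-up with
cumulative-minimum monotonization). A protein is called differentially
expressed at adjusted p ≤ 0.05 **and** linear fold change ≥ 2, interpreted
symmetrically as |log2FC| ≥ 1; both boundaries inclusive. Reported
fold changes use the signed convention: 2^lfc for lfc ≥ 0, −2^(−lfc)
otherwise, so a halving prints as −2. No minimum-expression filter is
applied.

## Boruta feature selection

Each iteration appends one independently shuffled shadow copy per feature,
fits a depth-5 random forest on the doubled matrix, and scores a hit for
every real feature whose mean-impurity-decrease importance strictly
exceeds the maximum shadow importance. After each iteration every
undecided feature is tested two-sided against Binomial(iterations, 1/2)
with Bonferroni correction over the undecided set; significant-many hits
confirm, significant-few reject, survivors after `max_iter` (default 100)
stay tentative. Defaults: 500 trees per iteration (the selection loop
requires many fits and the hit indicator is insensitive to tree count
well beyond this), 5,000 trees for the stand-alone classifier and the
final re-ranking of confirmed features (ties broken by feature id).
Impurity importance was chosen over permutation importance for determinism
and speed; the choice is a parameter of `train_forest` in all but name
since any importance vector of matching shape can be compared the same way.
No class reweighting is applied (the design is balanced).

**Known limitation — small-n false positives.** With many features and few
samples (e.g. 60 features at n = 100) the largest in-sample correlation
between a pure-noise feature and the labels is ≈ 0.25–0.3, an in-sample
t of ≈ 3. That fixed spurious correlation is genuine in-sample signal: the
feature outranks freshly shuffled shadows in most iterations whenever its
correlation sits in the upper tail of the max-shadow-correlation
distribution, and the binomial decision rule then confirms it regardless
of correction, because no importance-based wrapper can distinguish a
stable spurious association from a weak real one without fresh data. The
effect disappears at larger n (the same design at n = 1000 confirms
nothing): as correlations shrink with 1/√n, forest importance noise
dominates and real/shadow features become exchangeable. At the 23 + 23
cohort scale with ~120 proteins, confirmed features should therefore be
read as "all features carrying in-sample information", a superset of the
truly predictive ones.

## Outcome correlations

Pearson correlation for continuous scores, point-biserial (numerically
Pearson on the 0/1 coding) for mortality; two-sided p from
t = ρ√(n−2)/√(1−ρ²). Panels are per (variable, timepoint) — D1 proteins
against D1 scores, D3 against D3, both timepoints against final mortality —
with pairwise-complete deletion per protein and BH adjustment over the
protein family within each panel, never across panels. Constant proteins
are skipped with a warning.

## Over-representation analysis

For universe size N, term size K (after intersection with the universe),
hit-list size n and overlap k: p = P(X ≥ k) for hypergeometric X (exact,
one-sided over-representation only), odds ratio = cross-product of the
2×2 table (0 when k = 0, +∞ on a zero complement cell with k > 0), and a
direction statistic z = (U − D)/√(U + D) over the overlap members'
log2FC signs with direction up/down only when unanimous. Members with
log2FC exactly 0 count in neither tally. Terms are tested only when
2 ≤ K ≤ N − 2. The default universe is the measured panel, not the
genome: for a targeted assay, unmeasured proteins were never at risk of
being hits, and a genome background would inflate every enrichment. A
caller can supply any universe to override this.

## Pathway-clinical bipartite graph

R = √(log2FC² + (−log10 p_adj)²) is the Euclidean norm of a protein's
volcano-plot coordinates; adjusted p-values are floored at 1e-300 before
the log (observed values reach 1e-28 and below). The adjusted p comes from
the same contrast that defined the term's DEP membership (D1 vs control
for D1 analyses). For each enriched term and clinical variable, every
overlap protein whose correlation has **raw** p < 0.05 (the gate is
deliberately unadjusted) contributes w = ρ·R; protein-level weights are
aggregated into one edge per (term, variable). Sum is the default
aggregation (it preserves evidence mass — two weak concordant proteins
outweigh one); mean is exposed for comparability across terms of different
sizes. Edges with no passing protein are omitted, so every edge is backed
by at least one significantly correlated protein.

## Cohort summary conventions

Quartiles use linear interpolation between order statistics (the common
"type 7" default). Percentages round half-up to integers — this exactly
reproduces printed cohort fractions such as 15/23 → 65% and 19/23 → 83%.
Mann-Whitney uses the exact null distribution for combined n ≤ 20 without
ties, otherwise the tie-corrected normal approximation; chi-square is
Pearson's without continuity correction (a warning fires when an expected
count drops below 5). The pairwise association map picks the test by type
pair (Pearson, Mann-Whitney/Kruskal-Wallis, chi-square) and assigns tiers
from raw p and from BH over the whole pairwise family. PCA is
column-centered SVD with each component's sign fixed so its
largest-magnitude loading is positive.

## Synthetic-data generator

The generator emulates the assumed study design, with defaults matching
it: 23 sepsis subjects (paired D1/D3) + 23 controls, 120 proteins, 20
planted DEPs at |log2FC| = 1.5 over a residual SD of 0.5 (log2 scale),
D3 retaining half the D1 effect, 8 PELOD-2-correlated proteins at target
ρ = 0.6, 15% mortality. Abundances are log2-normal: per-protein baselines
drawn once from N(10, 2²), plus group shift, plus N(0, sd²) noise. D3
values reuse the subject's D1 draw plus the attenuation delta plus fresh
noise, giving the within-subject correlation a paired analysis expects.

Two calibration choices deserve note:

* **Outcome correlations.** A per-protein correlation of ρ with a single
  score is impossible for p mutually independent proteins once ρ > 1/√p,
  so the outcome proteins share a per-subject severity latent (pairwise
  correlation ρ within the sepsis group). PELOD-2 is then
  a·(standardized mean of the planted proteins) + noise with
  a = ρ/√(ρ + (1−ρ)/p), which makes each planted protein's population
  correlation equal ρ for any p (at p = 1 this reduces to the textbook
  a = ρ). Scores are mapped to a plausible integer 0–33 range, which
  attenuates correlations by well under 1%.
* **Mortality.** Death is Bernoulli from a logistic model on the
  standardized mean of the mortality proteins' D1 values (slope 1.5, a
  moderate signal), with the intercept solved numerically so the realized
  marginal death probability equals the configured rate exactly.

Outcome and mortality proteins are drawn from the planted DEPs when
possible so the pathway-clinical graph has a connected planted signal.
Gene sets sample the universe uniformly except for a few enriched terms
seeded so ≥ 70% of their members are planted DEPs (term size is capped at
⌊n_dep/0.7⌋ to keep that feasible). Nuisance covariates carry no protein
signal. By default no values are missing; an optional completely-at-random
missingness rate is available.

What the generator does **not** emulate: inter-protein correlation beyond
the planted latent structure, heavy-tailed or batch-structured noise,
informative missingness, assay floor/saturation effects, and any
relationship between nuisance covariates and proteins. Passing
recovery tests on this generator therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to real
plasma-proteomics artifacts.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run everything at the design's
own scale (23 + 23 subjects, 120 proteins) with replicate counts chosen
for stable Monte-Carlo estimates at interactive runtimes: 10–20 seeds for
recovery and calibration rates, 5 seeds for Boruta designs at n = 100,
1,000 random vectors for the BH oracle, and exhaustive enumeration up to
N = 12 for the hypergeometric oracle. Large-n law-of-large-numbers checks
inflate single dimensions (up to 1,000 subjects) while keeping everything
else small.

## Determinism

Every stochastic component takes an explicit integer seed; the pipeline
fans a single global seed out to per-stage seeds via `SeedSequence`, so a
stage can be re-run in isolation. All writers format floats at 17
significant digits; identical configuration reproduces every output file
byte for byte.
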