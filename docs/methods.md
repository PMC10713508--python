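# Methods

## Scientific setting

The SHSQ-25 is a 25-item screening questionnaire for suboptimal health
status (SHS) — the intermediate state between wellness and diagnosable
disease. Items are rated 0–4 ("never or almost never" … "always") and
grouped into five domains: cardiovascular (CS, 3 items), digestive (DS, 3),
fatigue (FT, 9), immune (IS, 3) and mental health (MH, 7). The total score
is the plain sum over items; a cohort is stratified at the sample median of
the total into an *optimal* (low) and a *suboptimal* (high) population.

The package treats the 25 items of each population as nodes of a Gaussian
graphical model (GGM). Under a multivariate-normal working model the zeros
of the precision matrix Θ = Σ⁻¹ encode conditional independence, and

ρ_ij = −θ_ij / √(θ_ii θ_jj)

is the partial correlation between items *i* and *j* given all others — the
edge weight of the network. Because n ≈ 100 per population is small relative
to the 300 candidate edges, Θ is estimated by the graphical lasso
(L1-penalised Gaussian likelihood) with the penalty chosen by the extended
Bayesian Information Criterion (EBIC). Downstream of estimation the package
provides the standard descriptive battery of psychometric network analysis:
centrality indices, node predictability, bootstrap accuracy and
case-dropping stability, a permutation two-group comparison test, and
ordinal-MDS / force-directed node placements.

## Scoring and group comparisons

- **Median split.** Scores strictly above the median are labelled
  suboptimal. The tie rule is explicit and configurable; the default sends
  ties to the optimal group (suboptimal ⇔ total > median). If all totals are
  equal the split is degenerate: everyone is labelled optimal and a warning
  is raised.
- **Missing ratings** are never imputed. Strict mode (default) refuses to
  score incomplete respondents; lenient mode drops them with a warning.
- **Effect sizes.** Cohen's d uses the pooled SD,
  d = |m₂−m₁| / s_p, s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
  and the two-sample t-test uses the same pooled form so that t and d are
  mutually consistent (t = d·√(n₁n₂/(n₁+n₂)) up to sign); this pooled form
  reproduces the published p-values from the published summary statistics.
  Magnitude labels follow the standard bands (<0.2 negligible, 0.2–0.5
  small, 0.5–0.8 medium, ≥0.8 large). The packaged copy of the published
  summary table carries its printed labels verbatim, which occasionally
  disagree with the bands (d = 0.43 is printed "medium"); recomputation
  reports both. One printed value (height, d = 0.03) is inconsistent with
  its own printed means/SDs (which imply d ≈ 0.43 as ~0.03/0.07); the
  recomputation keeps the value implied by the summaries and flags the
  discrepancy rather than forcing agreement.
- Categorical covariates are compared by a chi-square test on the group ×
  category contingency table without continuity correction (the 2×2 gender
  table then reproduces the hand value Σ(O−E)²/E ≈ 2.77).

## Synthetic cohorts

The study's respondent-level data are not deposited, so all end-to-end
validation runs on generated cohorts with a known truth.

- **Truth networks.** A sparse symmetric partial-correlation pattern is
  drawn at a requested edge density; magnitudes are uniform on a weight
  range (default 0.15–0.35, 10% negative signs — questionnaire networks are
  predominantly positive). The implied precision (unit partial variances,
  off-diagonals −ρ_ij) is made positive definite, when needed, by a uniform
  eigenvalue shift plus re-normalisation, and the stored partial
  correlations are recomputed from the final precision so the object is
  self-consistent.
- **Ordinal margins.** Items are produced by a Gaussian copula: a latent
  MVN draw with the truth's correlation matrix, each column cut at four
  thresholds. Thresholds are calibrated per item so the discretised mean
  matches a target: the item is modelled as a clipped rounded normal N(μ, σ)
  with σ fixed at the target SD and μ found by 1-D root finding (Brent) so
  the category-probability-weighted mean equals the target mean. Target
  means/SDs default to the published per-item values for the two
  populations (packaged JSON). Means are matched exactly in distribution;
  SDs are emergent and not forced.
- **What the generator does not emulate:** respondent-level covariates
  (age, blood pressure, …), item wording effects, response styles
  (acquiescence, social desirability), and any non-Gaussian latent
  dependence. Passing recovery tests therefore show the estimator works
  when the ordinal data really do arise from a sparse latent GGM — they do
  not certify the model for arbitrary real questionnaire data.

## Association matrices

Items are 5-point ordinal, so the default zero-order association is the
**polychoric correlation**, estimated by the classical two-step method:
thresholds from the marginal cumulative proportions via Φ⁻¹, then ρ by
maximising the multinomial likelihood of the contingency table under a
latent bivariate normal (bounded scalar optimisation; empty categories are
collapsed). The bivariate-normal rectangle probabilities use the
correlation-integral form of Φ₂ evaluated by 48-point Gauss–Legendre
quadrature, vectorised over all table cells at a fixed ρ (~1e-6 absolute
accuracy over |ρ| ≤ 0.999, which is far below the sampling noise of any
realistic contingency table and makes polychoric matrices cheap enough to
re-estimate inside bootstrap loops). Pearson and Spearman are selectable for sensitivity analysis;
Spearman and polychoric are invariant under strictly monotone recoding of
the categories, Pearson is not (tested). Correlations are capped at ±0.999
to keep downstream log-determinants finite, and polychoric matrices that
fail positive definiteness are repaired by eigenvalue clipping followed by
re-scaling to unit diagonal (iterated; the Frobenius distance to the input
is reported and the repair is idempotent).

## Network estimation

`glasso_fit` maximises log det Θ − tr(SΘ) − λΣ_{i≠j}|θ_ij| (diagonal
unpenalised, which keeps the λ=0 limit exactly Θ = S⁻¹). The solver is the
coordinate-descent graphical lasso from scikit-learn; its output is verified
in the test suite against an independent numeric optimiser of the same
objective (off-diagonals split into positive/negative parts, L-BFGS-B with
analytic gradients) to 1e-4 in every entry on small problems, and against
the closed-form bivariate soft-threshold case (s = 0.5, λ = 0.2 → ρ = 0.3).

The λ path is log-spaced descending from λ_max = max|s_ij| to
λ_max·`lambda_min_ratio` (defaults: 100 points, ratio 0.01). Model selection
minimises

EBIC = −2ℓ + E·log n + 4·γ·E·log p,  ℓ = (n/2)(log det Θ − tr(SΘ)),

with E the number of nonzero off-diagonal pairs and γ = 0.5 by default.
The published tuning parameter 0.5 is read as this EBIC hyperparameter γ
(the conventional EBIC-glasso setting), not as a fixed λ — the penalty
itself is selected by EBIC minimisation. Ties are broken toward larger λ
(sparser model). Likelihood constants are omitted consistently; selection is
invariant to them. "Mean edge weight" is reported as the mean of |w| over
nonzero edges by default (the signed and all-pairs variants are exposed as
options, since the convention behind the published values 0.043/0.024 is
not stated).

## Node metrics

- **Centrality.** Strength Σ_j|w_ij|; closeness and betweenness on the
  distance transform d = 1/|w| (absolute values, so negative edges still
  bind nodes together). Closeness is 1/Σ(shortest-path distances) within a
  node's connected component; cross-component pairs are excluded rather than
  set to ∞, with component sizes reported (the study's networks are
  connected, so this only matters for degenerate inputs). Betweenness is the
  standard weighted shortest-path count (networkx, unnormalised). Each index
  is also z-standardised across nodes, and the pairwise Pearson correlations
  among the three indices are reported.
- **Predictability** — the share of a node's variance explained by its
  neighbours — is computed analytically from the selected precision on the
  correlation scale as 1 − 1/θ̂_jj, clipped to [0, 1]. At λ = 0 this equals
  the R² of regressing the standardised node on all others (tested to
  1e-6); an unregularised cross-check variant from S⁻¹ is provided. The
  published analysis used an unspecified nodewise procedure for ordinal
  data, so exact numerical agreement is not expected; the analytic Gaussian
  definition is used because it is the quantity the fitted model actually
  implies.

## Resampling diagnostics

- **Edge accuracy:** nonparametric bootstrap of respondents (default
  B = 500), the full pipeline (correlation → glasso/EBIC) re-run per
  resample; per-edge 95% percentile intervals (BCa is deliberately not
  used — percentile intervals match common practice in this literature).
  Bootstrapped difference tests flag a pair of edges (or node strengths) as
  different iff the (α/2, 1−α/2) interval of the replicate differences
  excludes 0.
- **Stability:** case-dropping bootstrap over a drop grid (default 0.05 …
  0.75 in steps of 0.05, 50 subsamples per level, truncated so at least 20
  respondents remain). For each level the Pearson correlation between
  subset and original centralities is recorded; the CS-coefficient is the
  largest drop proportion whose empirical 5th percentile (95% certainty)
  of that correlation stays ≥ 0.7. CS ≥ 0.25 is conventionally usable,
  > 0.5 comfortably stable. Failed replicates (e.g. a constant item in a
  subsample) are dropped and counted, never imputed; >10% failures aborts.

## Two-group comparison

Observed networks are estimated per group; the null is built by pooling
respondents and permuting group labels with the original group sizes
preserved exactly, re-estimating both networks per permutation. Because
"overall connectivity" is ambiguous, two statistics are reported side by
side: |Δ global strength| (global strength = Σ|w_ij| over pairs) and the
maximum absolute edge difference. P-values use the add-one estimator
(1 + #{perm ≥ obs})/(1 + n_perm), which cannot be zero and is conservative
(p stochastically ≥ uniform under the null). Structural similarity is the
Pearson correlation of the vectorised lower-triangle weights, zeros
included.

## Embeddings

- **Ordinal MDS.** Dissimilarity d_ij = √(1 − |r_ij|) by default (strong
  negative association = proximity, matching the connectivity semantics of
  the centrality distances; the signed √(1 − r) variant is a flag).
  Non-metric SMACOF: isotonic regression of configuration distances on the
  dissimilarity rank order gives disparities, rescaled to the distances'
  norm, followed by the Guttman transform; fit is Kruskal stress-1. Stress
  non-increase is asserted at every iteration. The start is the classical
  (Torgerson) MDS solution, so the embedding is deterministic; the seed only
  perturbs rank-deficient starts. Shepard triples (dissimilarity, distance,
  disparity) are returned for diagnostic plots.
- **Force-directed layout** delegates to the seeded Fruchterman–Reingold
  implementation in networkx with |w| as attraction strength.

## Reproducibility and numerical choices

- Every stochastic routine takes an explicit seed; the pipeline spawns
  per-stage child seeds from one master seed via `SeedSequence`, so a run's
  config + seed reproduces every artefact checksum-for-checksum.
- Precision off-diagonals below 1e-8 count as zero edges; the PD tolerance
  for correlation matrices is 1e-8; the glasso solver tolerance defaults to
  1e-4 (tightened in oracle comparisons).
- Near-singular inputs (e.g. polychoric matrices at n < p) can make the
  coordinate-descent solve fail at the weak-penalty end of the λ path; such
  path points are skipped with a warning rather than aborting the selection
  — EBIC never favours those essentially unregularised fits — and
  estimation errors out only if every penalty on the path fails.
- EBIC ties, median ties and the degenerate all-equal-scores split all have
  explicit, documented rules (sparser model; optimal group; all optimal
  with warning).

## Problem sizes used in the validation studies

Chosen as desk-scale defaults that still make the statistical point:

- Solver-vs-oracle: p ∈ {2, 3}, λ ∈ {0, 0.05, 0.2, 0.4}.
- Edge recovery: p = 10, truth density 0.2, n ∈ {250, 1000, 2000},
  20 replicates, polychoric correlations, 40-point λ path. Sensitivity and
  specificity are expected to be monotone non-decreasing in n on average;
  sensitivity saturates at 1 before specificity does.
- Comparison-test calibration: 200 repeats of a null design (both groups of
  n = 200 drawn from one 5-item truth), n_perm = 200, Pearson correlations,
  6-point λ path with coarse solver tolerance. A permutation test applies
  the identical procedure to observed and permuted data, so the coarse
  estimation settings affect power only, not level; the empirical type-I
  error is compared to the nominal 0.05 within binomial error.
- MDS recovery: 12 random planar points, exact distance matrix; stress and
  Procrustes distance to the generating configuration should both be ~0.

## Known limitations

- Polychoric estimation is pairwise (two-step); the assembled matrix may
  need PD repair, which slightly perturbs entries (flagged, distance
  reported).
- Predictability and network estimates inherit the Gaussian-copula working
  model; heavy misspecification (e.g. strongly skewed latent traits) is not
  detected internally.
- The case-dropping grid and replicate counts trade precision for runtime;
  CS-coefficients are grid-valued by construction.
- The published cohort is not deposited, so the package reproduces its
  summary-derived quantities exactly but its data-dependent results
  (specific edge lists, p = 0.007/0.024, r = 0.760/0.630, CS = 0.51/0.54)
  only in kind, on synthetic cohorts, not in number.
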