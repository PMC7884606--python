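# Methods

`trajmix` clusters elderly participants by the shape of their longitudinal
white-matter trajectories: per region, each subject carries a latent linear
course of median fractional anisotropy (FA) — its level at age 60 (the
intercept) and its annual change (the slope) — and subjects are grouped by a
Gaussian mixture over these trajectories. This note records the model, its
assumptions, the numerical choices, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The trajectory mixture model

For subject i, region r, visit j at time t_ij = age − 60 (years):

    y_ijr = a_ir + s_ir t_ij + δ_sex,r · sex_i + δ_apoe,r · apoe4_i + ε_ijr,
    ε_ijr ~ N(0, σ_r²),
    (a_ir, s_ir) | z_i = k ~ N(μ_k(r), diag(τ²_0,kr, τ²_1,kr)),
    z_i ~ Categorical(π),  π ~ Dirichlet(α).

Assumptions worth stating plainly:

- **Linear trajectories.** FA decline over the observed window (2–5 visits,
  typically ~1.25 years apart) is modelled as a straight line per region.
- **Diagonal component covariance.** The cluster-level population over the
  2R trajectory dimensions (R regions × intercept/slope) is diagonal. With
  R = 48 this is what keeps the per-subject marginal likelihood analytic:
  integrating (a, s) out gives a rank-2-perturbed Gaussian per region,

      y_i·r | z_i=k ~ N(X_ir μ_k(r) + offset, X_ir Σ_k(r) X_irᵀ + σ_r² I),

  evaluated in closed form via the Woodbury identity and the matrix
  determinant lemma. Residual cross-region correlation is therefore pushed
  into the cluster structure; this is the model's key simplification.
- **Cluster-invariant fixed effects.** Sex and APOE4 enter as per-region
  confounder adjustments shared by all clusters (reference levels male,
  non-carrier).
- **Ignorable missingness.** Missing FA cells contribute nothing to the
  likelihood; they are never imputed.

Inference is a partially collapsed Gibbs sampler: allocations z are drawn
with the trajectories integrated out (then trajectories are redrawn
immediately, which keeps the kernel valid), and every other block —
trajectories, cluster means and variances, fixed effects, residual
variances, mixing weights — has a conjugate conditional. Empty clusters
fall back to their priors automatically through the conjugate updates.

### Priors and scales

Defaults (all exposed on `McmcConfig`): Dirichlet concentration α = 1;
means and fixed effects N(0, 10) (variance 10 on the z-scored FA scale);
variances Inverse-Gamma(2, 0.5) — **except slope variances**, which use
Inverse-Gamma(2, 0.5·0.05²). Annual slopes on the Z scale are two orders of
magnitude smaller than intercepts (~0.01–0.05/yr), and a 0.5-scale prior
would pin slope SDs near 0.5/yr regardless of the data. That inflates the
trajectory-integrated covariance at 15–25 years from the age-60 origin,
erases the cluster separation in the marginal likelihood, and collapses the
mixture; with the rescaled prior the same fixture is recovered exactly.
This is the single most consequential numerical choice in the package.

Initialization uses pooled per-cluster regressions for μ (a single
subject's two visits extrapolate terribly back to age 60; a cluster's
visits jointly span the age range) and moderate fixed starting SDs
(0.5, 0.05). Chains default to 5000 sweeps, half burn-in, thinning 5 (the
"desk" preset); a 250 000-sweep preset matching the full-scale analysis is
provided as `paper_preset`.

### Label switching, ordering, deviance

Within-chain label switching is corrected after sampling by matching each
draw's cluster means to the running mean of already-relabelled draws with
the Hungarian algorithm on squared distance. Clusters are then renumbered
by white-matter health: descending mean posterior intercept, ties broken
toward the shallower mean slope, so cluster 1 is always the healthiest.
Model fit is the posterior mean observed-data deviance, −2 log L with
trajectories integrated out, which is exactly invariant under relabelling.

## Model selection

Five baseline initializers per candidate K (first-visit FA matrix): an
unsupervised random forest (real rows vs column-permuted rows, 500 trees;
proximity = co-leaf frequency; average-linkage cut at K) and four Gaussian
mixtures (spherical / diagonal / tied / full covariance). Sweeping
K = 2..8 gives 35 fits, each scored on (1) deviance, (2) the fraction of
cluster-mean chains with first-lag autocorrelation above 0.5 — the paper
names the statistic but no cutoff; 0.5 on the thinned chain is this
package's choice — and (3) the number of HPD-uncertain subjects. The
chosen model minimizes the rank-sum of the three criteria (ties toward
smaller K), but the choice is advisory: a K = 2 solution that merely splits
high from low FA can score best while saying nothing new, so the full
ranked table is always written and a forced-K override is provided.

HPD intervals are the exact shortest window over sorted samples containing
⌈level·n⌉ points. A subject's allocation is "certain" only when the 95%
HPD interval of its best cluster's membership probability is disjoint from
the runner-up's — an uncertainty rule this package states explicitly
because published descriptions of HPD-based allocation leave the exact
comparison open.

## Discriminant-region ranking

Each non-reference cluster is contrasted against cluster 1 with a Bayesian
logistic model over all visits: predictors are every region's z-scored FA
plus each region's FA × centred-time interaction, with a per-subject random
intercept; region coefficients get a regularized horseshoe prior and
sampling uses Pólya-Gamma augmentation. Each coefficient is scored by its
posterior direction probability q = max(P(β>0), P(β<0)); a region passes a
contrast at q ≥ 0.60, and the final set keeps regions passing ≥ 2 contrasts
or reaching q ≥ 0.90 in one.

Calibration choices that matter (all verified on planted-effect cohorts):

- **Fixed global scale.** τ₀ = 2·p₀/(p−p₀)/√n_eff with p₀ from an assumed
  5 non-null regions of 48 and the logistic pseudo-SD 2. Giving τ a
  half-Cauchy hyperprior instead lets it drift upward under the many
  weakly-nonzero coefficient draws and visibly weakens shrinkage.
- **Standardized penalized columns.** FA × time columns are ~7× wider than
  FA columns; a shared shrinkage scale across unstandardized columns leaves
  the wide ones effectively unshrunk. Coefficients are mapped back to the
  original scale after sampling.
- **Unit-information visit weights.** Cluster membership is constant within
  subject, so unweighted visit-level rows replicate the same outcome ~2.3
  times against correlated predictors and inflate null evidence. Rows are
  weighted 1/n_visits (each subject contributes one unit of likelihood),
  implemented exactly through PG(w, ψ) draws with fractional shape.
- **Fixed random-intercept scale (SD 1 on the logit).** With a
  subject-constant outcome the random-intercept variance is unidentified:
  sampled freely it runs away (σ_u → ~7), the intercepts absorb the
  cluster signal, and every direction probability collapses to 0.5. The
  intercept is kept (it absorbs overdispersion) but its scale is fixed.
- **Warm start.** Coefficients start at a ridge logistic fit; the horseshoe
  Gibbs otherwise mixes slowly out of the all-null corner.
- Pólya-Gamma draws use the truncated sum-of-gammas series (50 terms) with
  the dropped tail replaced by its exact mean; the tail's variance share is
  ~1e-5. The local-scale conditionals use the standard inverse-gamma
  auxiliary scheme while the coefficient update uses the slab-regularized
  variance (slab width 2) — a practical hybrid.

## Covariate association

The discriminant regions' visit-level FA is regressed on cluster
indicators, sex, APOE4, time, cluster × time and optional biomarkers
(amyloid SUVR, gait speed) with a subject random intercept, weak N(0, 100)
coefficient priors and IG(10⁻³, 10⁻³) variance priors, fitted independently
per output region by conjugate Gibbs. A predictor is flagged when its 95%
highest-density interval excludes 0 (central intervals available behind a
flag). Cross-region residual correlation is deliberately not modelled —
outputs share a design but not a likelihood — which keeps every contract
testable per region.

## The synthetic cohort generator

`default_mcsa_template()` emulates the study design the clustering was
built for: 553 subjects aged 60–85 at baseline, visit-count marginal
(428, 114, 10, 1) for exactly 2/3/4/5 visits (cumulative 553/125/11/1),
visits ~1.25 ± 0.25 years apart, 48 regions on the default manifest, four
latent clusters with mixing (0.455, 0.155, 0.18, 0.21), male fraction
0.54, APOE4 fraction 0.29. Cluster trajectory patterns follow the
qualitative severity ordering: cluster 1 high FA / shallow decline,
cluster 2 low FA / stable, cluster 3 high FA / fast decline (starting near
cluster 1 in commissural and superficial tracts), cluster 4 low FA / fast
decline; commissural tracts decline steepest (slope multiplier 1.6),
brainstem tracts are essentially flat (0.15). Sex lowers FA by 0.1 SD in
half the regions; APOE4 has no effect, matching the absence of
carriership differences across clusters. Where the study reports no value
(visit jitter, age distribution, effect sizes) the defaults are stated
here and in the docstrings as this package's choices.

Visit counts are assigned by deterministic quota — the histogram equals the
marginal exactly on every seed — so count-based checks are exact, and the
generator is bit-reproducible from its seed.

What the generator does **not** emulate: scanner and site effects, skewed
or heavy-tailed FA noise, correlated intercept/slope populations (an
option exists but the default is diagonal, matching the model), informative
dropout, and real spatial correlation between tracts. Passing recovery
tests therefore demonstrate correctness of the inference under the model's
own assumptions, not robustness to their violation.

## Problem sizes used in the tests and acceptance script

Chosen so the full suite runs in minutes on one CPU: sweep cardinality on
N = 60, R = 6 with 200-sweep chains; parameter recovery on N = 150, R = 8,
K = 3 (clusters 4 within-SDs apart in intercept, 3 slope-SDs in slope)
with 3000-sweep chains — recovery is scored against each realized
cluster's mean trajectory (the mean of the generator's per-subject truths),
which is the estimand the fit targets; comparing against the configured
population means would add the generator's own sampling noise that no
estimator can remove. The single-cluster closed-form check runs on
N = 250, R = 3 with balanced covariates and 5000-sweep chains so the
Gibbs-vs-GLS gap is dominated by agreement, not Monte-Carlo error;
discriminant recovery uses 20 replicates of N = 220, R = 10, K = 3 with a
single region carrying a 2-within-SD intercept gap (contrast arms ~156
subjects, echoing the study's cluster sizes); pipeline reproducibility
runs on N = 40 with the 5000-sweep desk preset and K ∈ {2, 3}.

## Known limitations

- The packaged 48-region manifest is a faithful-count stand-in (28 deep,
  20 superficial, midline-merged JHU/Eve-style names); any study's true
  region list can be supplied as JSON and is validated on label
  consistency only.
- The HPD-overlap uncertainty rule and the poor-mixing cutoff are explicit
  operationalizations of criteria whose published descriptions are
  incomplete; both are configurable.
- The discriminant q statistic ranks evidence direction, not effect size;
  with very large cohorts small, real, uninteresting effects will pass the
  0.60 threshold.
- The mixture likelihood treats regions as conditionally independent given
  cluster; strong residual inter-tract correlation is absorbed into extra
  clusters rather than modelled.
- K is swept externally; there is no reversible-jump or nonparametric
  prior over the number of clusters.
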