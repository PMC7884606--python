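# trajmix

Bayesian clustering of longitudinal regional white-matter microstructure.

`trajmix` is for neuroimaging and biostatistics groups who follow elderly
cohorts with repeated diffusion MRI and want to know whether the population
contains distinct patterns of white-matter ageing — healthy agers, stable
low-FA subjects, fast decliners — rather than a single average trajectory.
Its input is a long-format visit table (one row per subject × scan) with
age, sex, APOE4 status and median fractional anisotropy (FA) for each of
~48 atlas tracts; its output is a soft cluster assignment per subject with
explicit uncertainty, per-cluster trajectory profiles, the tracts that
drive the separation, and the association between cluster membership,
covariates and regional FA.

## The model

Each subject i carries a latent linear FA trajectory per region r —
intercept at age 60 and annual slope — drawn from a cluster-specific
Gaussian population, with sex/APOE4 fixed effects and Gaussian noise:

    y_ijr = a_ir + s_ir t_ij + δ_sex,r sex_i + δ_apoe,r apoe4_i + ε_ijr
    (a_ir, s_ir) | z_i = k ~ N(μ_k(r), diag(τ²_0,kr, τ²_1,kr)),  z_i ~ π

Trajectories are integrated out analytically (the component covariance is
diagonal, so each region contributes a rank-2-perturbed Gaussian), which
handles irregular visit times, unequal visit counts and missing cells
without imputation. Inference is conjugate Gibbs sampling; label switching
is corrected by permutation matching and clusters are numbered by
white-matter health (cluster 1 = highest intercept). Candidate cluster
counts K = 2..8 are each fitted from five cross-sectional initializers
(a random-forest proximity clustering and four Gaussian-mixture variants),
and the 35 fits are ranked on deviance, chain mixing and the number of
HPD-uncertain subjects. Downstream, K−1 Pólya-Gamma logistic models with a
regularized-horseshoe prior rank the tracts that separate each cluster from
the reference, and a multi-output mixed linear regression relates cluster
membership and covariates to the discriminant tracts' FA.

See `docs/methods.md` for assumptions, priors, and every numerical choice.

## Worked example

Simulate a small cohort with three known clusters, fit the mixture, and
classify the subjects:

```python
import trajmix

cfg = trajmix.well_separated_config(n_subjects=150, n_regions=8, k_true=3, seed=11)
cohort, truth = trajmix.simulate_cohort(cfg)
zc = trajmix.zscore_regions(cohort)

from trajmix.select import baseline_initializers, classify_subjects
inits = baseline_initializers(zc, 3, seed=7)
model = trajmix.TrajectoryMixture(K=3, n_iter=3000, seed=5).fit(zc, init_labels=inits[1])
chains = trajmix.order_clusters(model.chains_)

labels = classify_subjects(chains)
print("mixing weights:", chains.pi.mean(0).round(3))
print("uncertain subjects:", sum(1 for l in labels if l == "uncertain"))

from sklearn.metrics import adjusted_rand_score
print("ARI vs truth:", round(adjusted_rand_score(
    truth.true_label, chains.allocation_means().argmax(1) + 1), 3))
```

Output:

```
mixing weights: [0.307 0.277 0.416]
uncertain subjects: 0
ARI vs truth: 1.0
```

The recovered weights track this cohort's realized cluster sizes (the
generator mixes equally in expectation; a 150-subject draw lands at
46/41/63), every subject is certainly allocated under the 95% HPD rule,
and the modal allocations reproduce the true clustering exactly.

The same workflow runs end-to-end from the shell:

```
trajmix simulate --seed 0 --out sim/          # cohort CSV + manifest + truth
trajmix sweep --config pipeline.yaml          # QC, z-score, 35-model sweep,
                                              # selection, classification,
                                              # profiles, discriminant set,
                                              # association
trajmix report out/                           # markdown summary
```

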