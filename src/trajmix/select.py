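"""Initializers, the K-sweep, convergence/uncertainty diagnostics and choice.

The clustering is initialized from cross-sectional (first-visit) structure:
one random-forest proximity clustering and four Gaussian-mixture variants
(spherical / diagonal / tied / full covariance) give five hard label sets per
candidate K. Sweeping K = 2..8 over the five initializers yields 35 fits,
each scored on three criteria: observed-data deviance, the fraction of
poorly mixing cluster-mean chains (first-lag autocorrelation above 0.5), and
the number of subjects whose cluster membership is uncertain under
highest-posterior-density (HPD) interval overlap. The chosen model minimizes
the rank-sum of the three criteria, but the full ranked table is always
returned — a severity-only solution (e.g. K = 2 splitting high from low FA)
may score best yet be uninformative, so the final call stays with the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture

from .cohort import LongitudinalCohort
from .mixmodel import (
    McmcConfig,
    PosteriorChains,
    deviance,
    fit_mixture,
    permute_clusters,
    relabel_chains,
)

#: A cluster-mean chain counts as poorly mixing above this first-lag
#: autocorrelation (computed on the thinned, retained chain).
POOR_MIX_LAG1_THRESHOLD = 0.5

#: Trees in the random-forest proximity initializer.
RF_N_TREES = 500


# ---------------------------------------------------------------------------
# Diagnostic primitives


def lag1_autocorrelation(chain) -> float:
    """First-lag autocorrelation: Pearson correlation of x[:-1] with x[1:].

    Constant chains return 0 by convention (a stuck chain is reported
    elsewhere; correlation is simply undefined there).
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("chain must be 1-D with length >= 3")
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class HpdInterval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower > upper")

    def disjoint(self, other: "HpdInterval") -> bool:
        return self.upper < other.lower or other.upper < self.lower


def hpd_interval(samples, level: float = 0.95) -> HpdInterval:
    """Shortest contiguous interval containing ceil(level * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"need >= 20 samples for an HPD interval, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m = int(np.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HpdInterval(float(x[i]), float(x[i + m - 1]), level)


def classify_subjects(chains: PosteriorChains, level: float = 0.95) -> np.ndarray:
    """HPD-based soft classification: cluster id (1..K) or 'uncertain'.

    A subject is certainly allocated to its highest-mean-probability cluster
    only when the level-HPD interval of that cluster's membership probability
    is disjoint from the runner-up cluster's; otherwise 'uncertain'. Requires
    relabelled chains (label switching breaks per-cluster probabilities).
    """
    p = chains.p  # (D, N, K)
    means = p.mean(axis=0)
    order = np.argsort(-means, axis=1)
    out = np.empty(chains.n_subjects, dtype=object)
    for i in range(chains.n_subjects):
        k1, k2 = order[i, 0], order[i, 1]
        h1 = hpd_interval(p[:, i, k1], level)
        h2 = hpd_interval(p[:, i, k2], level)
        out[i] = int(k1) + 1 if h1.disjoint(h2) else "uncertain"
    return out


# ---------------------------------------------------------------------------
# Baseline initializers


def _imputed_baseline(cohort: LongitudinalCohort) -> np.ndarray:
    X = cohort.baseline_matrix()
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = np.take(col_mean, idx[1])
    return X


def _rf_proximity_labels(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Unsupervised random-forest clustering: discriminate the real matrix
    from a column-permuted copy, read co-leaf frequency as proximity, and cut
    the average-linkage tree at K."""
    N = X.shape[0]
    perm = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
    Xall = np.vstack([X, perm])
    yall = np.r_[np.ones(N, dtype=int), np.zeros(N, dtype=int)]
    rf = RandomForestClassifier(
        n_estimators=RF_N_TREES,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    ).fit(Xall, yall)
    leaves = rf.apply(X)  # (N, n_trees)
    prox = np.zeros((N, N))
    for tcol in leaves.T:
        prox += tcol[:, None] == tcol[None, :]
    prox /= leaves.shape[1]
    dist = 1.0 - prox
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=K, criterion="maxclust")


def baseline_initializers(cohort: LongitudinalCohort, K: int, seed: int = 0) -> list[np.ndarray]:
    """Five hard label assignments (1..K) from the first-visit FA matrix:
    random-forest proximity clustering plus Gaussian-mixture fits with
    spherical, diagonal, tied and full covariances."""
    if K < 2:
        raise ValueError("K must be >= 2 for initialization")
    if K > cohort.n_subjects:
        raise ValueError("more clusters than subjects")
    X = _imputed_baseline(cohort)
    rng = np.random.default_rng(seed)
    inits = [_rf_proximity_labels(X, K, rng)]
    for cv in ("spherical", "diag", "tied", "full"):
        gm = GaussianMixture(
            n_components=K,
            covariance_type=cv,
            random_state=int(rng.integers(2**31 - 1)),
            n_init=3,
            reg_covar=1e-5,
        )
        inits.append(gm.fit_predict(X) + 1)
    return inits


# ---------------------------------------------------------------------------
# Sweep and choice


@dataclass
class ModelFitSummary:
    K: int
    init_id: int  # 1..5
    deviance: float = np.nan
    poor_mix_frac: float = np.nan
    n_uncertain: int = -1
    seed: int = 0
    status: str = "ok"  # or "failed: <reason>"
    chains_path: str = ""
    chains: PosteriorChains | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def poor_mixing_fraction(chains: PosteriorChains) -> float:
    """Fraction of monitored cluster-mean chains with first-lag
    autocorrelation above :data:`POOR_MIX_LAG1_THRESHOLD`."""
    D = chains.n_draws
    flat = chains.mu.reshape(D, -1)
    acs = np.array([lag1_autocorrelation(flat[:, j]) for j in range(flat.shape[1])])
    return float(np.mean(acs > POOR_MIX_LAG1_THRESHOLD))


def derive_seed(master_seed: int, K: int, init_id: int) -> int:
    """Deterministic per-fit seed from the master seed and the fit identity."""
    ss = np.random.SeedSequence(entropy=[int(master_seed), int(K), int(init_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def summarize_fit(
    chains: PosteriorChains, cohort: LongitudinalCohort, hpd_level: float = 0.95
) -> tuple[float, float, int]:
    """The three model-quality criteria for a relabelled fit."""
    dev = deviance(chains, cohort)
    pmf = poor_mixing_fraction(chains)
    labels = classify_subjects(chains, hpd_level)
    n_unc = int(sum(1 for lab in labels if lab == "uncertain"))
    return dev, pmf, n_unc


def run_sweep(
    cohort: LongitudinalCohort,
    Ks=range(2, 9),
    mcmc: McmcConfig | None = None,
    master_seed: int = 0,
    hpd_level: float = 0.95,
    keep_chains: bool = False,
) -> list[ModelFitSummary]:
    """Fit every (K, initializer) pair — len(Ks) x 5 fits, 35 by default.

    Each fit gets a deterministic seed derived from the master seed, K and
    the initializer id; a failing fit is recorded in its summary and the
    sweep continues.
    """
    mcmc = mcmc or McmcConfig()
    summaries: list[ModelFitSummary] = []
    for K in Ks:
        try:
            inits = baseline_initializers(cohort, K, seed=derive_seed(master_seed, K, 0))
        except Exception as exc:  # pragma: no cover - defensive
            for init_id in range(1, 6):
                summaries.append(
                    ModelFitSummary(K=K, init_id=init_id, status=f"failed: init: {exc}")
                )
            continue
        for init_id, labels in enumerate(inits, start=1):
            fit_seed = derive_seed(master_seed, K, init_id)
            cfg = McmcConfig(
                n_iter=mcmc.n_iter,
                burn_in_frac=mcmc.burn_in_frac,
                thin=mcmc.thin,
                seed=fit_seed,
                dirichlet_alpha=mcmc.dirichlet_alpha,
                mean_prior_var=mcmc.mean_prior_var,
                var_prior_shape=mcmc.var_prior_shape,
                var_prior_scale=mcmc.var_prior_scale,
                store_trajectories=mcmc.store_trajectories,
            )
            try:
                chains = relabel_chains(fit_mixture(cohort, K, labels, cfg))
                dev, pmf, n_unc = summarize_fit(chains, cohort, hpd_level)
                summaries.append(
                    ModelFitSummary(
                        K=K,
                        init_id=init_id,
                        deviance=dev,
                        poor_mix_frac=pmf,
                        n_uncertain=n_unc,
                        seed=fit_seed,
                        chains=chains if keep_chains else None,
                    )
                )
            except Exception as exc:
                summaries.append(
                    ModelFitSummary(K=K, init_id=init_id, seed=fit_seed, status=f"failed: {exc}")
                )
    return summaries


def sweep_table(summaries: list[ModelFitSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "K": [s.K for s in summaries],
            "init_id": [s.init_id for s in summaries],
            "deviance": [s.deviance for s in summaries],
            "poor_mix_frac": [s.poor_mix_frac for s in summaries],
            "n_uncertain": [s.n_uncertain for s in summaries],
            "seed": [s.seed for s in summaries],
            "status": [s.status for s in summaries],
            "chains_path": [s.chains_path for s in summaries],
        }
    )


def select_model(summaries: list[ModelFitSummary]) -> tuple[pd.DataFrame, ModelFitSummary]:
    """Rank the within-K best fits on the three criteria and pick the
    minimal rank-sum (ties toward smaller K). Returns the full ranked table
    and the chosen summary; the choice is advisory and can be overridden.
    """
    good = [s for s in summaries if s.ok]
    if not good:
        raise ValueError("no successful fits to select from")
    best_per_k: dict[int, ModelFitSummary] = {}
    for s in good:
        cur = best_per_k.get(s.K)
        if cur is None or s.deviance < cur.deviance:
            best_per_k[s.K] = s
    kept = [best_per_k[K] for K in sorted(best_per_k)]
    dev_rank = rankdata([s.deviance for s in kept])
    mix_rank = rankdata([s.poor_mix_frac for s in kept])
    unc_rank = rankdata([s.n_uncertain for s in kept])
    rank_sum = dev_rank + mix_rank + unc_rank
    table = pd.DataFrame(
        {
            "K": [s.K for s in kept],
            "init_id": [s.init_id for s in kept],
            "deviance": [s.deviance for s in kept],
            "poor_mix_frac": [s.poor_mix_frac for s in kept],
            "n_uncertain": [s.n_uncertain for s in kept],
            "deviance_rank": dev_rank,
            "poor_mix_rank": mix_rank,
            "uncertain_rank": unc_rank,
            "rank_sum": rank_sum,
        }
    ).sort_values(["rank_sum", "K"], kind="stable").reset_index(drop=True)
    chosen = kept[
        min(range(len(kept)), key=lambda i: (rank_sum[i], kept[i].K))
    ]
    return table, chosen


def order_clusters(chains: PosteriorChains) -> PosteriorChains:
    """Renumber clusters by white-matter health: descending mean posterior
    intercept across regions, ties broken by descending mean slope
    (shallower decline first). Cluster 1 ends up healthiest."""
    mean_icpt = chains.mu[:, :, :, 0].mean(axis=(0, 2))
    mean_slope = chains.mu[:, :, :, 1].mean(axis=(0, 2))
    perm = np.lexsort((-mean_slope, -mean_icpt))
    return permute_clusters(chains, perm)
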