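"""Bayesian mixture of subject-level linear FA trajectories.

Model. Subject i carries, for every region r, a latent linear trajectory
(a_ir, s_ir) — FA level at age 60 and annual change. Given cluster
z_i = k the trajectory is Gaussian around the cluster profile,

    (a_ir, s_ir) | z_i = k  ~  N(mu_k(r), diag(tau0_kr^2, tau1_kr^2)),

and the observed FA at visit j (time t_ij = age - 60) is

    y_ijr = a_ir + s_ir t_ij + d_sex_r sex_i + d_apoe_r apoe4_i + e_ijr,

with e_ijr ~ N(0, sigma_r^2) independent across regions and visits. The sex
and APOE4 fixed effects are cluster-invariant confounder adjustments. The
component covariance is diagonal over the 2R trajectory dimensions, which
keeps the per-subject marginal likelihood analytic: integrating (a, s) out,

    y_i.r | z_i = k ~ N(X_ir mu_k(r) + offset, X_ir Sigma_k(r) X_ir' + sigma_r^2 I),

a rank-2-perturbed covariance evaluated in closed form via Woodbury. Missing
FA cells simply drop out of the likelihood (ignorable missingness).

Inference is a partially collapsed Gibbs sampler: allocations are drawn from
the trajectory-integrated conditional, then trajectories, cluster means and
variances, fixed effects, residual variances and mixing weights from their
conjugate conditionals. Label switching is corrected after sampling by
greedy permutation matching against running reference means
(:func:`relabel_chains`); model fit is summarized by the posterior mean
observed-data deviance (:func:`deviance`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .cohort import LongitudinalCohort

LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Configuration and containers


@dataclass
class McmcConfig:
    """Sampler settings and prior hyperparameters.

    Priors are conjugate and weakly informative on the Z scale: mixing
    weights Dirichlet(alpha); cluster means and fixed effects Normal with
    variance ``mean_prior_var`` (Normal(0, 10), i.e. SD ~ 3.2); all variances
    Inverse-Gamma(``var_prior_shape``, ``var_prior_scale``).

    ``n_iter`` counts total sweeps including burn-in; the retained chain has
    ``floor(n_iter * (1 - burn_in_frac) / thin)`` draws.
    """

    n_iter: int = 5000
    burn_in_frac: float = 0.5
    thin: int = 5
    seed: int = 0
    dirichlet_alpha: float = 1.0
    mean_prior_var: float = 10.0
    var_prior_shape: float = 2.0
    var_prior_scale: float = 0.5
    # Annual slopes live two orders of magnitude below intercepts on the Z
    # scale (~0.01-0.05/yr), so slope variances get their own prior scale:
    # 0.5 * 0.05^2. A common scale would pin slope SDs near 0.5/yr and wash
    # out all cluster separation in the trajectory-integrated likelihood.
    var_prior_scale_slope: float = 0.00125
    store_trajectories: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not 0.0 < self.burn_in_frac < 1.0:
            raise ValueError("burn_in_frac must lie in (0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return int(np.floor(self.n_iter * (1.0 - self.burn_in_frac) / self.thin))


def desk_preset(seed: int = 0, **kw) -> McmcConfig:
    """Workstation-scale chain: 5000 sweeps, half burn-in, thin 5."""
    return McmcConfig(n_iter=5000, seed=seed, **kw)


def paper_preset(seed: int = 0, **kw) -> McmcConfig:
    """Full-scale chain of 250 000 sweeps including burn-in."""
    return McmcConfig(n_iter=250000, seed=seed, **kw)


@dataclass
class TrajectoryMixtureModel:
    """Point parameters of the mixture (one draw, or posterior means)."""

    K: int
    pi: np.ndarray  # (K,)
    mu: np.ndarray  # (K, R, 2)
    sigma_comp: np.ndarray  # (K, R, 2) SDs of (intercept, slope) per cluster
    delta: np.ndarray  # (R, 2) fixed effects (sex, apoe4)
    sigma_res: np.ndarray  # (R,) residual SDs

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_comp = np.asarray(self.sigma_comp, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.sigma_res = np.asarray(self.sigma_res, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("mixing weights must sum to 1")
        if (self.sigma_comp <= 0).any() or (self.sigma_res <= 0).any():
            raise ValueError("all SDs must be strictly positive")
        R = self.mu.shape[1]
        if self.mu.shape != (self.K, R, 2) or self.sigma_comp.shape != (self.K, R, 2):
            raise ValueError("mu / sigma_comp dimensions inconsistent")


@dataclass
class PosteriorChains:
    """Retained MCMC draws of every model block plus per-draw allocations."""

    pi: np.ndarray  # (D, K)
    mu: np.ndarray  # (D, K, R, 2)
    sigma_comp: np.ndarray  # (D, K, R, 2)
    delta: np.ndarray  # (D, R, 2)
    sigma_res: np.ndarray  # (D, R)
    z: np.ndarray  # (D, N) in 0..K-1
    p: np.ndarray  # (D, N, K) allocation probabilities
    traj: np.ndarray | None  # (D, N, R, 2) or None
    config: McmcConfig
    region_ids: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.z.shape[1]

    def posterior_mean_model(self) -> TrajectoryMixtureModel:
        pi = self.pi.mean(0)
        pi = pi / pi.sum()
        return TrajectoryMixtureModel(
            K=self.K,
            pi=pi,
            mu=self.mu.mean(0),
            sigma_comp=self.sigma_comp.mean(0),
            delta=self.delta.mean(0),
            sigma_res=self.sigma_res.mean(0),
        )

    def allocation_means(self) -> np.ndarray:
        """Posterior-mean subjects x clusters probability matrix."""
        return self.p.mean(0)

    def save(self, path) -> None:
        """Single-archive serialization (.npz) with a JSON config sidecar."""
        path = Path(path)
        arrays = dict(
            pi=self.pi,
            mu=self.mu,
            sigma_comp=self.sigma_comp,
            delta=self.delta,
            sigma_res=self.sigma_res,
            z=self.z,
            p=self.p,
        )
        if self.traj is not None:
            arrays["traj"] = self.traj
        np.savez_compressed(path, **arrays)
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "region_ids": self.region_ids,
                    "subject_ids": self.subject_ids,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "PosteriorChains":
        path = Path(path)
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(
            pi=arrays["pi"],
            mu=arrays["mu"],
            sigma_comp=arrays["sigma_comp"],
            delta=arrays["delta"],
            sigma_res=arrays["sigma_res"],
            z=arrays["z"],
            p=arrays["p"],
            traj=arrays.get("traj"),
            config=McmcConfig(**meta["config"]),
            region_ids=meta["region_ids"],
            subject_ids=meta["subject_ids"],
        )


# ---------------------------------------------------------------------------
# Sufficient statistics

# The per-(subject, region) statistics of the visit design [1, t] restricted
# to observed cells: n, sum t, sum t^2, sum y, sum y t, sum y^2. Everything
# downstream (marginal likelihood, trajectory conditionals, residual sums of
# squares) is a closed-form function of these.


class _Stats:
    def __init__(self, cohort: LongitudinalCohort):
        arr = cohort.to_arrays()
        t, y, obs = arr["t"], arr["y"], arr["obs"]
        self.sex = arr["sex"]
        self.apoe4 = arr["apoe4"]
        self.subject_ids = arr["subject_ids"]
        self.region_ids = arr["region_ids"]
        self.N, _, self.R = y.shape
        tb = t[:, :, None]
        self.n = obs.sum(axis=1).astype(float)  # (N, R)
        self.St = np.where(obs, tb, 0.0).sum(axis=1)
        self.Stt = np.where(obs, tb**2, 0.0).sum(axis=1)
        self.Sy = np.where(obs, y, 0.0).sum(axis=1)
        self.Syt = np.where(obs, y * tb, 0.0).sum(axis=1)
        self.Syy = np.where(obs, y**2, 0.0).sum(axis=1)
        if not (
            np.isfinite(self.Sy).all()
            and np.isfinite(self.Syt).all()
            and np.isfinite(self.Syy).all()
        ):
            raise ValueError("non-finite FA values in cohort")
        self.cov = np.stack([self.sex, self.apoe4], axis=1)  # (N, 2)

    def offset(self, delta: np.ndarray) -> np.ndarray:
        """Covariate offset per (subject, region): constant over visits."""
        return self.cov @ delta.T  # (N, R)

    def w_stats(self, delta: np.ndarray):
        """Offset-corrected sums: w = y - offset."""
        off = self.offset(delta)
        Sw = self.Sy - self.n * off
        Swt = self.Syt - self.St * off
        Sww = self.Syy - 2.0 * off * self.Sy + self.n * off**2
        return Sw, Swt, Sww


def _marginal_loglik_stats(
    stats: _Stats,
    pi: np.ndarray,
    mu: np.ndarray,
    sigma_comp: np.ndarray,
    delta: np.ndarray,
    sigma_res: np.ndarray,
):
    """Per-subject, per-cluster log marginal likelihood, trajectories
    integrated out. Returns (N, K) array (likelihood only, no log pi)."""
    Sw, Swt, Sww = stats.w_stats(delta)
    n, St, Stt = stats.n, stats.St, stats.Stt
    # broadcast shapes: subject axis 0, cluster axis 1, region axis 2
    n_b = n[:, None, :]
    St_b = St[:, None, :]
    Stt_b = Stt[:, None, :]
    mu0 = mu[None, :, :, 0]
    mu1 = mu[None, :, :, 1]
    tau0sq = sigma_comp[None, :, :, 0] ** 2
    tau1sq = sigma_comp[None, :, :, 1] ** 2
    s2 = (sigma_res**2)[None, None, :]
    Se = Sw[:, None, :] - n_b * mu0 - St_b * mu1
    Ste = Swt[:, None, :] - St_b * mu0 - Stt_b * mu1
    See = (
        Sww[:, None, :]
        - 2.0 * mu0 * Sw[:, None, :]
        - 2.0 * mu1 * Swt[:, None, :]
        + mu0**2 * n_b
        + 2.0 * mu0 * mu1 * St_b
        + mu1**2 * Stt_b
    )
    A11 = 1.0 / tau0sq + n_b / s2
    A12 = St_b / s2
    A22 = 1.0 / tau1sq + Stt_b / s2
    detA = A11 * A22 - A12**2
    quad = See / s2 - (A22 * Se**2 - 2.0 * A12 * Se * Ste + A11 * Ste**2) / (detA * s2**2)
    logdet = n_b * np.log(s2) + np.log(tau0sq) + np.log(tau1sq) + np.log(detA)
    ll = -0.5 * (n_b * LOG2PI + logdet + quad)  # (N, K, R)
    return ll.sum(axis=2)


def subject_marginal_loglik(model: TrajectoryMixtureModel, subject, manifest=None) -> np.ndarray:
    """Per-cluster log marginal likelihood of one subject's observations.

    ``subject`` is a :class:`~trajmix.cohort.SubjectRecord`; ``manifest``
    fixes the region order (defaults to the order of the model arrays using
    the subject's own FA keys sorted, so pass a manifest for >1 region).
    Trajectories are integrated analytically; missing cells are omitted.
    """
    from .cohort import LongitudinalCohort, RegionManifest, Region

    if manifest is None:
        rids = sorted({rid for v in subject.visits for rid in v.fa})
        manifest = RegionManifest(
            Region(rid, rid, "projection", "deep") for rid in rids
        )
    if not any(np.isfinite(val) for v in subject.visits for val in v.fa.values()):
        raise ValueError(f"subject {subject.subject_id} has no observed FA values")
    mini = LongitudinalCohort([subject], manifest)
    stats = _Stats(mini)
    ll = _marginal_loglik_stats(
        stats, model.pi, model.mu, model.sigma_comp, model.delta, model.sigma_res
    )
    return ll[0]


# ---------------------------------------------------------------------------
# Gibbs sampler


def _pooled_cluster_lines(stats: _Stats, z: np.ndarray, K: int) -> np.ndarray:
    """Initial cluster mean (intercept, slope) per region from a pooled
    regression over each cluster's observations. Pooling keeps the intercept
    well conditioned: a single subject's two visits extrapolate poorly back
    to age 60, but the cluster's visits jointly span the age range."""
    mu = np.zeros((K, R_ := stats.R, 2))
    for k in range(K):
        m = z == k
        if not m.any():
            continue
        n = stats.n[m].sum(axis=0)
        St = stats.St[m].sum(axis=0)
        Stt = stats.Stt[m].sum(axis=0)
        Sy = stats.Sy[m].sum(axis=0)
        Syt = stats.Syt[m].sum(axis=0)
        det = n * Stt - St**2
        good = det > 1e-10
        with np.errstate(divide="ignore", invalid="ignore"):
            b0 = np.where(good, (Stt * Sy - St * Syt) / det, Sy / np.maximum(n, 1.0))
            b1 = np.where(good, (n * Syt - St * Sy) / det, 0.0)
        mu[k, :, 0] = np.nan_to_num(b0)
        mu[k, :, 1] = np.nan_to_num(b1)
    return mu


def fit_mixture(
    cohort: LongitudinalCohort,
    K: int,
    init_labels: np.ndarray | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorChains:
    """Run the Gibbs sampler and return retained chains.

    ``init_labels`` carries one label in 1..K per subject (e.g. from a
    baseline initializer); by default subjects are assigned round-robin.
    The cohort should be z-scored so the weakly-informative priors are on
    the right scale. Fully reproducible from ``mcmc.seed``.
    """
    mcmc = mcmc or McmcConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    if cohort.n_subjects < K:
        raise ValueError(f"fewer subjects ({cohort.n_subjects}) than clusters ({K})")
    stats = _Stats(cohort)
    N, R = stats.N, stats.R
    rng = np.random.default_rng(mcmc.seed)

    if init_labels is None:
        z = np.arange(N) % K
    else:
        init_labels = np.asarray(init_labels)
        if init_labels.shape != (N,):
            raise ValueError("init_labels must have one entry per subject")
        if init_labels.min() < 1 or init_labels.max() > K:
            raise ValueError("init_labels must lie in 1..K")
        z = init_labels.astype(int) - 1

    # initial state: pooled per-cluster lines, moderate component spread
    traj = np.zeros((N, R, 2))  # overwritten by its first conditional draw
    mu = _pooled_cluster_lines(stats, z, K)
    sigma_comp = np.empty((K, R, 2))
    sigma_comp[:, :, 0] = 0.5
    sigma_comp[:, :, 1] = 0.05
    delta = np.zeros((R, 2))
    sigma_res = np.full(R, 0.5)
    pi = np.bincount(z, minlength=K).astype(float) + 1.0
    pi /= pi.sum()

    a0, b0 = mcmc.var_prior_shape, mcmc.var_prior_scale
    b_comp = np.array([b0, mcmc.var_prior_scale_slope])  # (intercept, slope)
    v0 = mcmc.mean_prior_var
    alpha = mcmc.dirichlet_alpha

    D = mcmc.n_retained
    burn = int(np.ceil(mcmc.n_iter * mcmc.burn_in_frac))
    out_pi = np.empty((D, K))
    out_mu = np.empty((D, K, R, 2))
    out_sc = np.empty((D, K, R, 2))
    out_delta = np.empty((D, R, 2))
    out_sr = np.empty((D, R))
    out_z = np.empty((D, N), dtype=np.int64)
    out_p = np.empty((D, N, K))
    out_traj = np.empty((D, N, R, 2)) if mcmc.store_trajectories else None

    n_ir, St_ir, Stt_ir = stats.n, stats.St, stats.Stt
    nobs_r = n_ir.sum(axis=0)  # observations per region
    d = 0
    for it in range(mcmc.n_iter):
        # --- allocations z, collapsed over trajectories
        ll = _marginal_loglik_stats(stats, pi, mu, sigma_comp, delta, sigma_res)
        logp = np.log(pi)[None, :] + ll
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(N)
        z = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        z = np.minimum(z, K - 1)

        # --- per-subject trajectories | z (2x2 conjugate Gaussian)
        Sw, Swt, _ = stats.w_stats(delta)
        tau0sq = sigma_comp[z, :, 0] ** 2  # (N, R)
        tau1sq = sigma_comp[z, :, 1] ** 2
        mu_z = mu[z]  # (N, R, 2)
        s2 = sigma_res**2
        P11 = 1.0 / tau0sq + n_ir / s2
        P12 = St_ir / s2
        P22 = 1.0 / tau1sq + Stt_ir / s2
        bvec0 = Sw / s2 + mu_z[:, :, 0] / tau0sq
        bvec1 = Swt / s2 + mu_z[:, :, 1] / tau1sq
        detP = P11 * P22 - P12**2
        m0 = (P22 * bvec0 - P12 * bvec1) / detP
        m1 = (P11 * bvec1 - P12 * bvec0) / detP
        # sample via 2x2 Cholesky of the precision
        L11 = np.sqrt(P11)
        L21 = P12 / L11
        L22 = np.sqrt(np.maximum(P22 - L21**2, 1e-300))
        e0 = rng.standard_normal((N, R))
        e1 = rng.standard_normal((N, R))
        u1 = e1 / L22
        u0 = (e0 - L21 * u1) / L11
        traj[:, :, 0] = m0 + u0
        traj[:, :, 1] = m1 + u1

        # --- cluster means and variances | trajectories, z
        onehot = np.zeros((N, K))
        onehot[np.arange(N), z] = 1.0
        nk = onehot.sum(axis=0)  # (K,)
        sum_traj = np.einsum("nk,nrd->krd", onehot, traj)
        sumsq_traj = np.einsum("nk,nrd->krd", onehot, traj**2)
        tausq = sigma_comp**2
        post_var = 1.0 / (nk[:, None, None] / tausq + 1.0 / v0)
        post_mean = post_var * (sum_traj / tausq)
        mu = post_mean + np.sqrt(post_var) * rng.standard_normal((K, R, 2))
        SS = sumsq_traj - 2.0 * mu * sum_traj + nk[:, None, None] * mu**2
        shape = a0 + nk[:, None, None] / 2.0
        scale = b_comp[None, None, :] + SS / 2.0
        tausq_new = scale / rng.gamma(shape, 1.0, size=(K, R, 2))
        sigma_comp = np.sqrt(tausq_new)

        # --- fixed effects | trajectories (2x2 conjugate per region)
        Sd = stats.Sy - traj[:, :, 0] * n_ir - traj[:, :, 1] * St_ir  # (N, R)
        sex, ap = stats.sex, stats.apoe4
        C11 = np.einsum("n,nr->r", sex**2, n_ir)
        C12 = np.einsum("n,nr->r", sex * ap, n_ir)
        C22 = np.einsum("n,nr->r", ap**2, n_ir)
        bd0 = np.einsum("n,nr->r", sex, Sd)
        bd1 = np.einsum("n,nr->r", ap, Sd)
        Q11 = C11 / s2 + 1.0 / v0
        Q12 = C12 / s2
        Q22 = C22 / s2 + 1.0 / v0
        detQ = Q11 * Q22 - Q12**2
        md0 = (Q22 * bd0 / s2 - Q12 * bd1 / s2) / detQ
        md1 = (Q11 * bd1 / s2 - Q12 * bd0 / s2) / detQ
        G11 = np.sqrt(Q11)
        G21 = Q12 / G11
        G22 = np.sqrt(np.maximum(Q22 - G21**2, 1e-300))
        f0 = rng.standard_normal(R)
        f1 = rng.standard_normal(R)
        g1 = f1 / G22
        g0 = (f0 - G21 * g1) / G11
        delta = np.stack([md0 + g0, md1 + g1], axis=1)

        # --- residual variances | trajectories, delta
        Sw, Swt, Sww = stats.w_stats(delta)
        a_t, s_t = traj[:, :, 0], traj[:, :, 1]
        ssr = (
            Sww
            - 2.0 * a_t * Sw
            - 2.0 * s_t * Swt
            + a_t**2 * n_ir
            + 2.0 * a_t * s_t * St_ir
            + s_t**2 * Stt_ir
        ).sum(axis=0)
        sigma_res = np.sqrt(
            (b0 + ssr / 2.0) / rng.gamma(a0 + nobs_r / 2.0, 1.0, size=R)
        )

        # --- mixing weights | z
        pi = rng.dirichlet(alpha + nk)

        if it >= burn and (it - burn) % mcmc.thin == 0 and d < D:
            out_pi[d] = pi
            out_mu[d] = mu
            out_sc[d] = sigma_comp
            out_delta[d] = delta
            out_sr[d] = sigma_res
            out_z[d] = z
            out_p[d] = p
            if out_traj is not None:
                out_traj[d] = traj
            d += 1

    return PosteriorChains(
        pi=out_pi[:d],
        mu=out_mu[:d],
        sigma_comp=out_sc[:d],
        delta=out_delta[:d],
        sigma_res=out_sr[:d],
        z=out_z[:d],
        p=out_p[:d],
        traj=out_traj[:d] if out_traj is not None else None,
        config=mcmc,
        region_ids=list(stats.region_ids),
        subject_ids=list(stats.subject_ids),
    )


# ---------------------------------------------------------------------------
# Post-processing


def relabel_chains(chains: PosteriorChains) -> PosteriorChains:
    """Undo label switching by permutation-matching each draw's cluster means
    to the running mean of already-relabelled draws (optimal assignment on
    squared distance). Allocations and probabilities are permuted consistently.
    """
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    K = chains.K
    pi = chains.pi.copy()
    mu = chains.mu.copy()
    sc = chains.sigma_comp.copy()
    z = chains.z.copy()
    p = chains.p.copy()
    ref = mu[0].reshape(K, -1).copy()
    count = 1.0
    for dIdx in range(1, chains.n_draws):
        flat = mu[dIdx].reshape(K, -1)
        cost = ((flat[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        row, col = linear_sum_assignment(cost)
        if not np.array_equal(col, row):
            newlab = np.empty(K, dtype=int)
            newlab[row] = col
            inv = np.argsort(newlab)  # new position l takes old component inv[l]
            pi[dIdx] = pi[dIdx, inv]
            mu[dIdx] = mu[dIdx, inv]
            sc[dIdx] = sc[dIdx, inv]
            p[dIdx] = p[dIdx][:, inv]
            z[dIdx] = newlab[z[dIdx]]
        ref = (ref * count + mu[dIdx].reshape(K, -1)) / (count + 1.0)
        count += 1.0
    return PosteriorChains(
        pi=pi,
        mu=mu,
        sigma_comp=sc,
        delta=chains.delta.copy(),
        sigma_res=chains.sigma_res.copy(),
        z=z,
        p=p,
        traj=chains.traj.copy() if chains.traj is not None else None,
        config=chains.config,
        region_ids=list(chains.region_ids),
        subject_ids=list(chains.subject_ids),
    )


def permute_clusters(chains: PosteriorChains, perm: np.ndarray) -> PosteriorChains:
    """Apply one fixed cluster permutation to every draw.

    ``perm[l]`` is the current cluster index that becomes new cluster ``l``.
    """
    perm = np.asarray(perm, dtype=int)
    old_to_new = np.argsort(perm)
    return PosteriorChains(
        pi=chains.pi[:, perm],
        mu=chains.mu[:, perm],
        sigma_comp=chains.sigma_comp[:, perm],
        delta=chains.delta.copy(),
        sigma_res=chains.sigma_res.copy(),
        z=old_to_new[chains.z],
        p=chains.p[:, :, perm],
        traj=chains.traj.copy() if chains.traj is not None else None,
        config=chains.config,
        region_ids=list(chains.region_ids),
        subject_ids=list(chains.subject_ids),
    )


def deviance(chains: PosteriorChains, cohort: LongitudinalCohort) -> float:
    """Posterior mean observed-data deviance, -2 log L with trajectories
    integrated out: mean over retained draws of
    -2 sum_i log sum_k pi_k exp(loglik_ik)."""
    if chains.n_draws < 1:
        raise ValueError("chains retain no draws")
    stats = _Stats(cohort)
    devs = np.empty(chains.n_draws)
    for dIdx in range(chains.n_draws):
        ll = _marginal_loglik_stats(
            stats,
            chains.pi[dIdx],
            chains.mu[dIdx],
            chains.sigma_comp[dIdx],
            chains.delta[dIdx],
            chains.sigma_res[dIdx],
        )
        logmix = logsumexp(np.log(chains.pi[dIdx])[None, :] + ll, axis=1)
        if not np.isfinite(logmix).all():
            bad = int(np.flatnonzero(~np.isfinite(logmix))[0])
            sid = chains.subject_ids[bad] if chains.subject_ids else str(bad)
            raise FloatingPointError(f"non-finite likelihood for subject {sid}")
        devs[dIdx] = -2.0 * logmix.sum()
    return float(devs.mean())


# ---------------------------------------------------------------------------
# Estimator facade


class TrajectoryMixture(BaseEstimator):
    """Mixture-of-trajectories clusterer with an sklearn-style surface.

    Parameters mirror :class:`McmcConfig`; ``fit`` accepts a
    :class:`~trajmix.cohort.LongitudinalCohort` (z-scored) and optional
    initial labels, runs the Gibbs sampler, corrects label switching and
    exposes the usual fitted attributes.

    Attributes
    ----------
    chains_ : PosteriorChains
        Relabelled retained draws.
    allocation_probs_ : ndarray of shape (n_subjects, K)
        Posterior-mean membership probabilities for the training cohort.
    labels_ : ndarray of shape (n_subjects,)
        Modal cluster per subject, in 1..K.
    deviance_ : float
        Posterior mean observed-data deviance on the training cohort.
    """

    def __init__(
        self,
        K: int = 4,
        n_iter: int = 5000,
        burn_in_frac: float = 0.5,
        thin: int = 5,
        seed: int = 0,
        dirichlet_alpha: float = 1.0,
        mean_prior_var: float = 10.0,
        var_prior_shape: float = 2.0,
        var_prior_scale: float = 0.5,
        store_trajectories: bool = True,
    ):
        self.K = K
        self.n_iter = n_iter
        self.burn_in_frac = burn_in_frac
        self.thin = thin
        self.seed = seed
        self.dirichlet_alpha = dirichlet_alpha
        self.mean_prior_var = mean_prior_var
        self.var_prior_shape = var_prior_shape
        self.var_prior_scale = var_prior_scale
        self.store_trajectories = store_trajectories

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_iter=self.n_iter,
            burn_in_frac=self.burn_in_frac,
            thin=self.thin,
            seed=self.seed,
            dirichlet_alpha=self.dirichlet_alpha,
            mean_prior_var=self.mean_prior_var,
            var_prior_shape=self.var_prior_shape,
            var_prior_scale=self.var_prior_scale,
            store_trajectories=self.store_trajectories,
        )

    def fit(self, X: LongitudinalCohort, y=None, init_labels: np.ndarray | None = None):
        chains = fit_mixture(X, self.K, init_labels=init_labels, mcmc=self._config())
        self.chains_ = relabel_chains(chains)
        self.allocation_probs_ = self.chains_.allocation_means()
        self.labels_ = self.allocation_probs_.argmax(axis=1) + 1
        self.deviance_ = deviance(self.chains_, X)
        self.model_ = self.chains_.posterior_mean_model()
        return self

    def predict_proba(self, X: LongitudinalCohort) -> np.ndarray:
        """Allocation probabilities for a cohort under the posterior-mean
        parameters (plug-in, not re-sampled)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        stats = _Stats(X)
        m = self.model_
        ll = _marginal_loglik_stats(stats, m.pi, m.mu, m.sigma_comp, m.delta, m.sigma_res)
        logp = np.log(m.pi)[None, :] + ll
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: LongitudinalCohort) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1) + 1

    def fit_predict(self, X: LongitudinalCohort, y=None, **kw) -> np.ndarray:
        return self.fit(X, **kw).labels_
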