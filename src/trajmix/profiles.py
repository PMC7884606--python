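"""Post-fit descriptive surfaces for an ordered, relabelled fit.

Three views summarize a fitted mixture: fitted FA values per cluster and
region at chosen ages (the intercept is the age-60 value and trajectories
are linear, so any age is an affine read-out); intercept/slope heat tables
with clusters ordered by profile similarity; and a classical
multidimensional-scaling embedding of the subjects x clusters allocation
probability matrix, which places each subject by how its membership
probabilities compare with every other subject's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .mixmodel import PosteriorChains

#: Reference covariate setting for fitted values: male, APOE4 non-carrier
#: (both coded 0, the model's reference levels).
REFERENCE_COVARIATES = {"sex": 0, "apoe4": 0}


@dataclass
class ClusterProfile:
    """Posterior-mean per-cluster trajectory summaries."""

    intercept: pd.DataFrame  # clusters x regions, FA at age 60
    slope: pd.DataFrame  # clusters x regions, annual FA change
    fitted: dict[float, pd.DataFrame]  # age -> clusters x regions fitted FA
    reference: dict[str, int]


def fitted_profiles(
    chains: PosteriorChains,
    ages=(60.0, 75.0, 90.0),
    reference: dict[str, int] | None = None,
) -> ClusterProfile:
    """Fitted FA per cluster/region at the requested ages.

    fitted_kr(age) = E[b0_kr] + E[b1_kr] (age - 60) + covariate offset at the
    reference setting (male, APOE4-negative by default, where the offset is
    zero). The model is parameterized from age 60, so younger ages error.
    """
    reference = dict(REFERENCE_COVARIATES, **(reference or {}))
    ages = [float(a) for a in ages]
    if any(a < 60.0 for a in ages):
        raise ValueError("model is parameterized from age 60; ages must be >= 60")
    mu = chains.mu.mean(axis=0)  # (K, R, 2)
    delta = chains.delta.mean(axis=0)  # (R, 2)
    offset = reference["sex"] * delta[:, 0] + reference["apoe4"] * delta[:, 1]
    K = mu.shape[0]
    cols = chains.region_ids or [f"r{i}" for i in range(mu.shape[1])]
    idx = [f"cluster_{k + 1}" for k in range(K)]
    icpt = pd.DataFrame(mu[:, :, 0], index=idx, columns=cols)
    slope = pd.DataFrame(mu[:, :, 1], index=idx, columns=cols)
    fitted = {
        age: pd.DataFrame(
            mu[:, :, 0] + mu[:, :, 1] * (age - 60.0) + offset[None, :],
            index=idx,
            columns=cols,
        )
        for age in ages
    }
    return ClusterProfile(intercept=icpt, slope=slope, fitted=fitted, reference=reference)


@dataclass
class HeatTable:
    intercept: pd.DataFrame  # regions x clusters, similarity-ordered columns
    slope: pd.DataFrame
    cluster_order: list[int]  # 1-based cluster ids, dendrogram leaf order
    linkage_matrix: np.ndarray


def trajectory_heat_table(chains: PosteriorChains) -> HeatTable:
    """Intercept and slope matrices with clusters ordered so the most
    similar trajectory profiles sit in adjacent columns (average-linkage
    hierarchical clustering on the concatenated intercept+slope profile)."""
    mu = chains.mu.mean(axis=0)  # (K, R, 2)
    K = mu.shape[0]
    profile = mu.reshape(K, -1)
    if K > 1:
        Z = linkage(profile, method="average")
        order = list(leaves_list(Z))
    else:
        Z = np.zeros((0, 4))
        order = [0]
    cols = [f"cluster_{k + 1}" for k in order]
    rows = chains.region_ids or [f"r{i}" for i in range(mu.shape[1])]
    icpt = pd.DataFrame(mu[order, :, 0].T, index=rows, columns=cols)
    slope = pd.DataFrame(mu[order, :, 1].T, index=rows, columns=cols)
    return HeatTable(
        intercept=icpt,
        slope=slope,
        cluster_order=[k + 1 for k in order],
        linkage_matrix=Z,
    )


@dataclass
class Embedding:
    coords: np.ndarray  # (N, n_components)
    eigenvalues: np.ndarray  # (n_components,), non-increasing

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")


def mds_embedding(prob_matrix: np.ndarray, n_components: int = 3) -> Embedding:
    """Classical (Torgerson) MDS of the allocation-probability matrix.

    Squared Euclidean distances between subject rows are double-centred into
    a Gram matrix whose top eigenvectors, scaled by the square root of their
    eigenvalues, give the coordinates. Deterministic up to sign; each axis is
    oriented so its largest-magnitude coordinate is positive. Negative
    eigenvalues (impossible for genuine Euclidean input) are clipped to zero.
    """
    P = np.asarray(prob_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] < 4:
        raise ValueError("need a 2-D matrix with at least 4 subjects")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("allocation probability rows must sum to 1")
    N = P.shape[0]
    sq = (P**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * P @ P.T
    J = np.eye(N) - np.full((N, N), 1.0 / N)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[idx], 0.0, None)
    V = evecs[:, idx]
    coords = V * np.sqrt(lam)[None, :]
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return Embedding(coords=coords, eigenvalues=lam)
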