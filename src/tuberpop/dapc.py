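"""Discriminant analysis of principal components (DAPC) for dosage panels.

The workflow mirrors the standard population-structure recipe: a PCA
reduces the dosage matrix to a few synthetic axes, k-means over a grid of
cluster counts scores each K by a BIC, and a linear discriminant analysis
on the retained principal components yields axes that maximise
between-group relative to within-group variance. Membership posteriors,
stratified cross-validation of the retained-PC count, and selection of
"structural" loci (the markers driving a discriminant axis) complete the
engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .panel import GenotypePanel, impute_missing_mean

__all__ = [
    "PCAModel",
    "ClusterSearchResult",
    "DAPCModel",
    "XvalResult",
    "SnpzipResult",
    "fit_pca",
    "split_structural",
    "kmeans_partition",
    "find_clusters",
    "fit_dapc",
    "predict_membership",
    "cross_validate",
    "snpzip",
]


@dataclass
class PCAModel:
    """Centered (optionally scaled) principal-component decomposition."""

    column_means: np.ndarray
    column_scales: np.ndarray  # divisor per column; 1.0 where not scaled
    loadings: np.ndarray  # loci x components, orthonormal columns
    eigenvalues: np.ndarray  # component variances, non-increasing
    scores: np.ndarray  # samples x components
    variance_fraction: np.ndarray  # cumulative proportion of variance

    def transform(self, matrix: np.ndarray, n_components: int | None = None) -> np.ndarray:
        z = (np.asarray(matrix, dtype=float) - self.column_means) / self.column_scales
        load = self.loadings if n_components is None else self.loadings[:, :n_components]
        return z @ load


@dataclass
class ClusterSearchResult:
    k_grid: np.ndarray
    wss: np.ndarray
    bic: np.ndarray
    best_k: int
    assignments: np.ndarray  # 1..best_k per sample
    seed: int


@dataclass
class DAPCModel:
    """Fitted DAPC: PCA stage parameters plus discriminant axes.

    ``memberships`` are posterior probabilities from equal-prior Gaussian
    densities with common isotropic covariance in discriminant space, i.e. a
    softmax of minus half the squared Euclidean distance to each group
    centroid.
    """

    group_names: list
    n_pca: int
    n_da: int
    pca: PCAModel
    da_eigenvalues: np.ndarray  # between/within variance ratios, non-increasing
    da_coefficients: np.ndarray  # n_pca x n_da
    individual_coords: np.ndarray  # samples x n_da
    group_centroids: np.ndarray  # groups x n_da
    memberships: np.ndarray  # samples x groups, rows sum to 1
    variable_loadings: np.ndarray  # loci x n_da

    def assignments(self) -> np.ndarray:
        return np.asarray(self.group_names, dtype=object)[
            np.argmax(self.memberships, axis=1)
        ]


@dataclass
class XvalResult:
    n_pca_grid: np.ndarray
    success: np.ndarray  # grid x replicates held-out assignment success
    rmse: np.ndarray
    best_n_pca: int


@dataclass
class SnpzipResult:
    axis: int
    abs_loadings: np.ndarray
    structural: list  # locus ids, sorted by |loading| descending
    non_structural: list


def fit_pca(matrix: np.ndarray, scale: bool = False) -> PCAModel:
    """PCA of a complete samples x loci matrix via SVD of the centered data.

    With ``scale`` each column is divided by its standard deviation;
    zero-variance columns are left centered only. Eigenvalues are sample
    variances (n-1 denominator) of the component scores.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    n = X.shape[0]
    means = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        scales = np.where(sd > 0, sd, 1.0)
    else:
        scales = np.ones(X.shape[1])
    Z = (X - means) / scales
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    scores = U * s
    total = eigenvalues.sum()
    cum = np.cumsum(eigenvalues) / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAModel(
        column_means=means,
        column_scales=scales,
        loadings=Vt.T,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fraction=cum,
    )


def kmeans_partition(
    scores: np.ndarray, k: int, n_init: int = 10, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Best-of-``n_init`` k-means on PC scores; returns (labels 1..k, WSS)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds the {scores.shape[0]} samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    return km.labels_ + 1, float(km.inertia_)


def find_clusters(
    panel: GenotypePanel,
    k_max: int = 10,
    n_pca: int | None = None,
    n_init: int = 10,
    seed: int = 0,
    scale: bool = False,
) -> ClusterSearchResult:
    """Search the number of clusters by k-means + BIC on PCA scores.

    For K = 1..k_max: BIC(K) = n*ln(WSS_K / n) + K*ln(n). The supported
    cluster count is the BIC argmin. Unlike the discriminant stage, the
    cluster search keeps all principal components by default (``n_pca``
    None): discarding the noise spectrum here concentrates residual
    variance into few axes and lets k-means keep paying for spurious extra
    clusters, flattening the BIC minimum.
    """
    matrix = impute_missing_mean(panel)
    if n_pca is not None and n_pca >= panel.n_samples:
        raise ValueError("n_pca must be below the number of samples")
    pca = fit_pca(matrix, scale=scale)
    X = pca.scores if n_pca is None else pca.scores[:, :n_pca]
    n = X.shape[0]
    k_grid = np.arange(1, k_max + 1)
    wss = np.empty(len(k_grid))
    labels_per_k = []
    for i, k in enumerate(k_grid):
        labels, w = kmeans_partition(X, int(k), n_init=n_init, seed=seed)
        wss[i] = w
        labels_per_k.append(labels)
    with np.errstate(divide="ignore"):
        bic = n * np.log(wss / n) + k_grid * np.log(n)
    best = int(np.argmin(bic))
    return ClusterSearchResult(
        k_grid=k_grid,
        wss=wss,
        bic=bic,
        best_k=int(k_grid[best]),
        assignments=labels_per_k[best],
        seed=seed,
    )


def _membership_from_coords(coords: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    logp = -0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def fit_dapc(
    matrix: np.ndarray,
    groups,
    n_pca: int,
    n_da: int | None = None,
    scale: bool = False,
) -> DAPCModel:
    """Fit DAPC: PCA to ``n_pca`` axes, then LDA on the retained scores.

    Discriminant axes solve the generalized eigenproblem B a = lambda W a
    (between- vs pooled within-group scatter of the PC scores), normalised
    to unit within-group variance so that Euclidean distances in
    discriminant space are Mahalanobis-like. ``variable_loadings`` compose
    the PCA loadings with the discriminant coefficients, giving per-locus
    contributions to each axis.
    """
    X = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    names = list(pd_unique_stable(groups))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if not np.any(groups == g):
            raise ValueError(f"group {g!r} has no samples")
    if n_pca >= X.shape[0]:
        raise ValueError("n_pca must be below the number of samples")
    max_da = min(len(names) - 1, n_pca)
    if n_da is None:
        n_da = max_da
    elif n_da > max_da:
        warnings.warn(f"n_da={n_da} clipped to {max_da}")
        n_da = max_da

    pca = fit_pca(X, scale=scale)
    S = pca.scores[:, :n_pca]
    n = S.shape[0]
    grand = S.mean(axis=0)
    W = np.zeros((n_pca, n_pca))
    B = np.zeros((n_pca, n_pca))
    centroids_pc = np.empty((len(names), n_pca))
    for gi, g in enumerate(names):
        Sg = S[groups == g]
        mu = Sg.mean(axis=0)
        centroids_pc[gi] = mu
        W += (Sg - mu).T @ (Sg - mu)
        B += len(Sg) * np.outer(mu - grand, mu - grand)
    W /= n - len(names) if n > len(names) else 1
    B /= len(names) - 1
    # ridge keeps W positive definite when n_pca approaches n
    W += np.eye(n_pca) * 1e-10 * max(np.trace(W), 1.0)
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1][:n_da]
    lam = np.maximum(evals[order], 0.0)
    A = evecs[:, order]
    # scipy.linalg.eigh already normalises a^T W a = 1
    coords = (S - grand) @ A
    centroids = (centroids_pc - grand) @ A
    memberships = _membership_from_coords(coords, centroids)
    variable_loadings = (pca.loadings[:, :n_pca] / pca.column_scales[:, None]) @ A
    return DAPCModel(
        group_names=names,
        n_pca=n_pca,
        n_da=n_da,
        pca=pca,
        da_eigenvalues=lam,
        da_coefficients=A,
        individual_coords=coords,
        group_centroids=centroids,
        memberships=memberships,
        variable_loadings=variable_loadings,
    )


def pd_unique_stable(values) -> list:
    seen: dict = {}
    for v in np.asarray(values).tolist():
        seen.setdefault(v, None)
    return list(seen)


def predict_membership(model: DAPCModel, new_matrix: np.ndarray) -> np.ndarray:
    """Membership posteriors for new samples on the training loci."""
    X = np.asarray(new_matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.pca.loadings.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} loci; the model was trained on "
            f"{model.pca.loadings.shape[0]}"
        )
    S = model.pca.transform(X, model.n_pca)
    grand = model.pca.scores[:, : model.n_pca].mean(axis=0)
    coords = (S - grand) @ model.da_coefficients
    return _membership_from_coords(coords, model.group_centroids)


def cross_validate(
    matrix: np.ndarray,
    groups,
    n_pca_grid,
    replicates: int = 30,
    holdout: float = 0.1,
    seed: int = 0,
    scale: bool = False,
) -> XvalResult:
    """Stratified holdout cross-validation of the retained-PC count.

    Per replicate a stratified ``holdout`` fraction (at least one sample
    per group) is set aside, a DAPC is fitted on the rest, and success is
    the fraction of held-out samples assigned to their true group.
    RMSE(grid point) = sqrt(mean((1 - success)^2)); ties in the argmin
    break toward fewer retained PCs.
    """
    X = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    names = pd_unique_stable(groups)
    rng = np.random.default_rng(seed)
    per_group_idx = {g: np.flatnonzero(groups == g) for g in names}
    for g, idx in per_group_idx.items():
        n_hold = max(1, int(round(holdout * len(idx))))
        if n_hold >= len(idx):
            raise ValueError(
                f"holdout {holdout} would empty group {g!r} ({len(idx)} members)"
            )
    grid = np.asarray(list(n_pca_grid), dtype=int)
    success = np.empty((len(grid), replicates))
    for rep in range(replicates):
        test_idx = []
        for g in names:
            idx = per_group_idx[g]
            n_hold = max(1, int(round(holdout * len(idx))))
            test_idx.append(rng.choice(idx, size=n_hold, replace=False))
        test_idx = np.concatenate(test_idx)
        train_mask = np.ones(len(groups), bool)
        train_mask[test_idx] = False
        for gi, n_pca in enumerate(grid):
            model = fit_dapc(
                X[train_mask], groups[train_mask], int(n_pca), scale=scale
            )
            prob = predict_membership(model, X[test_idx])
            pred = np.asarray(model.group_names, dtype=object)[prob.argmax(axis=1)]
            success[gi, rep] = np.mean(pred == groups[test_idx])
    rmse = np.sqrt(np.mean((1.0 - success) ** 2, axis=1))
    best = int(grid[np.argmin(rmse)])  # np.argmin returns the first minimum
    order = np.argsort(grid)
    return XvalResult(
        n_pca_grid=grid[order],
        success=success[order],
        rmse=rmse[order],
        best_n_pca=int(grid[order][np.argmin(rmse[order])]),
    )


def split_structural(abs_loadings: np.ndarray, method: str = "ward") -> np.ndarray:
    """Two-group cut of 1-D absolute loadings; True marks the high group."""
    x = np.asarray(abs_loadings, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all loadings equal; no structural/non-structural split")
    Z = linkage(x[:, None], method=method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    means = [x[labels == c].mean() for c in (1, 2)]
    return labels == (1 if means[0] > means[1] else 2)


def snpzip(
    model: DAPCModel,
    locus_ids,
    axis: int = 0,
    method: str = "ward",
) -> SnpzipResult:
    """Split loci into structural vs non-structural for a discriminant axis.

    The absolute per-locus loadings on the axis are clustered (1-D
    hierarchical clustering, Ward linkage by default) and cut into two
    groups; the group with the larger mean absolute loading is the
    structural set, listed by |loading| descending.
    """
    if axis >= model.n_da:
        raise ValueError(f"axis {axis} >= n_da={model.n_da}")
    x = np.abs(model.variable_loadings[:, axis])
    high = split_structural(x, method=method)
    struct_idx = np.flatnonzero(high)
    struct_idx = struct_idx[np.argsort(-x[struct_idx])]
    other_idx = np.flatnonzero(~high)
    locus_ids = list(locus_ids)
    return SnpzipResult(
        axis=axis,
        abs_loadings=x,
        structural=[locus_ids[i] for i in struct_idx],
        non_structural=[locus_ids[i] for i in other_idx],
    )
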