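"""Discriminant Analysis of Principal Components (DAPC).

The pipeline is: (1) centre (optionally scale) the allele-presence
matrix and reduce it by PCA; (2) detect clusters by k-means over the
retained PC scores, choosing K at the minimum of
``BIC(K) = N·ln(W_K/N) + K·ln(N)`` where W_K is the within-cluster sum
of squares (the find.clusters criterion); (3) fit Fisher discriminant
axes between the groups in PC space, maximizing between-group over
within-group variance; (4) validate the number of retained PCs by
repeated stratified holdout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedShuffleSplit

from .genotypes import BinaryMatrix, GenotypeTable, to_allele_presence

__all__ = [
    "PcaModel",
    "ClusterSearch",
    "DapcModel",
    "Dapc",
    "fit_pca",
    "find_clusters",
    "fit_dapc",
    "cross_validate",
    "subset_reanalysis",
]


def _as_imputed_array(X) -> np.ndarray:
    """Dense float matrix; BinaryMatrix masked cells mean-imputed per column."""
    if isinstance(X, BinaryMatrix):
        A = X.values.astype(float)
        obs = ~X.missing_mask
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_mean = np.where(n_obs > 0, (A * obs).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
        return np.where(obs, A, col_mean)
    return np.asarray(X, dtype=float)


@dataclass
class PcaModel:
    """Fitted PCA of a (possibly imputed) data matrix."""

    mean: np.ndarray
    scale: np.ndarray | None
    eigenvalues: np.ndarray       # descending, >= 0
    loadings: np.ndarray          # columns = axes
    scores: np.ndarray            # training-sample projections
    var_fraction: np.ndarray      # per-axis fraction of total variance

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.var_fraction)

    def transform(self, X, n_axes: int | None = None) -> np.ndarray:
        A = _as_imputed_array(X) - self.mean
        if self.scale is not None:
            A = A / self.scale
        L = self.loadings if n_axes is None else self.loadings[:, :n_axes]
        return A @ L


def fit_pca(X, center: bool = True, scale: bool = False) -> PcaModel:
    """PCA by SVD of the centred data matrix.

    ``X`` may be a BinaryMatrix (masked cells mean-imputed) or an array.
    Eigenvalues use the n−1 denominator.
    """
    A = _as_imputed_array(X)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mean = A.mean(axis=0) if center else np.zeros(A.shape[1])
    A = A - mean
    sd = None
    if scale:
        sd = A.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        A = A / sd
    if not A.any():
        raise ValueError("zero-variance matrix")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    return PcaModel(
        mean=mean,
        scale=sd,
        eigenvalues=eigenvalues,
        loadings=Vt.T,
        scores=U * s,
        var_fraction=eigenvalues / total,
    )


@dataclass
class ClusterSearch:
    """Result of the BIC-guided k-means cluster detection."""

    k_range: list[int]
    bic: np.ndarray
    wss: np.ndarray
    best_k: int
    labels: np.ndarray
    n_pcs: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_range, "WSS": self.wss, "BIC": self.bic})


def find_clusters(
    pca: PcaModel,
    k_max: int = 12,
    k_min: int = 1,
    n_pcs: int | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
) -> ClusterSearch:
    """Sequential k-means over retained PC scores with BIC model selection.

    For each K in ``k_min..k_max`` the best of ``n_restarts`` k-means
    solutions (by within-cluster sum of squares W_K) is kept and scored
    by ``BIC(K) = N·ln(W_K/N) + K·ln(N)``; the reported best K minimises
    BIC.  Deterministic for a given seed.
    """
    if n_pcs is None:
        n_pcs = pca.scores.shape[1]
    if n_pcs > pca.scores.shape[1]:
        raise ValueError("n_pcs exceeds available axes")
    S = pca.scores[:, :n_pcs]
    n = S.shape[0]
    if k_max > n:
        raise ValueError("K cannot exceed the number of samples")
    k_range = list(range(k_min, k_max + 1))
    wss = np.empty(len(k_range))
    bic = np.empty(len(k_range))
    labels_by_k = []
    for i, k in enumerate(k_range):
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=None if seed is None else seed + k,
        ).fit(S)
        wss[i] = km.inertia_
        labels_by_k.append(km.labels_)
        bic[i] = n * np.log(max(wss[i], 1e-300) / n) + k * np.log(n)
    best = int(np.argmin(bic))
    return ClusterSearch(
        k_range=k_range,
        bic=bic,
        wss=wss,
        best_k=k_range[best],
        labels=labels_by_k[best],
        n_pcs=n_pcs,
        seed=seed,
    )


def _fisher_lda(S: np.ndarray, labels: Sequence, n_da: int | None, reg: float):
    """Fisher discriminant axes of scores S for the given group labels.

    Solves the generalized eigenproblem Sb a = λ Sw a with a ridge term
    reg·tr(Sw)/p on Sw; axes are Sw-orthonormal.  Returns (eigenvalues,
    axes, groups, centroids_in_LD).
    """
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels.tolist()))
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n, p = S.shape
    grand = S.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    singular_groups = False
    for g in groups:
        G = S[labels == g]
        mu = G.mean(axis=0)
        if G.shape[0] < 2:
            singular_groups = True
        C = G - mu
        Sw += C.T @ C
        d = (mu - grand)[:, None]
        Sb += G.shape[0] * (d @ d.T)
    if singular_groups:
        warnings.warn("group(s) with a single member; ridge regularization applied")
    Sw += reg * max(np.trace(Sw), 1.0) / p * np.eye(p)
    evals, evecs = eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    max_da = min(k - 1, p)
    n_da = max_da if n_da is None else min(n_da, max_da)
    evals = np.clip(evals[order][:n_da], 0.0, None)
    axes = evecs[:, order][:, :n_da]
    centroids = np.array([S[labels == g].mean(axis=0) @ axes for g in groups])
    return evals, axes, groups, centroids


@dataclass
class DapcModel:
    """Fitted discriminant axes over retained PC scores."""

    n_pcs: int
    n_da: int
    eigenvalues: np.ndarray
    axes: np.ndarray              # (n_pcs, n_da), PC-space directions
    groups: list
    centroids: np.ndarray         # (k, n_da) group centroids in LD space
    ld_scores: np.ndarray         # training-sample LD coordinates

    def project(self, pc_scores: np.ndarray) -> np.ndarray:
        return np.asarray(pc_scores)[:, : self.n_pcs] @ self.axes

    def predict(self, pc_scores: np.ndarray):
        """Nearest-centroid assignment in LD space, with posterior weights."""
        ld = self.project(pc_scores)
        d2 = ((ld[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-0.5 * (d2 - d2.min(axis=1, keepdims=True)))
        posterior = w / w.sum(axis=1, keepdims=True)
        idx = d2.argmin(axis=1)
        return np.array([self.groups[i] for i in idx]), posterior


def fit_dapc(
    pca: PcaModel,
    labels: Sequence,
    n_pcs: int | None = None,
    n_da: int | None = None,
    reg: float = 1e-8,
) -> DapcModel:
    """Fisher discriminant analysis on the retained PC scores."""
    if n_pcs is None:
        n_pcs = pca.scores.shape[1]
    if n_pcs < 1:
        raise ValueError("need n_pcs >= 1")
    S = pca.scores[:, :n_pcs]
    evals, axes, groups, centroids = _fisher_lda(S, labels, n_da, reg)
    return DapcModel(
        n_pcs=n_pcs,
        n_da=axes.shape[1],
        eigenvalues=evals,
        axes=axes,
        groups=groups,
        centroids=centroids,
        ld_scores=S @ axes,
    )


class Dapc(BaseEstimator, ClassifierMixin):
    """End-to-end DAPC classifier (centre → PCA → Fisher axes → nearest centroid).

    Parameters
    ----------
    n_pcs : int or None
        PCs retained before the discriminant step (None = all).
    n_da : int or None
        Discriminant axes retained (None = min(K−1, n_pcs)).
    scale : bool
        Scale columns to unit variance before PCA (off for binary data).
    reg : float
        Ridge factor on the within-group scatter.
    """

    def __init__(self, n_pcs: int | None = None, n_da: int | None = None,
                 scale: bool = False, reg: float = 1e-8):
        self.n_pcs = n_pcs
        self.n_da = n_da
        self.scale = scale
        self.reg = reg

    def fit(self, X, y):
        self.pca_ = fit_pca(X, center=True, scale=self.scale)
        self.model_ = fit_dapc(self.pca_, y, n_pcs=self.n_pcs, n_da=self.n_da,
                               reg=self.reg)
        self.classes_ = np.asarray(self.model_.groups)
        return self

    def predict(self, X):
        scores = self.pca_.transform(X, n_axes=self.model_.n_pcs)
        labels, _ = self.model_.predict(scores)
        return labels

    def predict_proba(self, X):
        scores = self.pca_.transform(X, n_axes=self.model_.n_pcs)
        _, posterior = self.model_.predict(scores)
        return posterior


def cross_validate(
    X,
    labels: Sequence,
    pc_grid: Sequence[int],
    reps: int = 30,
    holdout: float = 0.1,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Holdout validation of the retained-PC count.

    Repeated stratified splits; for each candidate ``n_pcs`` a DAPC is
    fitted on the training part and scored by the fraction of held-out
    samples assigned to their true group.  Returns the per-``n_pcs``
    success table and the recommended count (max mean success, ties to
    fewer PCs).  Every group must have >= 2 members.
    """
    A = _as_imputed_array(X)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members for stratified holdout")
    # stratification needs >= 1 held-out sample per group
    test_size = max(int(round(holdout * len(y))), len(counts))
    splitter = StratifiedShuffleSplit(
        n_splits=reps, test_size=test_size, random_state=seed
    )
    success = {npc: [] for npc in pc_grid}
    for train, test in splitter.split(A, y):
        if len(np.unique(y[train])) < len(counts):
            raise ValueError("holdout left an empty training group")
        for npc in pc_grid:
            clf = Dapc(n_pcs=npc).fit(A[train], y[train])
            success[npc].append(float(np.mean(clf.predict(A[test]) == y[test])))
    table = pd.DataFrame(
        {
            "n_pcs": list(pc_grid),
            "mean_success": [np.mean(success[npc]) for npc in pc_grid],
            "sd_success": [np.std(success[npc], ddof=1) for npc in pc_grid],
        }
    )
    best = table.loc[
        table["mean_success"] == table["mean_success"].max(), "n_pcs"
    ].min()
    return table, int(best)


@dataclass
class SubsetDapc:
    """Full DAPC re-analysis of a sample subset."""

    sample_ids: list[str]
    binary: BinaryMatrix
    pca: PcaModel
    clusters: ClusterSearch
    dapc: DapcModel


def subset_reanalysis(
    table: GenotypeTable,
    sample_ids: Sequence[str] | None = None,
    k_max: int = 12,
    n_pcs: int | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
) -> SubsetDapc:
    """Re-run binarization → PCA → find_clusters → DAPC on a sample subset.

    Allele columns are re-derived from the subset, so private alleles of
    excluded samples disappear.  ``sample_ids=None`` analyses the full
    table.
    """
    sub = table if sample_ids is None else table.subset(sample_ids)
    if sub.n_samples < 4:
        raise ValueError("subset must contain at least 4 samples")
    bm = to_allele_presence(sub)
    pca = fit_pca(bm)
    n_keep = min(
        n_pcs if n_pcs is not None else pca.scores.shape[1],
        pca.scores.shape[1],
    )
    k_max_eff = min(k_max, sub.n_samples - 1)
    search = find_clusters(
        pca, k_max=k_max_eff, n_pcs=n_keep, n_restarts=n_restarts, seed=seed
    )
    if search.best_k >= 2:
        model = fit_dapc(pca, search.labels, n_pcs=n_keep)
    else:
        model = None
    return SubsetDapc(
        sample_ids=list(sub.sample_ids),
        binary=bm,
        pca=pca,
        clusters=search,
        dapc=model,
    )
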