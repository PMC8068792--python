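"""One-way distance-based AMOVA on binary allele-presence data.

The analysis of molecular variance partitions the total squared-distance
variation of a panel into among-group and within-group components.  For
k groups of sizes n_g (N total) and a matrix of pairwise squared
distances d²:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j in g} d²_ij
    SS_among  = SS_total − SS_within
    MS        = SS / df,  df_among = k − 1,  df_within = N − k
    n0        = (N − Σ n_g²/N) / (k − 1)
    Va        = max(0, (MS_among − MS_within) / n0),   Vw = MS_within
    PhiPT     = Va / (Va + Vw)

PhiPT is the binary/haploid-data analogue of Fst; gene flow is estimated
from it by the haploid transform Nm = (1 − Φ)/(2Φ).  Significance is
assessed by permuting sample labels with group sizes fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .genotypes import BinaryMatrix

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "squared_distances",
    "variance_components",
    "amova_oneway",
    "phipt",
    "nm_from_phipt",
    "permutation_test",
    "pairwise_phipt",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix of squared pairwise distances."""

    sample_ids: list[str]
    d2: np.ndarray

    def __post_init__(self) -> None:
        self.d2 = np.asarray(self.d2, dtype=float)
        n = len(self.sample_ids)
        if self.d2.shape != (n, n):
            raise ValueError("d2 must be square and match sample_ids")
        if not np.allclose(self.d2, self.d2.T):
            raise ValueError("d2 must be symmetric")
        if (np.diag(self.d2) != 0).any() or (self.d2 < 0).any():
            raise ValueError("d2 must be nonnegative with zero diagonal")


@dataclass
class AmovaResult:
    """Variance partition of a one-way AMOVA (the Table-3-shaped result)."""

    group_sizes: dict[str, int]
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    n0: float
    va: float
    vw: float
    phi_pt: float
    nm: float
    p_value: float | None = None
    n_permutations: int = 0

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def pct_among(self) -> float:
        tot = self.va + self.vw
        return 100.0 * self.va / tot if tot > 0 else 0.0

    @property
    def pct_within(self) -> float:
        tot = self.va + self.vw
        return 100.0 * self.vw / tot if tot > 0 else 100.0

    def significance_stars(self) -> str:
        if self.p_value is None:
            return ""
        for cut, stars in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < cut:
                return stars
        return "ns"

    def to_frame(self) -> pd.DataFrame:
        """Report table rounded per convention (SS/MS 3 dp, Φ/Nm 3 dp, whole %)."""
        return pd.DataFrame(
            [
                {
                    "SV": "Among groups",
                    "Df": self.df_among,
                    "SS": round(self.ss_among, 3),
                    "MS": round(self.ms_among, 3),
                    "Est. Var.": round(self.va, 3),
                    "%": f"{self.pct_among:.0f}%",
                    "PhiPT": f"{self.phi_pt:.3f} {self.significance_stars()}".strip(),
                    "Nm": round(self.nm, 3) if np.isfinite(self.nm) else np.inf,
                },
                {
                    "SV": "Within groups",
                    "Df": self.df_within,
                    "SS": round(self.ss_within, 3),
                    "MS": round(self.ms_within, 3),
                    "Est. Var.": round(self.vw, 3),
                    "%": f"{self.pct_within:.0f}%",
                    "PhiPT": "",
                    "Nm": "",
                },
                {
                    "SV": "Total",
                    "Df": self.df_among + self.df_within,
                    "SS": round(self.ss_total, 3),
                    "MS": "",
                    "Est. Var.": round(self.va + self.vw, 3),
                    "%": "100%",
                    "PhiPT": "",
                    "Nm": "",
                },
            ]
        )


def squared_distances(bm: BinaryMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distances between allele-presence rows.

    Masked cells are imputed with the per-column mean of unmasked cells
    (the GenAlEx "interpolate" behaviour); with no missing data this is
    the count of allele-presence mismatches.  Columns that are masked for
    every sample are dropped with a warning.
    """
    if bm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = bm.values.astype(float)
    obs = ~bm.missing_mask
    n_obs = obs.sum(axis=0)
    dead = n_obs == 0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} column(s) masked in every sample"
        )
        X, obs, n_obs = X[:, ~dead], obs[:, ~dead], n_obs[~dead]
    col_mean = (X * obs).sum(axis=0) / n_obs
    X = np.where(obs, X, col_mean)
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    return DistanceMatrix(list(bm.sample_ids), d2)


def variance_components(
    ms_among: float, ms_within: float, group_sizes: Sequence[int]
) -> dict[str, float]:
    """Variance components from mean squares and group sizes.

    Computes the weighted average sample size
    ``n0 = (N − Σ n_g²/N)/(k − 1)``, then ``Va = max(0, (MS_among −
    MS_within)/n0)``, ``Vw = MS_within``, PhiPT and Nm.  This is the
    desk-computable tail of the AMOVA chain, usable directly from a
    published table's MS values.
    """
    sizes = np.asarray(list(group_sizes), dtype=float)
    k = sizes.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    n_total = sizes.sum()
    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / (k - 1)
    va = max(0.0, (ms_among - ms_within) / n0)
    vw = ms_within
    # degenerate data (all samples identical): PhiPT = 0 by convention
    phi = phipt(va, vw) if va + vw > 0 else 0.0
    return {
        "n0": n0,
        "va": va,
        "vw": vw,
        "phi_pt": phi,
        "nm": nm_from_phipt(phi),
    }


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # Σ_g (1/n_g) Σ_{i<j in g} d²;  Gᵀ D G diagonal gives 2·Σ_{i<j in g} d²
    per_group = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    return float(np.sum(per_group / sizes))


def amova_oneway(
    D: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """One-way AMOVA of the squared-distance matrix by group labels.

    With ``n_perm > 0`` a label-permutation p-value for PhiPT is attached
    (see :func:`permutation_test`).
    """
    labels = list(labels)
    n = len(labels)
    if n != len(D.sample_ids):
        raise ValueError("labels must match the distance matrix samples")
    group_names = list(dict.fromkeys(labels))
    k = len(group_names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    gindex = np.array([group_names.index(l) for l in labels])
    sizes = np.bincount(gindex, minlength=k).astype(float)
    if (sizes == 0).any():
        raise ValueError("every group must be nonempty")

    d2 = D.d2
    ss_total = float(d2.sum()) / (2.0 * n)
    onehot = np.eye(k)[gindex]
    ss_within = _ss_within(d2, onehot, sizes)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    comp = variance_components(ms_among, ms_within, sizes.astype(int))

    result = AmovaResult(
        group_sizes={g: int(sizes[i]) for i, g in enumerate(group_names)},
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=comp["n0"],
        va=comp["va"],
        vw=comp["vw"],
        phi_pt=comp["phi_pt"],
        nm=comp["nm"],
    )
    if n_perm > 0:
        result.p_value = permutation_test(D, labels, n_perm=n_perm, seed=seed)
        result.n_permutations = n_perm
    return result


def phipt(va: float, vw: float) -> float:
    """PhiPT = Va/(Va + Vw), the among-group variance fraction."""
    if va < 0:
        raise ValueError("Va must be nonnegative")
    tot = va + vw
    if tot <= 0:
        raise ValueError("Va + Vw must be positive")
    return va / tot


def nm_from_phipt(phi: float) -> float:
    """Gene flow Nm = (1 − Φ)/(2Φ), the haploid/binary-data transform.

    Returns ``inf`` for Φ <= 0 (no differentiation implies unbounded
    apparent gene flow).
    """
    if phi > 1:
        raise ValueError("PhiPT cannot exceed 1")
    if phi <= 0:
        return float("inf")
    return (1.0 - phi) / (2.0 * phi)


def _phi_stat(d2, gindex, k, sizes, n):
    onehot = np.eye(k)[gindex]
    ss_total = float(d2.sum()) / (2.0 * n)
    ss_within = _ss_within(d2, onehot, sizes)
    ss_among = ss_total - ss_within
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (n - k)
    n0 = (n - float(np.sum(sizes**2)) / n) / (k - 1)
    va = max(0.0, (ms_among - ms_within) / n0)
    tot = va + ms_within
    return va / tot if tot > 0 else 0.0


def permutation_test(
    D: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the observed PhiPT.

    Sample labels are shuffled uniformly (group sizes fixed), PhiPT is
    recomputed each time, and ``p = (#{Φ_perm >= Φ_obs} + 1)/(n_perm + 1)``.
    Deterministic for a given seed.  A degenerate all-zero distance
    matrix yields p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = list(labels)
    n = len(labels)
    group_names = list(dict.fromkeys(labels))
    k = len(group_names)
    gindex = np.array([group_names.index(l) for l in labels])
    sizes = np.bincount(gindex, minlength=k).astype(float)
    d2 = D.d2
    if not d2.any():
        return 1.0
    observed = _phi_stat(d2, gindex, k, sizes, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(gindex)
        if _phi_stat(d2, perm, k, sizes, n) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pairwise_phipt(
    bm: BinaryMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise PhiPT (above diagonal) / Nm (below diagonal) matrices.

    Each unordered group pair is analysed by a one-way AMOVA restricted
    to that pair's samples (distances recomputed within the subset).
    Returns ``(matrix, p_values)`` where ``matrix`` holds PhiPT above and
    Nm below the diagonal, and ``p_values`` the permutation p-values
    (upper triangle; NaN elsewhere).  Groups smaller than 2 samples are
    skipped with a warning.
    """
    labels = list(labels)
    groups = list(dict.fromkeys(labels))
    usable = []
    for g in groups:
        if labels.count(g) < 2:
            warnings.warn(f"group {g!r} has < 2 samples; pairs skipped")
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups of size >= 2")

    mat = pd.DataFrame(np.nan, index=usable, columns=usable)
    pvals = pd.DataFrame(np.nan, index=usable, columns=usable)
    rng = np.random.default_rng(seed)
    idx = np.arange(bm.n_samples)
    for a_i, ga in enumerate(usable):
        for gb in usable[a_i + 1 :]:
            rows = idx[[l in (ga, gb) for l in labels]]
            sub = BinaryMatrix(
                [bm.sample_ids[i] for i in rows],
                list(bm.column_index),
                bm.values[rows],
                bm.missing_mask[rows],
            )
            sub_labels = [labels[i] for i in rows]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # fully masked columns in subset
                Dsub = squared_distances(sub)
            res = amova_oneway(
                Dsub,
                sub_labels,
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)) if n_perm else None,
            )
            mat.loc[ga, gb] = res.phi_pt
            mat.loc[gb, ga] = res.nm
            pvals.loc[ga, gb] = res.p_value
    return mat, pvals
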