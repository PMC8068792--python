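"""Per-locus and per-group SSR diversity statistics.

Conventions
-----------
* ``Na`` — number of distinct alleles observed at a locus.
* ``Ng`` — number of distinct genotype classes at a locus, where a class
  is the unordered multiset of allele calls (MISSING excluded).
* ``H`` — Shannon–Wiener index of the genotype-class proportions, in nats.
  Natural log is used so that the evenness formula ``E5 = (1/λ − 1)/(e^H − 1)``
  (with Stoddart–Taylor's ``1/λ``) is internally consistent; a different
  log base can be requested.
* ``GD`` — Nei's gene diversity ``h = n/(n−1) · (1 − Σ p_i²)`` over allele
  frequencies, averaged over loci.  ``n`` defaults to the number of
  observed gene copies at the locus (the standard small-sample
  correction); counting distinct alleles instead is available via
  ``n_convention="distinct"``.
* ``E5`` — evenness of genotype-class abundances, 1 for a perfectly even
  distribution (and by convention for a single class).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import AlleleCounts, GenotypeTable, allele_counts

__all__ = [
    "shannon",
    "nei_gd_locus",
    "gd_mean",
    "evenness_e5",
    "locus_table",
    "group_table",
]


def shannon(proportions: Sequence[float], base: float | None = None) -> float:
    """Shannon–Wiener index −Σ p ln p of a probability vector.

    Zero-probability classes contribute 0.  ``base`` converts to another
    logarithm base (e.g. 2); default is natural log (nats).
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def nei_gd_locus(
    counts: AlleleCounts, n_convention: str = "copies"
) -> float:
    """Nei's corrected gene diversity h = n/(n−1)·(1 − Σ p_i²) at one locus.

    ``n`` is the number of observed gene copies (``n_convention="copies"``,
    default) or the number of distinct alleles (``"distinct"``).  Clamped
    to [0, 1].
    """
    if n_convention == "copies":
        n = counts.n_obs
    elif n_convention == "distinct":
        n = counts.n_alleles
    else:
        raise ValueError(f"unknown n_convention {n_convention!r}")
    if n < 2:
        if counts.n_alleles == 1:
            return 0.0
        raise ValueError("need n >= 2 for the n/(n-1) correction")
    p = counts.frequencies()
    h = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    return float(np.clip(h, 0.0, 1.0))


def gd_mean(per_locus: Iterable[float]) -> float:
    """Locus-averaged gene diversity GD = Σ h_l / m."""
    h = list(per_locus)
    if not h:
        raise ValueError("empty per-locus diversity list")
    return float(np.mean(h))


def evenness_e5(genotype_counts: Mapping | Sequence[float]) -> float:
    """Evenness E5 = (1/λ − 1)/(e^H − 1) over genotype-class abundances.

    ``λ = Σ p_i²`` (so 1/λ is Stoddart–Taylor's index) and H is the
    Shannon index in nats.  Equals 1 for uniform abundances; defined as 1
    for a single class.
    """
    if isinstance(genotype_counts, Mapping):
        c = np.array(list(genotype_counts.values()), dtype=float)
    else:
        c = np.asarray(genotype_counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all genotype counts are zero")
    if c.size == 1:
        return 1.0
    p = c / c.sum()
    lam = float(np.sum(p**2))
    h = shannon(p)
    return float((1.0 / lam - 1.0) / (math.expm1(h)))


def _genotype_class_counts(table: GenotypeTable, j: int, rows) -> dict:
    counts: dict[tuple, int] = {}
    for i in rows:
        g = table.genotype(i, j)
        if g:
            counts[g] = counts.get(g, 0) + 1
    return counts


def _locus_stats(table: GenotypeTable, locus: str, rows, group=None):
    j = table.loci.index(locus)
    gcounts = _genotype_class_counts(table, j, rows)
    if not gcounts:
        return None
    ac = allele_counts(
        table, locus, group=[table.sample_ids[i] for i in rows] if group else None
    )
    ng = np.array(list(gcounts.values()), dtype=float)
    p = ng / ng.sum()
    return {
        "Na": ac.n_alleles,
        "Ng": len(gcounts),
        "H": shannon(p),
        "GD": nei_gd_locus(ac),
        "Evenness": evenness_e5(gcounts),
    }


def locus_table(table: GenotypeTable, mean_row: bool = True) -> pd.DataFrame:
    """Per-locus diversity summary (Na, Ng, H, GD, Evenness) + mean row.

    H is computed over genotype-class proportions and GD over allele
    frequencies, each within non-missing genotypes at the locus.
    """
    rows = range(table.n_samples)
    records = []
    for locus in table.loci:
        stats = _locus_stats(table, locus, rows)
        if stats is None:
            stats = dict.fromkeys(["Na", "Ng", "H", "GD", "Evenness"], np.nan)
        records.append({"Locus": locus, **stats})
    df = pd.DataFrame.from_records(records)
    if mean_row:
        means = df[["Na", "Ng", "H", "GD", "Evenness"]].mean()
        df = pd.concat(
            [df, pd.DataFrame([{"Locus": "mean", **means.to_dict()}])],
            ignore_index=True,
        )
    return df


def group_table(
    table: GenotypeTable, grouping: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-group diversity summary over a common locus set.

    ``grouping`` is a label per sample (defaults to the table's population
    labels).  Na and Ng are reported as mean ± sd (ddof=1) across loci;
    H, GD and Evenness as locus means.  A group with fewer than 2 samples
    yields a flagged row with undefined (NaN) GD.
    """
    labels = list(grouping) if grouping is not None else list(table.pop_labels)
    if len(labels) != table.n_samples:
        raise ValueError("grouping must label every sample")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)

    records = []
    for g, rows in groups.items():
        if len(rows) < 2:
            records.append(
                {"Group": g, "N": len(rows), "Na_mean": np.nan, "Na_sd": np.nan,
                 "Ng_mean": np.nan, "Ng_sd": np.nan, "H": np.nan, "GD": np.nan,
                 "Evenness": np.nan}
            )
            continue
        per_locus = []
        for locus in table.loci:
            stats = _locus_stats(table, locus, rows, group=True)
            if stats is not None:
                per_locus.append(stats)
        sub = pd.DataFrame(per_locus)
        records.append(
            {
                "Group": g,
                "N": len(rows),
                "Na_mean": sub["Na"].mean(),
                "Na_sd": sub["Na"].std(ddof=1),
                "Ng_mean": sub["Ng"].mean(),
                "Ng_sd": sub["Ng"].std(ddof=1),
                "H": sub["H"].mean(),
                "GD": sub["GD"].mean(),
                "Evenness": sub["Evenness"].mean(),
            }
        )
    return pd.DataFrame.from_records(records)
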