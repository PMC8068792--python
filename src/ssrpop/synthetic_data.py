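"""Synthetic SSR germplasm panels with known population structure.

The generator emulates a genebank collection genotyped at two dozen SSR
loci: a few hundred accessions from several origins, each origin nested
in one of two latent subpopulations, with weak among-origin
differentiation (a few percent of the molecular variance) and a small
fraction of admixed individuals.

Divergence follows the Balding–Nichols F-model: per locus an ancestral
frequency vector p is drawn from a symmetric Dirichlet (broken stick),
each subpopulation's vector from Dirichlet(p·(1−F)/F), and each origin's
vector from its subpopulation's with a smaller within-subpopulation F.
Genotypes are ``ploidy`` independent allele draws; admixed samples draw
each allele copy's subpopulation of origin from their own proportions
vector q.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genotypes import BinaryMatrix, GenotypeTable, write_genalex

__all__ = [
    "OriginSpec",
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_binary_fmodel",
    "emit_fixture_suite",
    "DEFAULT_ORIGINS",
    "SMALL_ORIGINS",
]


@dataclass(frozen=True)
class OriginSpec:
    """One origin group: label, sample count, parent subpopulation, F."""

    label: str
    size: int
    subpop: int
    f: float


# Seven origins emulating a genebank panel: sizes follow the reference
# collection's origin breakdown; one origin (PER) carries the second,
# wild-relative-like latent subpopulation.  Within-subpopulation F values
# are small so that only ~3% of molecular variance lies among origins.
DEFAULT_ORIGINS = (
    OriginSpec("BGR", 29, 0, 0.005),
    OriginSpec("CHN", 42, 0, 0.005),
    OriginSpec("JPN", 48, 0, 0.005),
    OriginSpec("KOR", 122, 0, 0.008),
    OriginSpec("NLD", 60, 0, 0.005),
    OriginSpec("PER", 41, 1, 0.008),
    OriginSpec("USA", 140, 0, 0.005),
)

# down-scaled layout for fast fixtures (N=60)
SMALL_ORIGINS = (
    OriginSpec("BGR", 4, 0, 0.005),
    OriginSpec("CHN", 5, 0, 0.005),
    OriginSpec("JPN", 6, 0, 0.005),
    OriginSpec("KOR", 15, 0, 0.008),
    OriginSpec("NLD", 8, 0, 0.005),
    OriginSpec("PER", 5, 1, 0.008),
    OriginSpec("USA", 17, 0, 0.005),
)


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the reference panel."""

    n_loci: int = 24
    alleles_min: int = 4
    alleles_max: int = 20
    ploidy: int = 4
    k_true: int = 2
    origins: tuple[OriginSpec, ...] = DEFAULT_ORIGINS
    subpop_f: float = 0.025
    admix_fraction: float = 0.05
    admix_concentration: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(o.size for o in self.origins)

    def validate(self) -> None:
        if not (2 <= self.alleles_min <= self.alleles_max <= 60):
            raise ValueError("allele range must lie within [2, 60]")
        if not all(0 < o.f < 1 for o in self.origins):
            raise ValueError("origin F values must lie in (0, 1)")
        if not 0 < self.subpop_f < 1:
            raise ValueError("subpop_f must lie in (0, 1)")
        if not all(0 <= o.subpop < self.k_true for o in self.origins):
            raise ValueError("origin subpopulation indices out of range")
        if len({o.label for o in self.origins}) != len(self.origins):
            raise ValueError("origin labels must be unique")


@dataclass
class SimTruth:
    """Generator ground truth for recovery tests."""

    allele_inventory: dict[str, list[int]]
    ancestral_freqs: dict[str, list[float]]
    subpop_freqs: dict[str, dict[str, list[float]]]    # "0".. -> locus -> p
    origin_freqs: dict[str, dict[str, list[float]]]    # label -> locus -> p
    sample_subpop: list[int]
    sample_q: list[list[float]]
    sample_admixed: list[bool]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _bn_dirichlet(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw: Dirichlet with concentration p·(1−F)/F."""
    draw = rng.dirichlet(p * (1.0 - f) / f)
    # guard against numerically zero categories
    draw = np.maximum(draw, 1e-9)
    return draw / draw.sum()


def simulate_panel(config: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Simulate an SSR panel with nested population structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, ploidy, K = (
        config.n_samples,
        config.n_loci,
        config.ploidy,
        config.k_true,
    )

    loci = [f"SSR{j + 1:02d}" for j in range(m)]
    inventory: dict[str, list[int]] = {}
    p_anc: dict[str, np.ndarray] = {}
    p_sub: list[dict[str, np.ndarray]] = [dict() for _ in range(K)]
    p_origin: dict[str, dict[str, np.ndarray]] = {o.label: {} for o in config.origins}
    for j, locus in enumerate(loci):
        n_alleles = int(
            rng.integers(config.alleles_min, config.alleles_max + 1)
        )
        # di-nucleotide-repeat-like fragment ladder, offset per locus
        inventory[locus] = [100 + 2 * j + 2 * a for a in range(n_alleles)]
        p_anc[locus] = rng.dirichlet(np.ones(n_alleles))
        for s in range(K):
            p_sub[s][locus] = _bn_dirichlet(rng, p_anc[locus], config.subpop_f)
        for o in config.origins:
            p_origin[o.label][locus] = _bn_dirichlet(
                rng, p_sub[o.subpop][locus], o.f
            )

    sample_ids, pop_labels = [], []
    sample_subpop, sample_q, sample_admixed = [], [], []
    calls = np.zeros((n, m, ploidy), dtype=np.int64)
    i = 0
    for o in config.origins:
        for r in range(o.size):
            sample_ids.append(f"{o.label}_{r + 1:03d}")
            pop_labels.append(o.label)
            sample_subpop.append(o.subpop)
            admixed = rng.random() < config.admix_fraction
            if admixed and K > 1:
                q = rng.dirichlet(np.full(K, config.admix_concentration))
            else:
                q = np.zeros(K)
                q[o.subpop] = 1.0
            sample_admixed.append(bool(admixed and K > 1))
            sample_q.append(q.tolist())
            for j, locus in enumerate(loci):
                if rng.random() < config.missing_rate:
                    continue  # MISSING genotype (all-zero slots)
                alleles = np.asarray(inventory[locus])
                for c in range(ploidy):
                    z = int(rng.choice(K, p=q))
                    p = (
                        p_origin[o.label][locus]
                        if z == o.subpop
                        else p_sub[z][locus]
                    )
                    calls[i, j, c] = int(rng.choice(alleles, p=p))
            i += 1

    table = GenotypeTable(sample_ids, pop_labels, loci, ploidy, calls)
    truth = SimTruth(
        allele_inventory=inventory,
        ancestral_freqs={l: p_anc[l].tolist() for l in loci},
        subpop_freqs={
            str(s): {l: p_sub[s][l].tolist() for l in loci} for s in range(K)
        },
        origin_freqs={
            o.label: {l: p_origin[o.label][l].tolist() for l in loci}
            for o in config.origins
        },
        sample_subpop=sample_subpop,
        sample_q=sample_q,
        sample_admixed=sample_admixed,
    )
    return table, truth


def simulate_binary_fmodel(
    n_per_pop: int | list[int],
    n_cols: int,
    f: float,
    k: int = 2,
    seed: int | None = None,
) -> tuple[BinaryMatrix, np.ndarray]:
    """Binary F-model panel: K pure populations, Bernoulli presence columns.

    Per column an ancestral presence frequency p ~ Uniform(0.1, 0.9) is
    drawn; each population's frequency comes from
    Beta(p·(1−F)/F, (1−p)·(1−F)/F); each sample's cells are independent
    Bernoulli draws from its population's frequencies.  Returns the
    matrix and the true population index per sample.
    """
    if isinstance(n_per_pop, int):
        sizes = [n_per_pop] * k
    else:
        sizes = list(n_per_pop)
        k = len(sizes)
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_cols)
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    pops = np.repeat(np.arange(k), sizes)
    freqs = rng.beta(a, b, size=(k, n_cols))
    X = (rng.random((len(pops), n_cols)) < freqs[pops]).astype(np.int8)
    bm = BinaryMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(len(pops))],
        column_index=[("BIN", c + 1) for c in range(n_cols)],
        values=X,
        missing_mask=np.zeros_like(X, dtype=bool),
    )
    return bm, pops


def emit_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a small (N=60) and a full-scale (N=482) fixture set.

    Each set holds the GenAlEx panel, the generator truth JSON, and
    golden per-locus / per-origin diversity tables regenerated from the
    pipeline itself.  Regeneration with the same seed is byte-identical.
    """
    from . import diversity

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tag, origins, n_loci in (
        ("small", SMALL_ORIGINS, 10),
        ("full", DEFAULT_ORIGINS, 24),
    ):
        cfg = SimConfig(origins=origins, n_loci=n_loci, seed=seed)
        table, truth = simulate_panel(cfg)
        panel = out / f"panel_{tag}.csv"
        write_genalex(table, panel, title=f"synthetic {tag} panel")
        truth_path = out / f"truth_{tag}.json"
        truth.to_json(truth_path)
        locus = out / f"locus_table_{tag}.csv"
        diversity.locus_table(table).round(6).to_csv(locus, index=False)
        group = out / f"group_table_{tag}.csv"
        diversity.group_table(table).round(6).to_csv(group, index=False)
        paths.update(
            {
                f"panel_{tag}": panel,
                f"truth_{tag}": truth_path,
                f"locus_table_{tag}": locus,
                f"group_table_{tag}": group,
            }
        )
    return paths
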