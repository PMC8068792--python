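"""Data model and I/O for codominant SSR genotype panels.

SSR (microsatellite) loci in polyploid germplasm are scored as fragment
sizes in base pairs.  In an autotetraploid such as cultivated potato the
number of distinct fragments per locus varies from 1 to ``ploidy`` and the
dosage of each allele is generally unknowable from peak data, so the
canonical downstream representation is *allele presence*: one 0/1 column
per observed (locus, allele) pair.  That encoding is what the distance
AMOVA, the admixture sampler and DAPC all consume.

The on-disk dialect is a GenAlEx-style codominant CSV (see
:func:`read_genalex`); a STRUCTURE-format export is also provided for
interoperability.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeTable",
    "BinaryMatrix",
    "AlleleCounts",
    "read_genalex",
    "write_genalex",
    "to_allele_presence",
    "allele_counts",
    "export_structure",
    "estimate_null_allele_freq",
]

#: sentinel used for empty allele slots on disk and in the calls array
MISSING = 0


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the expected dialect."""


@dataclass
class GenotypeTable:
    """Samples x loci matrix of multi-allelic SSR calls.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers.
    pop_labels : list of str
        Population (grouping) label per sample, e.g. origin country code.
    loci : list of str
        Locus names, unique.
    ploidy : int
        Number of allele slots per locus (4 for autotetraploid potato).
    calls : ndarray of shape (n_samples, n_loci, ploidy), int
        Allele calls as positive integers (fragment sizes in bp); 0 marks
        an empty slot.  A genotype is MISSING at a locus iff all its slots
        are 0.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    loci: list[str]
    ploidy: int
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.sample_ids), len(self.loci)
        if len(set(self.sample_ids)) != n:
            dup = [s for s, c in Counter(self.sample_ids).items() if c > 1]
            raise ValueError(f"duplicate sample ids: {dup}")
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length must match sample_ids")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus names")
        if m == 0:
            raise ValueError("table must contain at least one locus")
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        if self.calls.shape != (n, m, self.ploidy):
            raise ValueError(
                f"calls shape {self.calls.shape} != {(n, m, self.ploidy)}"
            )
        if (self.calls < 0).any():
            raise ValueError("allele calls must be nonnegative integers")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci); True where the genotype is MISSING."""
        return (self.calls == MISSING).all(axis=2)

    def genotype(self, i: int, j: int) -> tuple[int, ...]:
        """Sorted multiset of allele calls of sample *i* at locus *j*.

        Empty tuple for a MISSING genotype.
        """
        a = self.calls[i, j]
        return tuple(sorted(int(x) for x in a[a != MISSING]))

    def pop_sizes(self) -> dict[str, int]:
        """Population sizes in order of first appearance."""
        sizes: dict[str, int] = {}
        for p in self.pop_labels:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        """Restriction to the given samples (order preserved as given)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return GenotypeTable(
            sample_ids=list(sample_ids),
            pop_labels=[self.pop_labels[i] for i in rows],
            loci=list(self.loci),
            ploidy=self.ploidy,
            calls=self.calls[rows].copy(),
        )


@dataclass
class BinaryMatrix:
    """Samples x (locus, allele) allele-presence encoding.

    ``values[i, c] == 1`` iff sample *i* carries at least one copy of the
    allele of column *c*.  ``missing_mask`` is True where the sample's
    genotype at the column's locus is MISSING; masked cells carry no
    information and must be excluded or imputed downstream.
    """

    sample_ids: list[str]
    column_index: list[tuple[str, int]]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.sample_ids), len(self.column_index))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValueError("values/missing_mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_index)


@dataclass
class AlleleCounts:
    """Allele counts at one locus over a sample group.

    ``n_obs`` is the total number of observed allele copies (gene copies),
    i.e. the sum of counts.  Frequencies ``p_i = counts[i] / n_obs``.
    """

    locus: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    def frequencies(self) -> np.ndarray:
        n = self.n_obs
        return np.array([c / n for c in self.counts.values()], dtype=float)


# ---------------------------------------------------------------------------
# GenAlEx-style codominant CSV dialect
# ---------------------------------------------------------------------------
#
# row 1: n_loci, n_samples, n_pops, size_pop1, ..., size_popP
# row 2: title, <blank>, pop_name1, ..., pop_nameP
# row 3: Sample, Pop, Locus1, <ploidy-1 blanks>, Locus2, <ploidy-1 blanks>, ...
# data : sample_id, pop, a11, a12, ..., a1ploidy, a21, ...   (0 = empty slot)


def read_genalex(path, title_out: list | None = None) -> GenotypeTable:
    """Read a GenAlEx-style codominant CSV into a :class:`GenotypeTable`.

    The ploidy is inferred from the header row (number of allele columns
    per locus).  Allele cells equal to ``0`` or blank are empty slots; a
    genotype whose slots are all empty is MISSING.

    Raises
    ------
    GenotypeFormatError
        If declared counts disagree with the actual rows/columns, or the
        file is otherwise malformed.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise GenotypeFormatError("file too short: need 3 header rows + data")

    head = rows[0]
    try:
        n_loci, n_samples, n_pops = (int(x) for x in head[:3])
        declared_sizes = [int(x) for x in head[3 : 3 + n_pops]]
    except (ValueError, IndexError):
        raise GenotypeFormatError(f"malformed first row: {head!r}") from None
    if len(declared_sizes) != n_pops:
        raise GenotypeFormatError("first row lists fewer pop sizes than n_pops")

    title_row = rows[1]
    if title_out is not None:
        title_out.append(title_row[0] if title_row else "")

    header = rows[2]
    if len(header) < 2 or n_loci == 0:
        raise GenotypeFormatError("malformed column header row")
    n_allele_cols = len(header) - 2
    if n_allele_cols % n_loci != 0:
        raise GenotypeFormatError(
            f"line 3: {n_allele_cols} allele columns not divisible by "
            f"{n_loci} declared loci"
        )
    ploidy = n_allele_cols // n_loci
    loci = [header[2 + j * ploidy] for j in range(n_loci)]
    if any(not name for name in loci):
        raise GenotypeFormatError("line 3: blank cell where a locus name expected")

    data = [r for r in rows[3:] if any(cell.strip() for cell in r)]
    if len(data) != n_samples:
        raise GenotypeFormatError(
            f"line 1 declares {n_samples} samples but file has {len(data)} "
            "data rows"
        )

    sample_ids, pop_labels = [], []
    calls = np.zeros((n_samples, n_loci, ploidy), dtype=np.int64)
    for i, row in enumerate(data):
        if len(row) < 2 + n_allele_cols:
            raise GenotypeFormatError(
                f"line {i + 4}: expected {2 + n_allele_cols} fields, "
                f"got {len(row)}"
            )
        sample_ids.append(row[0])
        pop_labels.append(row[1])
        for j in range(n_loci):
            for k in range(ploidy):
                cell = row[2 + j * ploidy + k].strip()
                if cell == "":
                    continue
                try:
                    calls[i, j, k] = int(cell)
                except ValueError:
                    raise GenotypeFormatError(
                        f"line {i + 4}: non-integer allele cell {cell!r}"
                    ) from None

    table = GenotypeTable(sample_ids, pop_labels, loci, ploidy, calls)
    sizes = table.pop_sizes()
    if list(sizes.values()) != declared_sizes:
        raise GenotypeFormatError(
            f"declared pop sizes {declared_sizes} != actual "
            f"{list(sizes.values())}"
        )
    return table


def write_genalex(table: GenotypeTable, path, title: str = "ssrpop panel") -> None:
    """Write *table* in the canonical GenAlEx-style dialect.

    ``read_genalex`` inverts this exactly (byte-identical round trip on
    canonical files).  MISSING genotypes serialise as all-zero slots.
    """
    sizes = table.pop_sizes()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [table.n_loci, table.n_samples, len(sizes), *sizes.values()]
        )
        w.writerow([title, "", *sizes.keys()])
        header = ["Sample", "Pop"]
        for locus in table.loci:
            header.append(locus)
            header.extend([""] * (table.ploidy - 1))
        w.writerow(header)
        for i, sid in enumerate(table.sample_ids):
            row: list = [sid, table.pop_labels[i]]
            row.extend(int(x) for x in table.calls[i].ravel())
            w.writerow(row)


def to_allele_presence(table: GenotypeTable) -> BinaryMatrix:
    """Binary allele-presence encoding of *table*.

    One column per (locus, allele) pair observed anywhere in the table,
    alleles sorted ascending within a locus; cell = 1 iff the sample
    carries >= 1 copy.  Cells of MISSING genotypes are masked.
    """
    column_index: list[tuple[str, int]] = []
    for j, locus in enumerate(table.loci):
        observed = np.unique(table.calls[:, j, :])
        for a in observed[observed != MISSING]:
            column_index.append((locus, int(a)))
    col_of = {pair: c for c, pair in enumerate(column_index)}

    n = table.n_samples
    values = np.zeros((n, len(column_index)), dtype=np.int8)
    missing = np.zeros_like(values, dtype=bool)
    geno_missing = table.missing_mask()
    for j, locus in enumerate(table.loci):
        cols = [c for c, (loc, _) in enumerate(column_index) if loc == locus]
        missing[np.ix_(geno_missing[:, j], cols)] = True
        for i in range(n):
            if geno_missing[i, j]:
                continue
            for a in table.calls[i, j]:
                if a != MISSING:
                    values[i, col_of[(locus, int(a))]] = 1
    return BinaryMatrix(list(table.sample_ids), column_index, values, missing)


def allele_counts(
    table: GenotypeTable,
    locus: str,
    group: Iterable[str] | None = None,
) -> AlleleCounts:
    """Counts of allele copies at *locus*, optionally over a sample subset.

    Every recorded allele copy in a non-missing genotype contributes one
    count (so a tetraploid scored ``{173, 175, 175, 180}`` adds two copies
    of 175).  Raises if the locus is unknown, the group is empty, or all
    genotypes in the group are MISSING at the locus.
    """
    try:
        j = table.loci.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    if group is None:
        rows = range(table.n_samples)
    else:
        index = {s: i for i, s in enumerate(table.sample_ids)}
        rows = [index[s] for s in group]
        if not rows:
            raise ValueError("empty sample group")
    counts: Counter[int] = Counter()
    for i in rows:
        for a in table.calls[i, j]:
            if a != MISSING:
                counts[int(a)] += 1
    if not counts:
        raise ValueError(
            f"no observed alleles at locus {locus!r} in the given group"
        )
    return AlleleCounts(locus, dict(sorted(counts.items())))


def export_structure(table: GenotypeTable, path) -> dict[str, dict[int, int]]:
    """Write *table* in STRUCTURE's multi-row-per-individual format.

    One header row of locus names, then ``ploidy`` rows per sample:
    ``sample_id pop_int allele ...`` with alleles integer-recoded per locus
    (1-based, ascending fragment size) and ``-9`` for missing.  Empty
    slots of a partially filled genotype repeat the last recorded allele,
    so every non-missing genotype fills all ``ploidy`` rows.

    Returns the per-locus recode map ``{locus: {fragment_size: code}}``
    (bijective per locus), for round-tripping.
    """
    recode: dict[str, dict[int, int]] = {}
    for j, locus in enumerate(table.loci):
        observed = np.unique(table.calls[:, j, :])
        alleles = [int(a) for a in observed if a != MISSING]
        recode[locus] = {a: k + 1 for k, a in enumerate(sorted(alleles))}

    pops = {p: k + 1 for k, p in enumerate(table.pop_sizes())}
    with open(path, "w") as fh:
        fh.write("\t".join(table.loci) + "\n")
        for i, sid in enumerate(table.sample_ids):
            rows = [[sid, str(pops[table.pop_labels[i]])] for _ in range(table.ploidy)]
            for j, locus in enumerate(table.loci):
                geno = table.genotype(i, j)
                if not geno:
                    coded = [-9] * table.ploidy
                else:
                    coded = [recode[locus][a] for a in geno]
                    coded += [coded[-1]] * (table.ploidy - len(coded))
                for k in range(table.ploidy):
                    rows[k].append(str(coded[k]))
            for r in rows:
                fh.write("\t".join(r) + "\n")
    return recode


def estimate_null_allele_freq(table: GenotypeTable, locus: str) -> float:
    """Null-allele frequency at *locus* by the Brookfield (1996) estimator.

    ``r = (He - Ho) / (1 + He)`` with He the expected heterozygosity from
    allele frequencies and Ho the observed heterozygote fraction; the
    result is clamped to [0, 1].  Only defined for diploid-coded tables
    where heterozygotes are distinguishable.
    """
    if table.ploidy != 2:
        raise ValueError(
            "null-allele estimation requires diploid coding (ploidy 2); "
            "undefined for presence/absence-coded polyploids"
        )
    ac = allele_counts(table, locus)
    p = ac.frequencies()
    he = 1.0 - float(np.sum(p**2))
    j = table.loci.index(locus)
    genos = [table.genotype(i, j) for i in range(table.n_samples)]
    genos = [g for g in genos if g]
    if not genos:
        raise ValueError(f"all genotypes MISSING at {locus!r}")
    ho = sum(1 for g in genos if len(set(g)) > 1) / len(genos)
    return float(np.clip((he - ho) / (1.0 + he), 0.0, 1.0))
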