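"""Parent-usage counts and co-usage networks from pedigree cross strings.

Passport pedigrees are recorded as cross notation ("Superior x Dejima",
possibly nested: "(B x C) x D").  Only first-generation parents are
considered: the computational content of a breeder's word-cloud/network
view of a collection.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PedigreeRecord",
    "parse_cross",
    "parent_frequency",
    "cooccurrence_edges",
    "read_pedigrees",
]

_WS = re.compile(r"\s+")


@dataclass
class PedigreeRecord:
    """One accession with its parsed list of parents."""

    accession: str
    parents: list[str]


def _normalize(name: str) -> str:
    return _WS.sub(" ", name).strip()


def parse_cross(text: str) -> list[str]:
    """Split a cross string into parent names.

    The cross operator is a standalone ``x`` or ``×`` at parenthesis
    depth 0; parenthesised sub-crosses are kept as opaque single parents.
    Whitespace is collapsed; order preserved.
    """
    s = _normalize(text)
    if not s:
        raise ValueError("empty pedigree string")
    parents: list[str] = []
    depth = 0
    current: list[str] = []
    tokens = s.split(" ")
    for tok in tokens:
        if tok in ("x", "×", "X") and depth == 0 and current:
            parents.append(" ".join(current))
            current = []
            continue
        depth += tok.count("(") - tok.count(")")
        current.append(tok)
    if current:
        parents.append(" ".join(current))
    parents = [p for p in (_normalize(p) for p in parents) if p]
    if not parents:
        raise ValueError(f"no parents parsed from {text!r}")
    return parents


def parent_frequency(
    records: Iterable[PedigreeRecord],
) -> list[tuple[str, int]]:
    """Ranked (parent, count) list over all records.

    Every mention counts; descending by count, ties alphabetical.
    """
    counts: Counter[str] = Counter()
    n_records = 0
    for rec in records:
        n_records += 1
        counts.update(rec.parents)
    if n_records == 0:
        raise ValueError("no pedigree records")
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def cooccurrence_edges(
    records: Iterable[PedigreeRecord], min_count: int = 1
) -> list[tuple[str, str, int]]:
    """Undirected co-usage edges between parents of the same cross.

    Edge weight = number of crosses in which the unordered pair appears;
    single-parent records contribute no edge; no self-edges.  Edges with
    weight < ``min_count`` are dropped.
    """
    weights: Counter[tuple[str, str]] = Counter()
    for rec in records:
        for a, b in combinations(rec.parents, 2):
            if a == b:
                continue
            weights[tuple(sorted((a, b)))] += 1
    return sorted(
        (a, b, w) for (a, b), w in weights.items() if w >= min_count
    )


def read_pedigrees(path) -> list[PedigreeRecord]:
    """Read a CSV with columns ``accession,pedigree`` into records.

    Rows with an empty pedigree are skipped.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"accession", "pedigree"} <= set(df.columns):
        raise ValueError("pedigree CSV needs 'accession' and 'pedigree' columns")
    records = []
    for _, row in df.iterrows():
        ped = row["pedigree"]
        if not isinstance(ped, str) or not ped.strip():
            continue
        records.append(PedigreeRecord(str(row["accession"]), parse_cross(ped)))
    return records
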