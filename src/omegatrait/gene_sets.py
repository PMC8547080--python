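"""Gene-list overlap statistics and shared gene-family expansions.

Overlap between two gene lists drawn from a common universe is tested with
a one-sided Fisher exact test (upper hypergeometric tail, the GeneOverlap
convention) and summarized by the sample odds ratio; odds ratio > 1 marks
enrichment beyond independence.  Gene-family expansion sets are reduced to
the families expanded in at least k members of a phenotype group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class OverlapResult:
    """Fisher overlap test between two gene lists in a universe of size N."""

    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    odds_ratio: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]  # [[both, A only], [B only, neither]]


def overlap_test(
    list_a, list_b, universe, alternative: str = "greater"
) -> OverlapResult:
    """Fisher exact test of independence of two gene lists.

    The 2x2 table counts (both, A-only, B-only, neither) genes in the
    universe.  ``alternative='greater'`` (default) gives the enrichment
    (upper-tail hypergeometric) p-value; the odds ratio is the sample
    estimate (a*d)/(b*c), with 0 when the overlap is empty and +inf when a
    zero off-diagonal cell makes the association unbounded.
    """
    A, B, U = set(list_a), set(list_b), set(universe)
    outside = (A | B) - U
    if outside:
        raise ValueError(f"genes outside the universe: {sorted(outside)[:10]}")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - len(A | B)
    table = ((a, b), (c, d))
    p = float(fisher_exact(np.array(table), alternative=alternative)[1])
    if a == 0:
        odds = 0.0
    elif b == 0 or c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    return OverlapResult(
        n_a=len(A), n_b=len(B), n_overlap=a, universe_size=len(U),
        odds_ratio=float(odds), p=p, table=table,
    )


@dataclass
class ExpansionSets:
    """Per-species expanded / contracted gene-family ID sets."""

    expanded: dict[str, set[str]] = field(default_factory=dict)
    contracted: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in set(self.expanded) & set(self.contracted):
            both = self.expanded[sp] & self.contracted[sp]
            if both:
                raise ValueError(
                    f"{sp}: families both expanded and contracted: {sorted(both)[:5]}"
                )

    @property
    def species(self) -> list[str]:
        return sorted(set(self.expanded) | set(self.contracted))

    def counts(self) -> pd.DataFrame:
        """Per-species totals of expanded and contracted families."""
        return pd.DataFrame(
            {
                "expanded": {sp: len(self.expanded.get(sp, set())) for sp in self.species},
                "contracted": {sp: len(self.contracted.get(sp, set())) for sp in self.species},
            }
        )

    @classmethod
    def from_tsv(cls, path) -> "ExpansionSets":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"species", "family_id", "direction"}
        if not required.issubset(df.columns):
            raise ValueError(f"expansion table needs columns {sorted(required)}")
        bad = set(df["direction"]) - {"expanded", "contracted"}
        if bad:
            raise ValueError(f"invalid direction values: {sorted(bad)}")
        exp: dict[str, set[str]] = {}
        con: dict[str, set[str]] = {}
        for sp, fam, direction in df.itertuples(index=False):
            (exp if direction == "expanded" else con).setdefault(sp, set()).add(fam)
        return cls(expanded=exp, contracted=con)

    def to_tsv(self, path) -> None:
        rows = []
        for sp in self.species:
            rows += [(sp, f, "expanded") for f in sorted(self.expanded.get(sp, set()))]
            rows += [(sp, f, "contracted") for f in sorted(self.contracted.get(sp, set()))]
        pd.DataFrame(rows, columns=["species", "family_id", "direction"]).to_csv(
            path, sep="\t", index=False
        )


def shared_expanded_families(
    expansion: ExpansionSets, group: set[str] | list[str], k: int
) -> set[str]:
    """Families expanded in at least k members of a species group.

    Mirrors the shared-expansion criterion used to flag families expanding
    in parallel across a phenotype group (e.g. >= 6 of 13 ascrotal species).
    """
    group = set(group)
    missing = group - set(expansion.species)
    if missing:
        raise KeyError(f"species without expansion data: {sorted(missing)}")
    if k > len(group):
        warnings.warn(
            f"k={k} exceeds group size {len(group)}; no family can qualify",
            UserWarning,
            stacklevel=2,
        )
        return set()
    counts: dict[str, int] = {}
    for sp in group:
        for fam in expansion.expanded.get(sp, set()):
            counts[fam] = counts.get(fam, 0) + 1
    return {fam for fam, c in counts.items() if c >= k}


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one ID per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
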