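"""Functional-category over-representation of m6A-modified gene sets.

For a selected gene set of size n drawn from a universe of N annotated
genes, a category with K members and k selected members is scored by
the one-sided Fisher exact test — the upper tail P(X >= k) of the
hypergeometric(N, K, n) distribution — with Benjamini-Hochberg
adjustment across tested categories. Effect sizes are reported as
"k/K" (selected genes in the category over category size), the form
used in m6A methylome figure legends. Categories with K < 2 have
untestable margins and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CategoryMap",
    "EnrichmentRow",
    "fisher_exact_upper",
    "enrich",
]


@dataclass
class CategoryMap:
    """Gene-to-category assignments over a gene universe.

    The universe defaults to every gene mentioned in the assignments; a
    wider universe (e.g. all annotated genes, with some uncategorized)
    may be supplied explicitly.
    """

    assignments: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.assignments)
        missing = set(self.assignments) - self.universe
        if missing:
            raise ValueError(f"assigned genes outside universe: {sorted(missing)[:5]}")
        for gene, cats in self.assignments.items():
            if not cats:
                raise ValueError(f"gene {gene} has an empty category set")

    def genes_in(self, category: str) -> set[str]:
        return {g for g, cats in self.assignments.items() if category in cats}

    @property
    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.assignments.values():
            out |= cats
        return out


@dataclass
class EnrichmentRow:
    """One category's over-representation result."""

    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float = 1.0

    @property
    def effect(self) -> str:
        return f"{self.k}/{self.K}"


def fisher_exact_upper(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact p-value P(X >= k), X ~ hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(selected: Iterable[str], category_map: CategoryMap) -> list[EnrichmentRow]:
    """Over-representation rows for every category touched by the selection.

    Rows are sorted by p-value ascending (ties by category label); BH
    q-values are computed over the tested categories. Categories with
    fewer than two universe members are skipped.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected gene set is empty")
    extra = selected - category_map.universe
    if extra:
        raise ValueError(f"selected genes outside universe: {sorted(extra)[:5]}")

    N = len(category_map.universe)
    n = len(selected)
    rows = []
    for cat in sorted(category_map.categories):
        members = category_map.genes_in(cat)
        K = len(members)
        if K < 2:
            continue
        k = len(members & selected)
        if k == 0:
            continue
        rows.append(
            EnrichmentRow(category=cat, k=k, K=K, n=n, N=N,
                          p_value=fisher_exact_upper(k, K, n, N))
        )
    if rows:
        qvals = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        qvals = np.maximum(qvals, [r.p_value for r in rows])
        for r, q in zip(rows, qvals):
            r.q_value = float(q)
    rows.sort(key=lambda r: (r.p_value, r.category))
    return rows
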