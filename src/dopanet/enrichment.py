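"""Hypergeometric over-representation analysis with BH correction.

Given a query gene set (e.g. a literature-curated disease catalog) and a
collection of pathways, each pathway is scored by the upper tail of the
hypergeometric distribution — the probability of drawing at least the
observed overlap when the query is sampled at random from the universe —
and p-values are corrected across the reported pathways with the
Benjamini–Hochberg step-up. Pathways overlapping the query in fewer than
``min_overlap`` genes are dropped before correction. Categories (e.g. KEGG
main classes) can then be summarized by their number of significant
pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import GeneSetCollection, normalize_symbols

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "aggregate_categories",
]


@dataclass
class EnrichmentResult:
    """One row per retained pathway: pathway, category, N, m, n, k, p, q."""

    table: pd.DataFrame

    def significant(self, alpha_q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha_q]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hypergeom_upper_tail(N: int, m: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes m, draws n).

    This is the enrichment p-value for an overlap of ``k`` between a
    pathway of size ``m`` and a query of size ``n`` in a universe of ``N``.
    """
    N, m, n, k = int(N), int(m), int(n), int(k)
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= m, n <= N, got N={N}, m={m}, n={n}")
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"require 0 <= k <= min(m, n), got k={k}, m={m}, n={n}")
    if k == 0:
        return 1.0  # P(X >= 0); also covers the empty-population edge case
    p = float(hypergeom.sf(k - 1, N, m, n))
    # the upper tail is strictly positive whenever k <= min(m, n); guard
    # against underflow for extreme overlaps
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    min_overlap: int = 10,
    filter_on: str = "overlap",
) -> EnrichmentResult:
    """Over-representation of ``query`` in each set of ``collection``.

    Parameters
    ----------
    universe
        Background gene population. Defaults to the union of all genes in
        the collection (the pathway-annotated genome). Query genes outside
        the universe are dropped with a warning.
    min_overlap
        Minimum number of "target genes" a pathway must have to be
        reported. With ``filter_on="overlap"`` (default) this counts query
        genes in the pathway; ``filter_on="pathway_size"`` counts the
        pathway's genes in the universe instead.

    BH correction runs over exactly the rows that survive the filter; rows
    are sorted by p ascending, ties broken by pathway name.
    """
    if filter_on not in ("overlap", "pathway_size"):
        raise ValueError("filter_on must be 'overlap' or 'pathway_size'")
    universe_set = (
        normalize_symbols(universe) if universe is not None else collection.all_genes()
    )
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = normalize_symbols(query)
    dropped = query_set - universe_set
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped"
        )
    query_set = frozenset(query_set & universe_set)
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name in collection:
        gs = collection[name]
        pathway = gs.genes & universe_set
        m = len(pathway)
        k = len(pathway & query_set)
        size_for_filter = k if filter_on == "overlap" else m
        if size_for_filter < min_overlap or m == 0:
            continue
        p = hypergeom_upper_tail(N, m, n, k)
        rows.append(
            {
                "pathway": name,
                "category": gs.category if gs.category is not None else "",
                "N": N,
                "m": m,
                "n": n,
                "k": k,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "category", "N", "m", "n", "k", "p"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return EnrichmentResult(table)


def aggregate_categories(
    result: EnrichmentResult, alpha_q: float = 0.05
) -> list[tuple[str, int]]:
    """Count significant pathways (q < alpha_q) per category, descending."""
    sig = result.significant(alpha_q)
    if not len(sig):
        return []
    counts = sig.groupby("category").size()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(cat, int(cnt)) for cat, cnt in ordered]
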