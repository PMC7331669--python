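"""Gene-set overrepresentation analysis of regulated protein sets.

The query (by default the up-regulated proteins at one intensity, mapped
to unique gene symbols) is compared against each catalog set restricted
to the platform universe. For a set containing K of the N background
genes and k of the n query genes, fold enrichment is (k/n)/(K/N) and the
raw p-value is the binomial upper tail P(X >= k), X ~ Binomial(n, K/N),
with Bonferroni correction over the sets that have nonzero background
overlap. A hypergeometric tail is available as an alternative test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

__all__ = [
    "GeneSetCatalog",
    "fold_enrichment",
    "binomial_overrepresentation_p",
    "bonferroni",
    "run_enrichment",
]


@dataclass
class GeneSetCatalog:
    """Named gene sets over a background universe.

    On construction each set is restricted to the universe; sets whose
    overlap with the universe is empty are kept (with zero members) so
    the caller can see they were untestable.
    """

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("set names must be unique")
        self.universe = frozenset(self.universe)
        self.sets = {
            name: frozenset(members) & self.universe
            for name, members in self.sets.items()
        }

    @classmethod
    def from_mapping(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCatalog":
        return cls(
            sets={k: frozenset(v) for k, v in sets.items()},
            universe=frozenset(universe),
        )


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment (k/n)/(K/N) of a set in the query vs background."""
    if n <= 0 or N <= 0:
        raise ValueError("query and background sizes must be positive")
    if k > n:
        raise ValueError("overlap k cannot exceed query size n")
    if K == 0:
        if k > 0:
            raise ValueError("set absent from background but present in query")
        return 0.0
    return (k / n) / (K / N)


def binomial_overrepresentation_p(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, p0)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("background proportion p0 must be in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p * m); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def map_proteins_to_genes(
    proteins: Iterable[str], platform_map: pd.DataFrame
) -> set[str]:
    """Unique gene symbols for a protein collection (aptamer-level ids are
    deduplicated at the gene level here)."""
    gene_of = platform_map.set_index("protein_id")["gene_symbol"]
    genes = set()
    for p in proteins:
        if p in gene_of.index:
            genes.add(gene_of.loc[p])
    return genes


def run_enrichment(
    query_genes: Iterable[str],
    catalog: GeneSetCatalog,
    method: str = "binomial",
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Overrepresentation of every catalog set in a query gene list.

    The query must be a subset of the catalog universe. Bonferroni m is
    the number of sets with nonzero background overlap (sets absent from
    the background are not comparisons). Results are sorted by descending
    fold enrichment, ties broken by raw p then set name.
    """
    if method not in ("binomial", "hypergeometric"):
        raise ValueError("method must be 'binomial' or 'hypergeometric'")
    query = set(query_genes)
    if not query:
        raise ValueError("query is empty after gene mapping")
    stray = query - set(catalog.universe)
    if stray:
        raise ValueError(
            f"query genes outside the background universe: {sorted(stray)[:5]}"
        )
    N = len(catalog.universe)
    n = len(query)
    testable = {name: s for name, s in catalog.sets.items() if len(s) > 0}
    m = len(testable)
    rows = []
    for name, members in testable.items():
        K = len(members)
        k = len(query & members)
        if k == 0 and not include_zero_overlap:
            continue
        if method == "binomial":
            p_raw = binomial_overrepresentation_p(k, n, K / N)
        else:
            p_raw = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold_enrichment(k, n, K, N),
                "p_raw": p_raw,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "k", "n", "K", "N", "fold_enrichment", "p_raw"],
    )
    out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(), m)
    return out.sort_values(
        ["fold_enrichment", "p_raw", "set_name"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
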