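"""PPI-expanded hypergeometric over-representation analysis.

The candidate gene set is expanded by one hop in a STRING-style
protein–protein interaction network (edges kept at combined score >= 700
by default), then each functional term is tested by the hypergeometric
upper tail: the probability of drawing at least the observed overlap when
|query| genes are sampled without replacement from the universe. Raw
p-values are adjusted by Benjamini–Hochberg step-up, both pooled across
all tested terms and within each source; significance is called on the
pooled adjustment at padj < 0.01 by default. The universe defaults to all
genes appearing in the supplied term collection.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import CohortError, EnrichmentResult, GeneSetTerm


def expand_gene_set(query: Iterable[str], ppi: Optional[nx.Graph]) -> set[str]:
    """One-hop expansion: the query plus every direct PPI neighbor of a
    query member. The query is always a subset of the result. Applying the
    expansion to an already expanded set may grow it further (one-hop is
    not transitive closure)."""
    expanded = {g.upper() for g in query}
    if ppi is None:
        return expanded
    for gene in sorted(expanded):
        if gene in ppi:
            expanded.update(ppi.neighbors(gene))
    return expanded


def hypergeom_test(
    term_genes: Iterable[str], query_genes: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p: P(overlap >= observed) drawing |query|
    genes without replacement from the universe; the term is intersected
    with the universe first."""
    universe = {g.upper() for g in universe}
    if not universe:
        raise CohortError("empty gene universe")
    query = {g.upper() for g in query_genes} & universe
    term = {g.upper() for g in term_genes} & universe
    overlap = len(term & query)
    # survival function is P(X > k), so evaluate at overlap-1 for >= overlap
    return float(hypergeom.sf(overlap - 1, len(universe), len(term), len(query)))


def adjust_pvalues(pvals: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg step-up by default),
    order-preserving, clipped to [0, 1]."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise CohortError("p-values outside [0, 1]")
    adjusted = multipletests(arr, method=method)[1]
    return np.clip(adjusted, 0.0, 1.0)


def enrich(
    query: Iterable[str],
    terms: Sequence[GeneSetTerm],
    universe: Optional[Iterable[str]] = None,
    padj_threshold: float = 0.01,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Test every term against the (already expanded) query.

    Results are sorted by pooled adjusted p ascending, then term id.
    Both a pooled adjustment across all terms and a within-source
    adjustment are reported; significance uses the pooled one.
    """
    if universe is None:
        universe_set: set[str] = set()
        for t in terms:
            universe_set.update(t.genes)
    else:
        universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise CohortError("empty gene universe")
    query_set = {g.upper() for g in query} & universe_set

    raw = [hypergeom_test(t.genes, query_set, universe_set) for t in terms]
    pooled = adjust_pvalues(raw, method=method) if terms else np.array([])
    by_source = np.empty(len(terms))
    for source in sorted({t.source for t in terms}):
        idx = [i for i, t in enumerate(terms) if t.source == source]
        by_source[idx] = adjust_pvalues([raw[i] for i in idx], method=method)

    results = []
    for i, t in enumerate(terms):
        eff_term = {g.upper() for g in t.genes} & universe_set
        results.append(
            EnrichmentResult(
                term_id=t.term_id,
                source=t.source,
                name=t.name,
                term_size=len(eff_term),
                overlap=len(eff_term & query_set),
                p_value=raw[i],
                p_adjusted=float(pooled[i]),
                p_adjusted_source=float(by_source[i]),
                significant=bool(pooled[i] < padj_threshold),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return results
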