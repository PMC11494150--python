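"""Hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N genes, a term with K
annotated genes in the universe and k of them in the query gets the
one-sided upper-tail p-value P[X >= k], X ~ Hypergeometric(N, K, n), with
Benjamini–Hochberg correction across tested terms.  The universe defaults
to the detected genes of the analysis, not the whole annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnnotationMap
from .diffexpr import bh_adjust

__all__ = ["enrich"]


def enrich(query, annotation: AnnotationMap, universe,
           min_term_size: int = 1) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    ``query`` must be a subset of ``universe``; term gene sets are
    intersected with the universe first, and terms smaller than
    ``min_term_size`` after intersection are dropped.  Rows are sorted by
    p-value.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe: {extra}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term_id, (term_name, genes) in annotation.items():
        term_genes = genes & universe
        size = len(term_genes)
        if size < min_term_size or size == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, size, n_query))
        fold = (k / n_query) / (size / n_universe) if n_query and k else 0.0
        rows.append({"term_id": term_id, "term_name": term_name,
                     "k": k, "K": size, "n": n_query, "N": n_universe,
                     "p_value": min(p, 1.0), "fold_enrichment": fold})
    result = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K",
                                         "n", "N", "p_value",
                                         "fold_enrichment"])
    result["fdr"] = bh_adjust(result["p_value"].to_numpy())
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)
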