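"""Hypergeometric over-representation of selected genes in annotation terms.

For a universe of ``N`` background genes of which ``K`` carry a term and
``n`` are selected, the enrichment p-value of observing ``k`` or more
selected genes with the term is the upper tail

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N, n).

Annotations are used as given, as flat (gene, term) pairs — no ontology
DAG or ancestor propagation. Raw p-values are reported (an optional
Benjamini-Hochberg column can be requested); results mirror the usual
term table: id, description, class, counts, P value.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .io import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "enrich", "top_terms"]

DEFAULT_TOP_K = 10


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    Computed stably (log space internally) for large ``N``; validates
    ``0 <= k <= min(K, n)``, ``n <= N`` and ``K <= N``.
    """
    if K > N:
        raise ValueError(f"K <= N violated: K={K}, N={N}")
    if n > N:
        raise ValueError(f"n <= N violated: n={n}, N={N}")
    if k < 0:
        raise ValueError(f"k >= 0 violated: k={k}")
    if k > min(K, n):
        raise ValueError(f"k <= min(K, n) violated: k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected_genes: set[str],
    background_genes: set[str],
    annotation: AnnotationMap,
    bh_column: bool = False,
) -> pd.DataFrame:
    """Test every annotated term for over-representation of selected genes.

    The universe is the intersection of ``background_genes`` (genes on
    the platform) with genes carrying at least one annotation; selected
    genes outside that universe are dropped with a logged count. Returns
    one row per term with ``K >= 1``, unsorted.
    """
    selected_genes = set(selected_genes)
    if not selected_genes <= set(background_genes):
        extra = sorted(selected_genes - set(background_genes))[:5]
        raise ValueError(f"selected genes not in background, e.g. {extra}")
    universe = set(background_genes) & annotation.genes
    n_dropped = len(selected_genes - universe)
    if n_dropped:
        logger.info(
            "%d selected genes have no annotation and are excluded from enrichment",
            n_dropped,
        )
    selected = selected_genes & universe
    N, n = len(universe), len(selected)
    ann = annotation.table[annotation.table["gene_id"].isin(universe)]
    rows = []
    for term_id, group in ann.groupby("term_id", sort=False):
        term_genes = set(group["gene_id"])
        K = len(term_genes)
        k = len(term_genes & selected)
        rows.append(
            {
                "term_id": term_id,
                "term_name": group["term_name"].iloc[0],
                "term_class": group["term_class"].iloc[0],
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": hypergeom_upper_tail(N, K, n, k),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "term_class", "N", "K", "n", "k", "p_value"],
    )
    if bh_column and len(result):
        result["p_bh"] = stats.false_discovery_control(result["p_value"], method="bh")
    return result


def top_terms(results: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Top-``k`` terms by ascending p-value.

    Ties are broken by larger selected-in-term count ``k``, then by
    lexicographic term id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = results.sort_values(
        by=["p_value", "k", "term_id"],
        ascending=[True, False, True],
        kind="stable",
        ignore_index=True,
    )
    return ranked.head(k)
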