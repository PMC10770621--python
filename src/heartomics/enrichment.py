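"""Over-representation analysis with the cumulative hypergeometric test.

The statistical universe of each annotation source is the union of its term
gene sets: only annotated genes enter the test, so padding a query with
annotation-free genes changes nothing.  P-values are corrected per source
with Benjamini-Hochberg FDR; terms with zero overlap are not tested (they
cannot be significant and would only inflate the correction burden).

A one-tailed Fisher exact test of enrichment equals this cumulative
hypergeometric upper tail, so no separate implementation is provided.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationDatabase

logger = logging.getLogger("heartomics.enrichment")

Q_MAX = 0.001


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them in the term, ``n`` drawn
    (the query), ``k`` the observed overlap.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy's M, n, N are universe, successes, draws
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    db: AnnotationDatabase | list[AnnotationDatabase],
    q_max: float = Q_MAX,
    pooled: bool = False,
    test_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Test a gene set against one or more annotation sources.

    Returns one row per tested term: source, term, description, k (overlap),
    K (term size), n (effective query size), N (universe size), p, q,
    significant (q < ``q_max``), overlap_genes.  BH correction is applied
    within each source unless ``pooled``.  Rows sorted by (q, source, term).
    """
    dbs = [db] if isinstance(db, AnnotationDatabase) else list(db)
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")

    rows: list[dict] = []
    for database in dbs:
        universe = database.universe
        eff_query = query & universe
        outside = query - universe
        if outside:
            logger.info(
                "source %s: %d query gene(s) outside the annotated universe excluded",
                database.source,
                len(outside),
            )
        if not eff_query:
            logger.warning("source %s: query disjoint from universe; no tests", database.source)
            continue
        n, N = len(eff_query), len(universe)
        for term in sorted(database.terms):
            desc, genes = database.terms[term]
            overlap = eff_query & genes
            k, K = len(overlap), len(genes)
            if k == 0 and not test_zero_overlap:
                continue
            rows.append(
                {
                    "source": database.source,
                    "term": term,
                    "description": desc,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": hypergeom_upper_tail(k, K, n, N),
                    "overlap_genes": ",".join(sorted(overlap)),
                }
            )
    cols = ["source", "term", "description", "k", "K", "n", "N", "p", "q",
            "significant", "overlap_genes"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    if pooled:
        df["q"] = bh_fdr(df["p"])
    else:
        df["q"] = np.nan
        for _, idx in df.groupby("source").groups.items():
            df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"])
    df["significant"] = df["q"] < q_max
    df = df.sort_values(["q", "source", "term"], kind="mergesort").reset_index(drop=True)
    return df[cols]
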