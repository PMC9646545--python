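"""Term enrichment of gene sets and binding-class enrichment in clusters.

Over-representation is tested per term with the one-sided Fisher exact test
(hypergeometric upper tail P(X >= k)) against a declared gene background —
the set of all genes assayable on the platform — with FDR adjustment across
all tested terms.  Cluster x binding-class contingency tables are tested
with the Pearson chi-squared statistic.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ChisqResult(NamedTuple):
    statistic: float
    p: float
    dof: int
    low_expected: bool   # any expected cell count < 5


def fisher_enrich(
    query,
    annotation: pd.DataFrame,
    background,
    method: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of every annotated term in a query set.

    ``annotation`` has columns gene_id, term_id and is restricted to the
    background before testing; the term universe is every term with at least
    one background gene.  ``method`` selects the adjustment: "BH"
    (Benjamini-Hochberg FDR, default) or "hochberg" (Hochberg step-up).
    """
    query, background = set(query), set(background)
    if not query:
        raise ValueError("query set is empty")
    if not background:
        raise ValueError("background set is empty")
    outside = sorted(query - background)
    if outside:
        raise ValueError(f"query genes outside the background: {outside[:10]}")
    ann = annotation[annotation["gene_id"].isin(background)]
    if ann.empty:
        raise ValueError("no annotation left after restricting to the background")
    n, big_n = len(query), len(background)
    rows = []
    for term, members in ann.groupby("term_id")["gene_id"]:
        term_genes = set(members)
        big_k = len(term_genes)
        k = len(term_genes & query)
        # upper tail P(X >= k) under Hypergeometric(N, K, n)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": n,
                "K": big_k,
                "N": big_n,
                "fold_enrichment": (k / n) / (big_k / big_n),
                "p_fisher": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    mt_method = {"BH": "fdr_bh", "hochberg": "simes-hochberg"}.get(method)
    if mt_method is None:
        raise ValueError(f"unknown adjustment method {method!r}; use 'BH' or 'hochberg'")
    _, p_adj, _, _ = multipletests(out["p_fisher"], alpha=alpha, method=mt_method)
    out["p_adjusted"] = p_adj
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values(["p_adjusted", "p_fisher", "term_id"]).reset_index(drop=True)


def chisq_class_enrichment(contingency: pd.DataFrame) -> ChisqResult:
    """Pearson chi-squared test of independence on a cluster x class count table.

    Zero-margin rows/columns are dropped with a warning; a warning flag is
    set when any expected count is below 5 (the classical validity caveat).
    """
    table = pd.DataFrame(contingency).astype(float)
    if (table.to_numpy() < 0).any() or not np.allclose(
        table.to_numpy(), np.round(table.to_numpy())
    ):
        raise ValueError("contingency table must hold non-negative integer counts")
    zero_rows = table.index[table.sum(axis=1) == 0].tolist()
    zero_cols = table.columns[table.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        logger.warning("dropping zero-margin rows %s / columns %s", zero_rows, zero_cols)
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table of at least 2x2 after dropping zero margins")
    observed = table.to_numpy()
    stat, p, dof, expected = stats.chi2_contingency(observed, correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.warning("some expected counts are < 5; chi-squared approximation is weak")
    return ChisqResult(float(stat), float(p), int(dof), low)
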