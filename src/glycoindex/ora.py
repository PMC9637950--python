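"""Hypergeometric over-representation analysis against a custom background.

One-sided enrichment of a query gene list in user-supplied annotation terms
(GMT), restricted to a declared background universe (e.g. the genes
measured in every dataset), with BH correction across tested terms.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection
from .stats import bh_adjust


def ora_enrich(
    query: Sequence[str],
    annotation: GeneSetCollection,
    background: Sequence[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    Per term restricted to the background: with N background genes, K term
    genes, n query genes and k hits, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n). Query genes outside the background are
    dropped with a warning; terms with no background gene are skipped.

    Returns a DataFrame with columns term, k, K, n, N, p_value, fdr,
    hit_genes (comma-joined, sorted), ordered by p ascending then term name.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    q_all = list(dict.fromkeys(query))
    q = [g for g in q_all if g in bg]
    dropped = len(q_all) - len(q)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the background were dropped")
    if not q:
        raise ValueError("query is empty after restriction to the background")
    qset = set(q)
    N, n = len(bg), len(qset)
    rows = []
    for term, genes in annotation:
        term_bg = set(genes) & bg
        K = len(term_bg)
        if K == 0:
            continue
        hits = sorted(term_bg & qset)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0), ",".join(hits)))
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_value", "fdr", "hit_genes"]
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value", "hit_genes"])
    df["fdr"] = bh_adjust(df["p_value"].values)
    df = df[["term", "k", "K", "n", "N", "p_value", "fdr", "hit_genes"]]
    return df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
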