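"""Consensus glycolysis-gene / cell-marker co-expression network.

Per dataset, Spearman correlations for every (glycolysis gene, marker gene)
cross pair with BH correction within the dataset (FDR < 0.05, strict). A
pair becomes a consensus edge when it is supported by at least
``min_support`` of the five evidence channels — four dataset co-expression
flags plus one protein-protein interaction flag — and, when required, the
correlation signs of all *significant* datasets agree (non-significant
datasets are ignored for the sign rule). The edge sign is that shared sign,
so an edge needs at least one significant dataset; a pair supported only by
the PPI flag carries no sign and is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionDataset, PpiTable
from .stats import bh_adjust

logger = logging.getLogger(__name__)

FDR_SIGNIFICANT = 0.05


@dataclass
class ConsensusEdge:
    gene_a: str
    gene_b: str
    sign: str  # "+" or "-"
    support_count: int
    evidence: Dict[str, bool]


@dataclass
class ConsensusNetwork:
    nodes: Dict[str, str]  # gene -> role ("glycolysis" | "marker:<cell_type>" | "")
    edges: List[ConsensusEdge]

    def evidence_keys(self) -> List[str]:
        keys: List[str] = []
        for e in self.edges:
            for k in e.evidence:
                if k not in keys:
                    keys.append(k)
        return keys

    def edge_pairs(self) -> List[Tuple[str, str]]:
        return [(e.gene_a, e.gene_b) for e in self.edges]

    def __len__(self) -> int:
        return len(self.edges)


def _spearman_matrix(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Spearman rho for every row of a against every row of b (columns = samples)."""
    ra = sps.rankdata(values_a, axis=1)
    rb = sps.rankdata(values_b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra ** 2).sum(axis=1))
    nb = np.sqrt((rb ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra @ rb.T) / np.outer(na, nb)
    return rho


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation used throughout the package."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho ** 2, 1e-300, None))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def coexpr_per_dataset(
    ds: ExpressionDataset,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
) -> pd.DataFrame:
    """Spearman co-expression of every cross pair present in the dataset.

    Returns one row per (gene_a, gene_b) pair with rho, p_value, fdr (BH
    over all testable pairs in this dataset) and a strict fdr < 0.05
    significance flag. Constant genes make their pairs untestable: such rows
    keep NaN statistics, are excluded from the BH family and are never
    significant. Pairs with identical genes on both sides are skipped.
    """
    ga = [g for g in dict.fromkeys(genes_a) if g in ds.values.index]
    gb = [g for g in dict.fromkeys(genes_b) if g in ds.values.index]
    if not ga or not gb:
        raise ValueError("gene lists share no genes with the dataset")
    A = ds.values.loc[ga].values
    B = ds.values.loc[gb].values
    n = ds.n_samples
    const_a = np.array([np.unique(row).size == 1 for row in A])
    const_b = np.array([np.unique(row).size == 1 for row in B])
    rho = _spearman_matrix(A, B)
    p = _spearman_p(rho, n)

    rows = []
    for i, a in enumerate(ga):
        for j, b in enumerate(gb):
            if a == b:
                continue
            testable = not (const_a[i] or const_b[j])
            rows.append(
                (a, b,
                 rho[i, j] if testable else np.nan,
                 p[i, j] if testable else np.nan,
                 testable)
            )
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p_value", "tested"])
    df["fdr"] = np.nan
    tested = df["tested"].values
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"].values)
    df["significant"] = df["fdr"] < FDR_SIGNIFICANT
    df.attrs["dataset_id"] = ds.dataset_id
    return df


def consensus_network(
    tables: Dict[str, pd.DataFrame],
    ppi: PpiTable,
    min_support: int = 4,
    require_sign_consistency: bool = True,
    roles: Optional[Dict[str, str]] = None,
) -> ConsensusNetwork:
    """Apply the >= min_support-of-(n_datasets + 1) consensus rule.

    ``tables`` maps dataset id to the output of :func:`coexpr_per_dataset`.
    Evidence flags per pair are the per-dataset significance flags plus PPI
    membership; pairs absent from a dataset (gene unmeasured or untestable)
    get a false flag for that dataset so the five-channel arithmetic stays
    intact. The result is independent of dataset and pair ordering.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    n_channels = len(tables) + 1
    if min_support > n_channels:
        raise ValueError(
            f"min_support={min_support} exceeds the {n_channels} evidence channels"
        )
    dataset_ids = sorted(tables)
    info: Dict[Tuple[str, str], Dict[str, Tuple[bool, float]]] = {}
    for did in dataset_ids:
        t = tables[did]
        for row in t.itertuples(index=False):
            key = (row.gene_a, row.gene_b)
            info.setdefault(key, {})[did] = (bool(row.significant), row.rho)

    edges: List[ConsensusEdge] = []
    for (a, b) in sorted(info):
        per_ds = info[(a, b)]
        evidence = {did: per_ds.get(did, (False, np.nan))[0] for did in dataset_ids}
        evidence["ppi"] = (a, b) in ppi
        support = sum(evidence.values())
        if support < min_support:
            continue
        sig_signs = {
            np.sign(per_ds[did][1])
            for did in dataset_ids
            if evidence[did] and np.isfinite(per_ds.get(did, (False, np.nan))[1])
        }
        sig_signs.discard(0.0)
        if not sig_signs:
            logger.info("pair %s-%s reached support %d without a defined sign; dropped",
                        a, b, support)
            continue
        if require_sign_consistency and len(sig_signs) > 1:
            continue
        if len(sig_signs) > 1:
            # sign ambiguous but consistency not required: majority of
            # significant rho values decides, ties favor positive
            rhos = [per_ds[did][1] for did in dataset_ids if evidence[did]]
            sign = "+" if np.sum(np.sign(rhos)) >= 0 else "-"
        else:
            sign = "+" if sig_signs.pop() > 0 else "-"
        edges.append(
            ConsensusEdge(gene_a=a, gene_b=b, sign=sign,
                          support_count=int(support), evidence=evidence)
        )

    nodes: Dict[str, str] = {}
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            nodes[g] = (roles or {}).get(g, "")
    return ConsensusNetwork(nodes=nodes, edges=edges)
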