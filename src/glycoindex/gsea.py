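"""Gene set enrichment analysis (GSEA) from scratch.

Phenotype-based gene ranking (signal-to-noise or moderated t), the weighted
Kolmogorov-Smirnov running enrichment score, permutation significance with
sign-matched normalization, and leading-edge extraction.

Conventions (documented assumptions, since published analyses rarely state
them): signal-to-noise ranking with the classic variance floor, weight p=1,
and a gene-permutation null by default; a phenotype-permutation null is
available. Ranking ties break by gene symbol ascending so results are
platform-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import ExpressionDataset, GeneSetCollection
from .stats import bh_adjust

logger = logging.getLogger(__name__)

RANK_METRICS = ("signal_to_noise", "moderated_t")
NULL_SCHEMES = ("gene", "phenotype")

_NES_EPS = 1e-12


@dataclass
class RankedList:
    """Genes sorted by a case-vs-control metric, descending.

    Ties break by gene symbol ascending (stable, deterministic).
    """

    genes: np.ndarray
    metrics: np.ndarray
    metric_name: str

    def __len__(self) -> int:
        return len(self.genes)

    def position_of(self, gene: str) -> int:
        idx = np.nonzero(self.genes == gene)[0]
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])


@dataclass
class RunningScore:
    es: float
    curve: np.ndarray
    extremum_index: int
    weight: float


@dataclass
class GseaResult:
    dataset_id: str
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: List[str]
    n_perm: int
    seed: int
    nes_degenerate: bool = False


def _group_matrices(ds: ExpressionDataset) -> Tuple[np.ndarray, np.ndarray]:
    groups = ds.metadata["group"].values
    case = ds.values.values[:, groups == "case"]
    ctrl = ds.values.values[:, groups == "control"]
    if case.shape[1] < 3 or ctrl.shape[1] < 3:
        raise ValueError(
            f"signal-to-noise ranking needs >=3 samples per group "
            f"(got case={case.shape[1]}, control={ctrl.shape[1]})"
        )
    return case, ctrl


def signal_to_noise(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Per-gene (mu_case - mu_ctrl) / (sd_case + sd_ctrl) with the classic
    GSEA floor: each group's sd is raised to at least max(0.2*|mu|, 0.2)."""
    mu_c = case.mean(axis=1)
    mu_k = ctrl.mean(axis=1)
    sd_c = case.std(axis=1, ddof=1)
    sd_k = ctrl.std(axis=1, ddof=1)
    sd_c = np.maximum(sd_c, np.maximum(0.2 * np.abs(mu_c), 0.2))
    sd_k = np.maximum(sd_k, np.maximum(0.2 * np.abs(mu_k), 0.2))
    return (mu_c - mu_k) / (sd_c + sd_k)


def rank_genes(ds: ExpressionDataset, metric: str = "signal_to_noise") -> RankedList:
    """Rank all genes case-vs-control, positive metric = higher in case."""
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric '{metric}'; expected one of {RANK_METRICS}")
    genes = np.asarray(ds.genes, dtype=object)
    if metric == "signal_to_noise":
        case, ctrl = _group_matrices(ds)
        m = signal_to_noise(case, ctrl)
    else:
        from . import diffexpr

        design = diffexpr.build_design(ds.metadata, contrast="case_vs_control")
        fits = diffexpr.fit_linear_models(ds, design)
        table = diffexpr.moderate_ebayes(fits)
        m = table.loc[list(genes), "t_mod"].values
    order = np.lexsort((genes.astype(str), -m))
    return RankedList(genes=genes[order], metrics=m[order], metric_name=metric)


def _prepare_set_mask(ranked: RankedList, gene_set: Sequence[str]) -> np.ndarray:
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                       count=len(ranked.genes))
    if not mask.any():
        raise ValueError("no gene of the set is present in the ranked list")
    if mask.all():
        raise ValueError("gene set covers the entire ranking; ES undefined")
    return mask


def _running_curve(abs_w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """P_hit - P_miss per position for precomputed |metric|^weight values."""
    hit_w = np.where(mask, abs_w, 0.0)
    denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom
    n = mask.size
    n_hit = int(mask.sum())
    p_miss = np.cumsum(~mask) / (n - n_hit)
    return p_hit - p_miss


def _es_from_curve(curve: np.ndarray) -> Tuple[float, int]:
    idx = int(np.argmax(np.abs(curve)))  # earliest position on ties
    return float(curve[idx]), idx


def running_es(ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0) -> RunningScore:
    """Weighted KS running enrichment score over the ranked list.

    At position i, P_hit accumulates |metric|^weight over set members
    (normalized by the set total) and P_miss accumulates 1/(N - N_hit) over
    non-members; the ES is the signed largest absolute deviation of their
    difference. If every set member has |metric|^weight == 0 the statistic
    falls back to weight 0 for this set (with a logged warning).
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    mask = _prepare_set_mask(ranked, gene_set)
    abs_w = np.abs(ranked.metrics) ** weight
    used_weight = weight
    if abs_w[mask].sum() == 0.0:
        logger.warning("all |metric|^weight are zero for the set; falling back to weight 0")
        abs_w = np.ones_like(abs_w)
        used_weight = 0.0
    curve = _running_curve(abs_w, mask)
    es, idx = _es_from_curve(curve)
    return RunningScore(es=es, curve=curve, extremum_index=idx, weight=used_weight)


def extract_leading_edge(
    ranked: RankedList, gene_set: Sequence[str], rs: RunningScore
) -> List[str]:
    """Set members at/before the peak (ES > 0) or at/after the trough (ES < 0).

    The extremum position itself is included on both sides; an ES of exactly
    zero yields an empty leading edge.
    """
    members = set(gene_set)
    if rs.es > 0:
        region = ranked.genes[: rs.extremum_index + 1]
    elif rs.es < 0:
        region = ranked.genes[rs.extremum_index:]
    else:
        return []
    return [g for g in region if g in members]


def _gene_perm_nulls(
    abs_w: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = abs_w.size
    nulls = np.empty(n_perm, dtype=float)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        mask[:] = False
        mask[idx] = True
        curve = _running_curve(abs_w, mask)
        nulls[i], _ = _es_from_curve(curve)
    return nulls


def _phenotype_perm_nulls(
    ds: ExpressionDataset,
    gene_set: Sequence[str],
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    values = ds.values.values
    genes = np.asarray(ds.genes, dtype=object)
    groups = ds.metadata["group"].values
    n_case = int((groups == "case").sum())
    members = set(gene_set)
    nulls = np.empty(n_perm, dtype=float)
    n = values.shape[1]
    for i in range(n_perm):
        perm = rng.permutation(n)
        case = values[:, perm[:n_case]]
        ctrl = values[:, perm[n_case:]]
        m = signal_to_noise(case, ctrl)
        order = np.lexsort((genes.astype(str), -m))
        g_sorted = genes[order]
        mask = np.fromiter((g in members for g in g_sorted), dtype=bool, count=len(g_sorted))
        abs_w = np.abs(m[order]) ** weight
        if abs_w[mask].sum() == 0.0:
            abs_w = np.ones_like(abs_w)
        curve = _running_curve(abs_w, mask)
        nulls[i], _ = _es_from_curve(curve)
    return nulls


def _significance_from_nulls(es: float, nulls: np.ndarray) -> Tuple[float, float, bool]:
    same_sign = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
    n_match = same_sign.size
    if n_match == 0:
        logger.warning("no matching-sign null enrichment scores; NES is degenerate")
        return es / _NES_EPS, 1.0, True
    p = (1.0 + float(np.sum(np.abs(same_sign) >= abs(es)))) / (1.0 + n_match)
    nes = es / float(np.mean(np.abs(same_sign)))
    return nes, p, False


def gsea_significance(
    ds: ExpressionDataset,
    gene_set: Sequence[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "gene",
) -> Tuple[float, float]:
    """Permutation NES and p-value for one gene set.

    The gene scheme permutes set membership over the ranked universe; the
    phenotype scheme permutes group labels and re-ranks. NES divides the
    observed ES by the mean |null ES| of matching sign; the p-value is the
    sign-matched tail fraction with the +1 pseudo-count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in NULL_SCHEMES:
        raise ValueError(f"unknown permutation scheme '{scheme}'")
    ranked = rank_genes(ds)
    nes, p, _ = _significance_from_ranked(ranked, ds, gene_set, weight, n_perm, seed, scheme)
    return nes, p


def _significance_from_ranked(
    ranked: RankedList,
    ds: Optional[ExpressionDataset],
    gene_set: Sequence[str],
    weight: float,
    n_perm: int,
    seed: int,
    scheme: str,
) -> Tuple[float, float, bool]:
    rs = running_es(ranked, gene_set, weight)
    rng = np.random.default_rng(seed)
    mask = _prepare_set_mask(ranked, gene_set)
    if scheme == "gene":
        abs_w = np.abs(ranked.metrics) ** rs.weight
        if abs_w.sum() == 0.0:
            abs_w = np.ones_like(abs_w)
        nulls = _gene_perm_nulls(abs_w, int(mask.sum()), n_perm, rng)
    else:
        if ds is None:
            raise ValueError("phenotype permutation requires the dataset")
        nulls = _phenotype_perm_nulls(ds, gene_set, rs.weight, n_perm, rng)
    return _significance_from_nulls(rs.es, nulls)


def run_gsea_collection(
    ds: ExpressionDataset,
    coll: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "gene",
) -> List[GseaResult]:
    """GSEA for every set in a collection with BH FDR across the collection.

    Sets sharing no genes with the dataset are skipped with a logged
    warning. Identical sets receive identical null ensembles (the seed is
    reused per set), so their results coincide exactly.
    """
    if len(coll) == 0:
        raise ValueError("empty gene set collection")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = rank_genes(ds)
    present = set(ranked.genes)
    results: List[GseaResult] = []
    pvals: List[float] = []
    for name, genes in coll:
        usable = [g for g in genes if g in present]
        if not usable:
            logger.warning("skipping set '%s': no genes present in dataset %s",
                           name, ds.dataset_id)
            continue
        rs = running_es(ranked, usable, weight)
        nes, p, degenerate = _significance_from_ranked(
            ranked, ds, usable, weight, n_perm, seed, scheme
        )
        le = extract_leading_edge(ranked, usable, rs)
        results.append(
            GseaResult(
                dataset_id=ds.dataset_id,
                set_name=name,
                es=rs.es,
                nes=nes,
                p_value=p,
                fdr=np.nan,
                leading_edge=le,
                n_perm=n_perm,
                seed=seed,
                nes_degenerate=degenerate,
            )
        )
        pvals.append(p)
    if results:
        fdrs = bh_adjust(np.asarray(pvals))
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


def gsea_results_to_frame(results: Sequence[GseaResult]):
    """Tabulate GSEA results (leading edges comma-joined) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in results],
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
            "n_perm": [r.n_perm for r in results],
            "seed": [r.seed for r in results],
        }
    )


def gsea_results_from_frame(df) -> List[GseaResult]:
    results = []
    for row in df.itertuples(index=False):
        le = [] if (not isinstance(row.leading_edge, str) or not row.leading_edge) \
            else row.leading_edge.split(",")
        results.append(
            GseaResult(
                dataset_id=str(row.dataset_id),
                set_name=str(row.set_name),
                es=float(row.es),
                nes=float(row.nes),
                p_value=float(row.p_value),
                fdr=float(row.fdr),
                leading_edge=le,
                n_perm=int(row.n_perm),
                seed=int(row.seed),
            )
        )
    return results
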