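"""Core gene set pooling and the ssGSEA glycolysis index.

The core set pools GSEA leading edges across datasets: a gene qualifies
when it is a leading-edge member of at least one passing gene set in at
least ``min_datasets`` datasets (direction and FDR filters configurable;
the defaults harvest significantly *down*-regulated sets, the situation the
index was designed for).

The per-sample score is the Barbie-style integrated ssGSEA enrichment score
on within-sample expression ranks with exponent alpha (default 0.25). The
raw (unnormalized) ES is the index; optional range normalization divides by
max-min across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .gsea import GseaResult
from .io import ExpressionDataset

logger = logging.getLogger(__name__)

DIRECTIONS = ("down", "up", "any")


@dataclass
class CoreGeneSet:
    """Genes that were leading-edge members in >= min_datasets datasets."""

    genes: List[str]
    support: Dict[str, List[str]]
    min_datasets: int

    def __post_init__(self) -> None:
        for g in self.genes:
            if len(self.support.get(g, [])) < self.min_datasets:
                raise ValueError(f"gene {g} has support below min_datasets")

    def __len__(self) -> int:
        return len(self.genes)

    def support_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "n_datasets": [len(self.support[g]) for g in self.genes],
                "datasets": [",".join(sorted(self.support[g])) for g in self.genes],
            }
        )


@dataclass
class SampleScoreVector:
    """Per-sample enrichment scores (e.g. the glycolysis index)."""

    sample_ids: List[str]
    scores: np.ndarray
    score_name: str
    alpha: float
    normalized: bool

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.scores):
            raise ValueError("one score per sample required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.score_name)


def pool_core_genes(
    results: Sequence[GseaResult],
    min_datasets: int = 2,
    require_direction: str = "down",
    fdr_max: Optional[float] = 0.05,
) -> CoreGeneSet:
    """Pool leading edges across datasets into the core gene set.

    A gene is "leading in dataset d" iff it appears in the leading edge of
    at least one gene set in d whose GSEA result passes the direction filter
    (down => ES < 0, up => ES > 0) and, when ``fdr_max`` is given, has
    fdr <= fdr_max. Genes leading in >= min_datasets distinct datasets are
    kept, with their supporting dataset ids recorded.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    if require_direction not in DIRECTIONS:
        raise ValueError(f"require_direction must be one of {DIRECTIONS}")
    dataset_ids = {r.dataset_id for r in results}
    if len(dataset_ids) < min_datasets:
        raise ValueError(
            f"results cover {len(dataset_ids)} datasets; need >= {min_datasets}"
        )
    support: Dict[str, set] = {}
    for r in results:
        if require_direction == "down" and not (r.es < 0):
            continue
        if require_direction == "up" and not (r.es > 0):
            continue
        if fdr_max is not None and not (r.fdr <= fdr_max):
            continue
        for g in r.leading_edge:
            support.setdefault(g, set()).add(r.dataset_id)
    genes = sorted(g for g, ds in support.items() if len(ds) >= min_datasets)
    return CoreGeneSet(
        genes=genes,
        support={g: sorted(support[g]) for g in genes},
        min_datasets=min_datasets,
    )


def _ssgsea_single(
    values: np.ndarray,
    gene_keys: np.ndarray,
    mask_by_gene: np.ndarray,
    alpha: float,
) -> float:
    """Integrated ssGSEA ES for one sample.

    ``gene_keys`` are alphabetical ranks of the gene symbols used as a
    deterministic tie-break (value descending, symbol ascending).
    """
    n = values.size
    order = np.lexsort((gene_keys, -values))
    in_set = mask_by_gene[order]
    # within-sample ranks, 1 = lowest expression => top of list has rank N
    v = np.arange(n, 0, -1, dtype=float)
    w = np.where(in_set, v ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    n_in = int(in_set.sum())
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    ds: ExpressionDataset,
    gene_set: Sequence[str],
    alpha: float = 0.25,
    normalize: bool = False,
    score_name: str = "ssgsea",
) -> SampleScoreVector:
    """Single-sample GSEA enrichment scores for every sample.

    Per sample, genes are ordered by expression descending (ties broken by
    gene symbol ascending); with v = within-sample ranks (1 = lowest), the
    ES is the sum over positions of the difference between the
    alpha-weighted in-set rank ECDF and the uniform out-of-set ECDF — the
    integrated (summed) statistic, not the running-sum extremum. Scores are
    computed sample by sample, so they are identical whether samples are
    scored jointly or singly; range normalization (divide by max-min across
    samples) is the only cross-sample step.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = set(gene_set)
    genes = np.asarray(ds.genes, dtype=object)
    mask = np.fromiter((g in members for g in genes), dtype=bool, count=genes.size)
    if not mask.any():
        raise ValueError("no gene of the set is present in the dataset")
    if mask.all():
        raise ValueError("gene set covers every gene; out-of-set ECDF undefined")
    if normalize and ds.n_samples < 2:
        raise ValueError("range normalization undefined for a single sample")
    gene_keys = np.argsort(np.argsort(genes.astype(str)))
    values = ds.values.values
    scores = np.array(
        [
            _ssgsea_single(values[:, j], gene_keys, mask, alpha)
            for j in range(values.shape[1])
        ]
    )
    normalized = False
    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ == 0:
            warnings.warn("all ssGSEA scores identical; skipping range normalization")
        else:
            scores = scores / rng_
            normalized = True
    return SampleScoreVector(
        sample_ids=list(ds.samples),
        scores=scores,
        score_name=score_name,
        alpha=alpha,
        normalized=normalized,
    )


def glycolysis_index(
    ds: ExpressionDataset,
    core,
    alpha: float = 0.25,
    normalize: bool = False,
) -> SampleScoreVector:
    """The glycolysis index: ssGSEA ES of the core glycolysis genes."""
    genes = core.genes if isinstance(core, CoreGeneSet) else list(core)
    sv = ssgsea_score(ds, genes, alpha=alpha, normalize=normalize,
                      score_name="glycolysis_index")
    return sv


def median_split_by_region(scores: SampleScoreVector, meta: pd.DataFrame) -> pd.Series:
    """Label each sample low/high by its score relative to its region's median.

    Ties (score exactly equal to the median) go to "low". A region with a
    single sample is labeled low with a warning.
    """
    s = scores.to_series()
    missing = [sid for sid in s.index if sid not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    regions = meta.loc[s.index, "region"]
    labels = pd.Series(index=s.index, dtype=object, name="split_label")
    for region, idx in s.groupby(regions).groups.items():
        vals = s.loc[idx]
        if len(vals) == 1:
            logger.warning("region %s has a single sample; labeled 'low'", region)
            labels.loc[idx] = "low"
            continue
        med = vals.median()
        labels.loc[idx] = np.where(vals <= med, "low", "high")
    return labels
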