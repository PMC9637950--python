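"""Covariate-adjusted differential expression with variance moderation.

Per-gene ordinary least squares on a design of intercept + contrast +
brain-region dummies + sex + a natural cubic spline of age (one degree of
freedom), followed by empirical-Bayes shrinkage of the residual variances
toward a scaled inverse-chi-square prior whose parameters (d0, s0^2) are
estimated by method of moments on log s_g^2. The moderated t-statistic is
log2FC / (s~_g * sqrt(v_contrast)) with d0 + d_g degrees of freedom.

Reference levels are fixed for sign stability: first region alphabetically,
sex F, group control — so a positive contrast coefficient means higher in
the case (or high-index) group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .io import ExpressionDataset
from .stats import bh_adjust, trigamma_inverse

CONTRASTS = ("case_vs_control", "high_vs_low_index")

D0_CAP = 1e6


def natural_spline_basis(values, df: int = 1) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns.

    Boundary knots at min/max of the input, interior knots at quantiles for
    df > 1. With df = 1 there are no interior knots, and the natural
    constraints (linearity beyond the boundaries with continuous second
    derivatives) reduce the basis to a single linear column.
    """
    x = np.asarray(values, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("constant input: spline basis undefined")
    if df == 1:
        return x[:, None].copy()
    interior = np.quantile(x, [i / df for i in range(1, df)])
    knots = np.concatenate([[lo], interior, [hi]])  # K = df + 1 knots
    K = knots.size

    def d(k_idx: int) -> np.ndarray:
        num = (np.clip(x - knots[k_idx], 0, None) ** 3
               - np.clip(x - knots[K - 1], 0, None) ** 3)
        return num / (knots[K - 1] - knots[k_idx])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    values: pd.DataFrame  # samples x columns
    contrast_column: str

    @property
    def columns(self) -> List[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.values


def _check_full_rank(df: pd.DataFrame) -> None:
    X = df.values
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the QR decomposition diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [c for c, v in zip(df.columns, diag) if v < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def build_design(
    meta: pd.DataFrame,
    contrast: str = "case_vs_control",
    split_labels: Optional[pd.Series] = None,
    age_df: int = 1,
) -> DesignMatrix:
    """Intercept + contrast indicator + region dummies + sex + age spline.

    ``case_vs_control`` codes case = 1; ``high_vs_low_index`` requires
    per-sample split labels and codes high = 1. Region dummies use the first
    region alphabetically as reference and are dropped entirely for
    single-region data.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast '{contrast}'")
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    if contrast == "case_vs_control":
        cols["contrast"] = (meta["group"] == "case").astype(float).values
    else:
        if split_labels is None:
            raise ValueError("high_vs_low_index contrast requires split labels")
        labels = split_labels.loc[meta.index]
        bad = set(labels) - {"low", "high"}
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}")
        cols["contrast"] = (labels == "high").astype(float).values
    regions = sorted(meta["region"].unique())
    for region in regions[1:]:
        cols[f"region_{region}"] = (meta["region"] == region).astype(float).values
    cols["sex_M"] = (meta["sex"] == "M").astype(float).values
    basis = natural_spline_basis(meta["age"].astype(float).values, df=age_df)
    for j in range(basis.shape[1]):
        cols[f"age_spline_{j + 1}"] = basis[:, j]
    df = pd.DataFrame(cols, index=meta.index)
    _check_full_rank(df)
    return DesignMatrix(values=df, contrast_column="contrast")


@dataclass
class LinearFits:
    """Per-gene OLS results against a shared design."""

    genes: List[str]
    coefficients: pd.DataFrame  # genes x design columns
    sigma2: np.ndarray
    residual_df: float
    v_contrast: float  # unscaled variance of the contrast coefficient
    contrast_column: str


def fit_linear_models(ds: ExpressionDataset, design: DesignMatrix) -> LinearFits:
    """Ordinary least squares per gene; log2FC = contrast coefficient."""
    X = design.matrix
    n, p = X.shape
    if list(design.values.index) != list(ds.samples):
        raise ValueError("design rows do not align with dataset samples")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    Y = ds.values.values  # genes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (X @ xtx_inv)  # genes x p
    resid = Y - beta @ X.T
    rank = np.linalg.matrix_rank(X)
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    c_idx = design.columns.index(design.contrast_column)
    return LinearFits(
        genes=list(ds.genes),
        coefficients=pd.DataFrame(beta, index=ds.genes, columns=design.columns),
        sigma2=sigma2,
        residual_df=float(df_resid),
        v_contrast=float(xtx_inv[c_idx, c_idx]),
        contrast_column=design.contrast_column,
    )


def moderate_ebayes(fits: LinearFits) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics and BH-adjusted p-values.

    The prior (d0, s0^2) is fit by method of moments on z_g = log s_g^2
    using the digamma/trigamma identities for log chi-square moments; the
    trigamma equation is inverted by Newton iteration. When the observed
    spread of z_g is at or below its sampling expectation, d0 is capped
    (effectively infinite pooling) and every posterior variance equals s0^2.
    """
    genes = fits.genes
    if len(genes) < 10:
        raise ValueError("variance moderation needs >= 10 genes")
    s2 = fits.sigma2
    dg = fits.residual_df
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("too few genes with nonzero residual variance")
    z = np.log(s2[ok]) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, dg / 2.0)
    if evar > 0:
        d0 = min(2.0 * trigamma_inverse(evar), D0_CAP)
    else:
        d0 = D0_CAP
    s02 = float(np.exp(np.mean(z) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
    lfc = fits.coefficients[fits.contrast_column].values
    t_mod = lfc / np.sqrt(s2_post * fits.v_contrast)
    df_total = min(d0 + dg, 1e7)
    p = 2.0 * sps.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t_mod": t_mod,
            "p_value": p,
            "fdr": bh_adjust(p),
            "sigma": np.sqrt(s2),
            "residual_df": dg,
        },
        index=pd.Index(genes, name="gene"),
    )
    table.attrs["d0"] = d0
    table.attrs["s02"] = s02
    return table


def select_degs(table: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 0.5) -> List[str]:
    """Genes with fdr < fdr_max AND |log2fc| > lfc_min (both strict)."""
    if fdr_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    keep = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > lfc_min)
    return list(table.index[keep])


def overlap_genes(a: Sequence[str], b: Sequence[str]) -> List[str]:
    """Sorted intersection of two gene lists."""
    return sorted(set(a) & set(b))
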