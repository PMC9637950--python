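"""Brain microenvironment quantification and association tests.

Two complementary abundance estimates: marker-set ssGSEA enrichment scores
(a rank-based relative-abundance proxy, e.g. for microglia) and
non-negative least squares deconvolution of de-logged bulk expression
against a cell-type signature matrix. Associations use two-sided Wilcoxon
rank-sum tests with a directed -log10 p (positive = higher in cases),
Spearman correlation, and covariate-adjusted linear/logistic models.

The NNLS deconvolution is a transparent reference-free stand-in for
heavier signature-deconvolution suites: ``absolute`` mode returns the raw
coefficients, ``relative`` mode rescales each sample's coefficients to sum
to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .index import ssgsea_score
from .io import ExpressionDataset, GeneSetCollection, SignatureMatrix

logger = logging.getLogger(__name__)

ABUNDANCE_MODES = ("relative", "absolute")
EXACT_WILCOXON_MAX_N = 20
_P_FLOOR = 1e-300


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    directed_log_p: float
    rho: Optional[float] = None
    adjusted: bool = False
    failed: bool = False


def _directed_log_p(p: float, direction: float) -> float:
    if not np.isfinite(p):
        return float("nan")
    return float(np.sign(direction) * (-np.log10(max(p, _P_FLOOR))))


def score_markers(
    ds: ExpressionDataset,
    markers: GeneSetCollection,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA enrichment score of each cell type's markers, per sample.

    Returns a samples x cell_types DataFrame. Marker sets sharing no gene
    with the dataset are skipped with a warning.
    """
    cols = {}
    for cell_type, genes in markers:
        present = [g for g in genes if g in ds.values.index]
        if not present:
            logger.warning("skipping cell type '%s': no marker genes in dataset %s",
                           cell_type, ds.dataset_id)
            continue
        sv = ssgsea_score(ds, present, alpha=alpha, score_name=cell_type)
        cols[cell_type] = sv.scores
    if not cols:
        raise ValueError("no marker set shares genes with the dataset")
    return pd.DataFrame(cols, index=ds.samples)


def nnls_deconvolve(
    ds: ExpressionDataset,
    sig: SignatureMatrix,
    mode: str = "relative",
) -> pd.DataFrame:
    """Cell-type abundances by non-negative least squares per sample.

    Expression is de-logged to linear scale (2**x - 1) and regressed on the
    signature columns over shared genes. Relative mode rescales each
    sample's coefficients to sum to one (an all-zero solution becomes a
    uniform vector with a warning); absolute mode returns raw coefficients.
    """
    if mode not in ABUNDANCE_MODES:
        raise ValueError(f"mode must be one of {ABUNDANCE_MODES}")
    shared = [g for g in sig.genes if g in ds.values.index]
    if len(shared) < 2:
        raise ValueError("need >= 2 genes shared between dataset and signature")
    A = sig.values.loc[shared].values  # genes x cell_types
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("signature matrix is rank-deficient on shared genes")
    linear = np.power(2.0, ds.values.loc[shared].values) - 1.0
    k = len(sig.cell_types)
    out = np.empty((ds.n_samples, k))
    for j in range(ds.n_samples):
        coef, _ = optimize.nnls(A, linear[:, j])
        if mode == "relative":
            total = coef.sum()
            if total == 0:
                warnings.warn(f"all-zero NNLS solution for sample {ds.samples[j]}; "
                              "returning uniform proportions")
                coef = np.full(k, 1.0 / k)
            else:
                coef = coef / total
        out[j] = coef
    return pd.DataFrame(out, index=ds.samples, columns=sig.cell_types)


def compare_groups(values, labels) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test, case vs control.

    Exact p-value when the combined sample size is <= 20 and there are no
    ties; normal approximation with tie correction otherwise.
    directed_log_p is signed by median(case) - median(control).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    case = values[labels == "case"]
    ctrl = values[labels == "control"]
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("both groups need >= 2 samples")
    n_total = case.size + ctrl.size
    has_ties = np.unique(values).size < n_total
    method = "exact" if (n_total <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    direction = float(np.median(case) - np.median(ctrl))
    if p >= 1.0 or direction == 0.0:
        dlp = 0.0 if direction == 0.0 else _directed_log_p(p, direction)
    else:
        dlp = _directed_log_p(p, direction)
    return AssociationResult(statistic=float(res.statistic), p_value=p,
                             directed_log_p=dlp)


def spearman_assoc(x, y) -> AssociationResult:
    """Spearman correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4 for the Spearman test")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    return AssociationResult(
        statistic=float(rho),
        p_value=float(p),
        directed_log_p=_directed_log_p(float(p), float(rho)),
        rho=float(rho),
    )


def adjusted_assoc(
    y,
    x,
    covariates: Optional[pd.DataFrame] = None,
    family: str = "linear",
) -> AssociationResult:
    """Association of y with x adjusted for covariates.

    Fits y ~ x + covariates by least squares (``linear``) or logistic
    regression (``logistic``, y binary 0/1) and returns the Wald statistic
    and p-value for x's coefficient. Perfect separation in the logistic fit
    is reported as a failed result with NaN p-value rather than raised.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    parts = [pd.Series(x, name="x")]
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    X = pd.concat(parts, axis=1)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        failed = AssociationResult(statistic=float("nan"), p_value=float("nan"),
                                   directed_log_p=float("nan"), adjusted=True,
                                   failed=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return failed
        if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse["x"]):
            return failed
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    stat = float(fit.tvalues["x"])
    p = float(fit.pvalues["x"])
    return AssociationResult(
        statistic=stat,
        p_value=p,
        directed_log_p=_directed_log_p(p, stat),
        adjusted=True,
    )
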