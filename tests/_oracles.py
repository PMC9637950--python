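"""Independent brute-force oracles used to pin expected values.

Each oracle is a naive, literal transcription of the statistic's definition,
kept deliberately separate from the package implementation it checks.
"""

import math

import numpy as np


def naive_running_es(metrics, in_set, weight):
    """Per-position running-sum ES via an explicit loop.

    metrics/in_set are aligned with the ranked order (descending metric).
    Returns (es, extremum_index, curve).
    """
    n = len(metrics)
    n_hit = sum(in_set)
    denom_hit = sum(abs(metrics[i]) ** weight for i in range(n) if in_set[i])
    p_hit = 0.0
    p_miss = 0.0
    curve = []
    for i in range(n):
        if in_set[i]:
            p_hit += abs(metrics[i]) ** weight / denom_hit
        else:
            p_miss += 1.0 / (n - n_hit)
        curve.append(p_hit - p_miss)
    best = 0
    for i in range(1, n):
        if abs(curve[i]) > abs(curve[best]):
            best = i
    return curve[best], best, curve


def naive_ssgsea(values, genes, gene_set, alpha):
    """Integrated ssGSEA ES for one sample via an explicit per-position loop.

    Genes are ordered by (value descending, symbol ascending); v = rank from
    the bottom (1 = lowest expression).
    """
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], genes[i]))
    members = set(gene_set)
    n_in = sum(1 for g in genes if g in members)
    denom_in = 0.0
    for pos, i in enumerate(order):
        if genes[i] in members:
            denom_in += float(n - pos) ** alpha
    p_in = 0.0
    p_out = 0.0
    total = 0.0
    for pos, i in enumerate(order):
        if genes[i] in members:
            p_in += float(n - pos) ** alpha / denom_in
        else:
            p_out += 1.0 / (n - n_in)
        total += p_in - p_out
    return total


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_reference(p):
    """BH step-up via statsmodels (independent of the package's version)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def consensus_rule_reference(dataset_flags, dataset_signs, ppi_flag, min_support,
                             require_sign_consistency):
    """Literal evaluation of the consensus retention rule for one pair.

    dataset_flags: per-dataset significance booleans; dataset_signs: the rho
    sign (+1/-1) for each dataset (only meaningful where the flag is true).
    Returns (retained, sign) where sign is '+'/'-' or None.
    """
    support = sum(dataset_flags) + int(ppi_flag)
    if support < min_support:
        return False, None
    sig_signs = {s for f, s in zip(dataset_flags, dataset_signs) if f}
    if not sig_signs:
        return False, None  # no significant dataset -> no sign -> dropped
    if require_sign_consistency and len(sig_signs) > 1:
        return False, None
    if len(sig_signs) == 1:
        return True, "+" if sig_signs.pop() > 0 else "-"
    total = sum(s for f, s in zip(dataset_flags, dataset_signs) if f)
    return True, "+" if total >= 0 else "-"
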