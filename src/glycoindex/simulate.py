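"""Synthetic multi-region case/control expression data with planted structure.

Emulates the study design the pipeline targets: four region-stratified
case/control cohorts (frontal cortex, temporal cortex, hippocampus,
entorhinal cortex) on a shared gene universe, with

* a planted gene set shifted in cases (negative = downregulated),
* a per-sample latent pathway-activity factor shared by the planted genes
  (pathway genes are co-regulated in real brain expression data, and the
  high-vs-low-index contrast is only meaningful when they are),
* age and sex covariate effects on random gene subsets,
* planted cross-gene co-expression for network recovery, and
* optional cell-type mixtures drawn from a signature matrix.

Expression follows a Gaussian model on the log2 scale (normalized
microarray intensities are approximately Gaussian in log space); ages are
Uniform(60, 95), the typical late-onset dementia range. Everything is a
pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .io import (
    ExpressionDataset,
    GeneSetCollection,
    SignatureMatrix,
    write_expression_dataset,
    write_gmt,
    write_signature_matrix,
)

DEFAULT_REGIONS = ("FC", "TC", "HP", "EC")

# fixed synthetic gene nomenclature: a 50-gene "glycolysis universe"
# (default planted set = first 30), six brain cell types with 8 markers each
GLYCO_UNIVERSE = tuple(f"GLY{i:03d}" for i in range(1, 51))
DEFAULT_PLANTED = GLYCO_UNIVERSE[:30]

MARKER_SETS: Dict[str, Tuple[str, ...]] = {
    "astrocyte": tuple(f"AS{i:02d}" for i in range(1, 9)),
    "endothelial": tuple(f"EN{i:02d}" for i in range(1, 9)),
    "microglia": tuple(f"MG{i:02d}" for i in range(1, 9)),
    "neuron": tuple(f"NE{i:02d}" for i in range(1, 9)),
    "oligodendrocyte": tuple(f"OL{i:02d}" for i in range(1, 9)),
    "opc": tuple(f"OP{i:02d}" for i in range(1, 9)),
}

# Planted glycolysis-gene / marker-gene correlations. Sources are glycolysis
# genes OUTSIDE the default planted (case-shifted) set: planted genes share a
# latent pathway factor, so coupling a marker to one of them would correlate
# it with the whole planted block and the "10 planted pairs" ground truth
# would no longer describe the data.
DEFAULT_COEXPR_PAIRS: Tuple[Tuple[str, str, float], ...] = (
    ("GLY031", "AS01", 0.7),
    ("GLY032", "EN01", 0.7),
    ("GLY033", "MG01", 0.7),
    ("GLY034", "NE01", 0.7),
    ("GLY035", "OL01", 0.7),
    ("GLY036", "OP01", 0.7),
    ("GLY037", "MG02", 0.7),
    ("GLY038", "NE02", 0.7),
    ("GLY039", "AS02", 0.7),
    ("GLY040", "OL02", 0.7),
)

AGE_RANGE = (60.0, 95.0)
AGE_CENTER = 77.5
AGE_GENE_FRACTION = 0.10
SEX_GENE_FRACTION = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    regions: Tuple[str, ...] = DEFAULT_REGIONS
    n_per_group: int = 30
    planted_set: Tuple[str, ...] = DEFAULT_PLANTED
    effect_size: float = -0.8
    age_effect: float = 0.01
    sex_effect: float = 0.2
    noise_sd: float = 0.5
    pathway_factor_sd: float = 0.5
    coexpr_pairs: Tuple[Tuple[str, str, float], ...] = DEFAULT_COEXPR_PAIRS
    mixture_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < len(self.planted_set):
            raise ValueError("n_genes must be >= the planted set size")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for a, b, rho in self.coexpr_pairs:
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"target rho {rho} for ({a},{b}) outside (-1, 1)")


def null_config(seed: int = 0, n_genes: int = 2000, n_per_group: int = 30) -> SimulationConfig:
    """A configuration with no planted structure (calibration scenarios)."""
    return SimulationConfig(
        n_genes=n_genes,
        n_per_group=n_per_group,
        planted_set=(),
        effect_size=0.0,
        pathway_factor_sd=0.0,
        coexpr_pairs=(),
        mixture_mode=False,
        seed=seed,
    )


def gene_universe(config: SimulationConfig) -> List[str]:
    """The shared gene universe: planted genes, glycolysis nulls, markers, filler."""
    names: List[str] = list(dict.fromkeys(config.planted_set))
    for g in GLYCO_UNIVERSE:
        if len(names) >= config.n_genes:
            break
        if g not in names:
            names.append(g)
    for genes in MARKER_SETS.values():
        for g in genes:
            if len(names) >= config.n_genes:
                break
            if g not in names:
                names.append(g)
    i = 1
    while len(names) < config.n_genes:
        g = f"GENE{i:05d}"
        if g not in names:
            names.append(g)
        i += 1
    return names[: config.n_genes]


def _universe_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1_000_003])


def _universe_params(config: SimulationConfig):
    """Gene-level parameters shared by every region (means, covariate genes)."""
    genes = gene_universe(config)
    rng = _universe_rng(config)
    means = rng.normal(7.0, 1.5, size=len(genes))
    n_age = int(round(AGE_GENE_FRACTION * len(genes)))
    n_sex = int(round(SEX_GENE_FRACTION * len(genes)))
    age_idx = rng.choice(len(genes), size=n_age, replace=False)
    sex_idx = rng.choice(len(genes), size=n_sex, replace=False)
    return genes, means, age_idx, sex_idx


def generate_expression_dataset(config: SimulationConfig, region: str) -> ExpressionDataset:
    """One region's case/control dataset; reproducible given (seed, region)."""
    if region not in config.regions:
        raise ValueError(f"region '{region}' not in config.regions {config.regions}")
    genes, means, age_idx, sex_idx = _universe_params(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in config.planted_set if g not in gene_pos]
    if missing:
        raise ValueError(f"planted genes not in the gene universe: {missing[:5]}")

    region_idx = config.regions.index(region)
    rng = np.random.default_rng([config.seed, 7, region_idx])
    n_genes = len(genes)
    n = 2 * config.n_per_group
    groups = np.array(["control"] * config.n_per_group + ["case"] * config.n_per_group)
    sexes = np.array([("F" if i % 2 == 0 else "M") for i in range(n)])
    ages = rng.uniform(*AGE_RANGE, size=n)

    values = means[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n))
    if age_idx.size:
        values[age_idx] += config.age_effect * (ages - AGE_CENTER)[None, :]
    if sex_idx.size:
        values[sex_idx] += config.sex_effect * (sexes == "M").astype(float)[None, :]

    planted_idx = np.array([gene_pos[g] for g in config.planted_set], dtype=int)
    if planted_idx.size:
        if config.pathway_factor_sd > 0:
            factor = rng.normal(0.0, config.pathway_factor_sd, size=n)
            values[planted_idx] += factor[None, :]
        values[np.ix_(planted_idx, np.nonzero(groups == "case")[0])] += config.effect_size

    samples = [f"{region}_s{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {"group": groups, "region": region, "age": ages, "sex": sexes},
        index=pd.Index(samples, name="sample_id"),
    )
    ds = ExpressionDataset(
        dataset_id=region,
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=meta,
    )
    if config.coexpr_pairs:
        ds = plant_coexpression(ds, config.coexpr_pairs,
                                seed=[config.seed, 99_991, region_idx])
    return ds


def plant_coexpression(
    ds: ExpressionDataset,
    pairs: Sequence[Tuple[str, str, float]],
    seed=0,
) -> ExpressionDataset:
    """Rebuild each target gene as a rho-weighted mixture of its partner.

    For a pair (a, b, rho), gene b's centered values become
    ``sd_b * (rho * z_a + sqrt(1 - rho^2) * eps)`` around its original mean,
    so the population correlation with gene a is approximately rho. Pairs
    sharing the same target gene would overwrite each other and are
    rejected.
    """
    targets = [b for _, b, _ in pairs]
    dup = {t for t in targets if targets.count(t) > 1}
    if dup:
        raise ValueError(f"pairs share target genes (would overwrite): {sorted(dup)}")
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    for a, b, rho in pairs:
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"target rho {rho} outside (-1, 1)")
        for g in (a, b):
            if g not in values.index:
                raise ValueError(f"gene '{g}' not in the dataset")
        xa = values.loc[a].values
        xb = values.loc[b].values
        sd_a = xa.std()
        if sd_a == 0:
            raise ValueError(f"source gene '{a}' is constant")
        za = (xa - xa.mean()) / sd_a
        sd_b = xb.std() if xb.std() > 0 else 1.0
        eps = rng.normal(0.0, 1.0, size=xb.size)
        values.loc[b] = xb.mean() + sd_b * (rho * za + np.sqrt(1.0 - rho ** 2) * eps)
    return ExpressionDataset(dataset_id=ds.dataset_id, values=values,
                             metadata=ds.metadata.copy())


def generate_mixture_samples(
    sig: SignatureMatrix,
    proportions: pd.DataFrame,
    noise_sd: float,
    seed: int = 0,
    dataset_id: str = "mixture",
    metadata: Optional[pd.DataFrame] = None,
) -> ExpressionDataset:
    """Bulk samples as linear mixtures of signature columns.

    Linear expression = signature @ proportions^T, multiplied by log-normal
    noise (sigma = noise_sd in natural-log units), then log2(x + 1).
    Proportion rows must sum to 1 within 1e-8 with non-negative entries.
    """
    P = proportions.values.astype(float)
    if list(proportions.columns) != sig.cell_types:
        raise ValueError("proportion columns must match signature cell types")
    if (P < 0).any():
        raise ValueError("proportions must be non-negative")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("each proportion row must sum to 1 (tolerance 1e-8)")
    rng = np.random.default_rng(seed)
    linear = sig.values.values @ P.T  # genes x samples
    if noise_sd > 0:
        linear = linear * np.exp(rng.normal(0.0, noise_sd, size=linear.shape))
    values = np.log2(linear + 1.0)
    samples = [str(s) for s in proportions.index]
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "group": "control",
                "region": "MIX",
                "age": 70.0,
                "sex": [("F" if i % 2 == 0 else "M") for i in range(len(samples))],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=sig.genes, columns=samples),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Fixture bundle


def make_glycolysis_sets(config: SimulationConfig) -> GeneSetCollection:
    """Seven overlapping glycolysis-like gene sets (sizes 10-40).

    Drawn from the 50-gene glycolysis universe containing the planted set;
    the largest set is forced to contain every planted gene so leading-edge
    pooling has full coverage, the rest are random overlapping subsets.
    """
    universe = [g for g in gene_universe(config) if g in GLYCO_UNIVERSE
                or g in config.planted_set]
    universe = list(dict.fromkeys(universe))
    rng = np.random.default_rng([config.seed, 31])
    planted = [g for g in config.planted_set if g in universe]
    nulls = [g for g in universe if g not in planted]
    sets: Dict[str, List[str]] = {}
    size1 = min(40, len(universe))
    extra = [g for g in nulls if g in universe][: max(0, size1 - len(planted))]
    sets["SIM_GLYCOLYSIS_1"] = sorted(planted + extra)
    for i, size in enumerate((35, 30, 25, 20, 15, 10), start=2):
        size = min(size, len(universe))
        chosen = rng.choice(len(universe), size=size, replace=False)
        sets[f"SIM_GLYCOLYSIS_{i}"] = sorted(universe[j] for j in chosen)
    return GeneSetCollection(sets=sets, source="simulated")


def make_marker_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets={ct: list(genes) for ct, genes in MARKER_SETS.items()},
        source="simulated",
    )


def make_signature_matrix(config: SimulationConfig) -> SignatureMatrix:
    """Linear-scale signature: each cell type expresses its own markers highly."""
    rng = np.random.default_rng([config.seed, 47])
    cell_types = list(MARKER_SETS)
    genes = [g for ct in cell_types for g in MARKER_SETS[ct]]
    base = 6.0
    vals = np.full((len(genes), len(cell_types)), base)
    vals = vals * np.exp(rng.normal(0.0, 0.2, size=vals.shape))
    row = 0
    for ct_idx, ct in enumerate(cell_types):
        for _ in MARKER_SETS[ct]:
            vals[row, ct_idx] = 120.0 * np.exp(rng.normal(0.0, 0.2))
            row += 1
    return SignatureMatrix(
        values=pd.DataFrame(vals, index=genes, columns=cell_types)
    )


def make_mixture_proportions(
    config: SimulationConfig, n_per_group: int = 20
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth mixture proportions with a case shift.

    Cases carry more microglia and fewer neurons (gliosis with neuronal
    loss, the pattern the deconvolution stage is meant to detect). Returns
    (proportions, metadata).
    """
    rng = np.random.default_rng([config.seed, 53])
    cell_types = list(MARKER_SETS)
    base_alpha = {"astrocyte": 4.0, "endothelial": 2.0, "microglia": 3.0,
                  "neuron": 8.0, "oligodendrocyte": 3.0, "opc": 2.0}
    rows, groups = [], []
    for grp in ("control", "case"):
        alpha = dict(base_alpha)
        if grp == "case":
            alpha["microglia"] *= 2.0
            alpha["neuron"] *= 0.5
        a = np.array([alpha[ct] for ct in cell_types])
        draws = rng.gamma(shape=a, scale=1.0, size=(n_per_group, len(cell_types)))
        rows.append(draws / draws.sum(axis=1, keepdims=True))
        groups.extend([grp] * n_per_group)
    P = np.vstack(rows)
    samples = [f"MIX_s{i + 1:03d}" for i in range(P.shape[0])]
    proportions = pd.DataFrame(P, index=pd.Index(samples, name="sample_id"),
                               columns=cell_types)
    ages = rng.uniform(*AGE_RANGE, size=len(samples))
    metadata = pd.DataFrame(
        {
            "group": groups,
            "region": "MIX",
            "age": ages,
            "sex": [("F" if i % 2 == 0 else "M") for i in range(len(samples))],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return proportions, metadata


def make_ppi_edges(config: SimulationConfig) -> List[Tuple[str, str, float]]:
    """A PPI table consistent with the planted co-expression pairs.

    The first six planted pairs get high-confidence scores; a handful of
    decoy pairs sit above and below the 0.7 confidence cut.
    """
    edges: List[Tuple[str, str, float]] = []
    for i, (a, b, _rho) in enumerate(config.coexpr_pairs[:6]):
        edges.append((a, b, round(0.85 + 0.02 * i, 3)))
    decoys_high = [("GLY020", "AS05", 0.75), ("GLY021", "NE05", 0.72),
                   ("GLY022", "MG05", 0.8)]
    decoys_low = [("GLY023", "OL05", 0.4), ("GLY024", "EN05", 0.69),
                  ("GLY025", "OP05", 0.3)]
    planted = {(a, b) for a, b, _ in config.coexpr_pairs}
    for a, b, s in decoys_high + decoys_low:
        if (a, b) not in planted:
            edges.append((a, b, s))
    return edges


def make_fixture_bundle(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Write a complete, pipeline-loadable fixture directory.

    Per-region expression + metadata TSVs, the seven glycolysis-like sets
    (GMT), cell-type marker sets (GMT), a PPI TSV consistent with the
    planted pairs, a signature TSV, an optional mixture dataset with its
    ground-truth proportions, a ground_truth.json and a ready-to-run
    config.yaml. Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    dataset_entries = []
    for region in config.regions:
        ds = generate_expression_dataset(config, region)
        expr_p = out / f"expr_{region}.tsv"
        meta_p = out / f"meta_{region}.tsv"
        write_expression_dataset(ds, expr_p, meta_p)
        paths[f"expr_{region}"] = expr_p
        paths[f"meta_{region}"] = meta_p
        dataset_entries.append(
            {"id": region, "expression": expr_p.name, "metadata": meta_p.name}
        )

    glyco = make_glycolysis_sets(config)
    paths["gene_sets"] = out / "glycolysis_sets.gmt"
    write_gmt(glyco, paths["gene_sets"])

    markers = make_marker_collection()
    paths["markers"] = out / "cell_markers.gmt"
    write_gmt(markers, paths["markers"])

    ppi_edges = make_ppi_edges(config)
    paths["ppi"] = out / "ppi.tsv"
    pd.DataFrame(ppi_edges, columns=["gene_a", "gene_b", "score"]).to_csv(
        paths["ppi"], sep="\t", index=False
    )

    sig = make_signature_matrix(config)
    paths["signature"] = out / "signature.tsv"
    write_signature_matrix(sig, paths["signature"])

    ground_truth = {
        "planted_set": sorted(config.planted_set),
        "effect_size": config.effect_size,
        "coexpr_pairs": [[a, b, rho] for a, b, rho in config.coexpr_pairs],
        "ppi_pairs": [[a, b] for a, b, _ in ppi_edges],
        "marker_sets": {ct: list(genes) for ct, genes in MARKER_SETS.items()},
        "seed": config.seed,
    }

    if config.mixture_mode:
        proportions, mix_meta = make_mixture_proportions(config)
        mix = generate_mixture_samples(
            sig, proportions, noise_sd=0.1,
            seed=int(np.random.default_rng([config.seed, 59]).integers(2 ** 31)),
            metadata=mix_meta,
        )
        paths["mixture_expr"] = out / "mixture_expr.tsv"
        paths["mixture_meta"] = out / "mixture_meta.tsv"
        write_expression_dataset(mix, paths["mixture_expr"], paths["mixture_meta"])
        paths["true_proportions"] = out / "true_proportions.tsv"
        proportions.to_csv(paths["true_proportions"], sep="\t")
        ground_truth["true_proportions"] = paths["true_proportions"].name

    paths["ground_truth"] = out / "ground_truth.json"
    with paths["ground_truth"].open("w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cfg = {
        "datasets": dataset_entries,
        "gene_sets": paths["gene_sets"].name,
        "markers": paths["markers"].name,
        "ppi": paths["ppi"].name,
        "signature": paths["signature"].name,
        "output_dir": "results",
        "seed": config.seed,
        "gsea": {"weight": 1.0, "n_perm": 500, "scheme": "gene"},
        "pooling": {"min_datasets": 2, "direction": "down", "fdr_max": 0.05},
        "ssgsea": {"alpha": 0.25, "normalize": False},
        "de": {"fdr_max": 0.05, "lfc_min": 0.5},
        "network": {"min_support": 4, "sign_consistency": True, "ppi_min_score": 0.7},
    }
    paths["config"] = out / "config.yaml"
    with paths["config"].open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    return paths
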