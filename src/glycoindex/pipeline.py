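"""Config-driven orchestration of the full glycolysis-index analysis.

Stage order mirrors the analysis: per-dataset GSEA over the glycolysis gene
sets -> leading-edge pooling into the core set -> per-sample ssGSEA index
with per-region median split -> two moderated differential-expression
contrasts (case vs control over the combined regions; high vs low index
within cases) -> DEG overlap -> over-representation analysis against the
genes measured in every dataset -> microenvironment scoring, deconvolution
and associations -> consensus co-expression + PPI network.

Every stage writes plain TSV outputs plus a deterministic manifest
(config hash, seed, per-output SHA-256); a run log records wall times and
is the only non-deterministic artifact. Identical config + seed therefore
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, gsea, index as index_mod, microenv, network as network_mod, ora
from .io import (
    ExpressionDataset,
    GeneSetCollection,
    parse_gmt,
    read_expression_dataset,
    read_ppi_table,
    read_signature_matrix,
    write_gmt,
    write_network,
)

logger = logging.getLogger(__name__)

STAGES = (
    "gsea",
    "pool",
    "index",
    "de_case_vs_control",
    "de_high_vs_low_index",
    "ora",
    "microenv",
    "network",
)


@dataclass
class DatasetPaths:
    id: str
    expression: Path
    metadata: Path


@dataclass
class PipelineConfig:
    datasets: List[DatasetPaths]
    gene_sets: Path
    markers: Path
    ppi: Path
    output_dir: Path
    signature: Optional[Path] = None
    seed: int = 0
    gsea_weight: float = 1.0
    gsea_n_perm: int = 500
    gsea_scheme: str = "gene"
    pool_min_datasets: int = 2
    pool_direction: str = "down"
    pool_fdr_max: Optional[float] = 0.05
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = False
    de_fdr_max: float = 0.05
    de_lfc_min: float = 0.5
    network_min_support: int = 4
    network_sign_consistency: bool = True
    ppi_min_score: float = 0.7

    def validate(self) -> None:
        if not self.datasets:
            raise ValueError("config lists no datasets")
        for d in self.datasets:
            for p in (d.expression, d.metadata):
                if not Path(p).exists():
                    raise FileNotFoundError(f"dataset file not found: {p}")
        for p in (self.gene_sets, self.markers, self.ppi):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.signature is not None and not Path(self.signature).exists():
            raise FileNotFoundError(f"signature file not found: {self.signature}")
        if self.de_fdr_max <= 0 or self.de_lfc_min <= 0:
            raise ValueError("DE thresholds must be positive")
        if self.network_min_support > len(self.datasets) + 1:
            raise ValueError(
                f"min_support={self.network_min_support} exceeds "
                f"{len(self.datasets) + 1} evidence channels"
            )
        if self.gsea_n_perm < 100:
            raise ValueError("gsea n_perm must be >= 100")

    def canonical_dict(self) -> dict:
        return {
            "datasets": [
                {"id": d.id, "expression": str(d.expression), "metadata": str(d.metadata)}
                for d in self.datasets
            ],
            "gene_sets": str(self.gene_sets),
            "markers": str(self.markers),
            "ppi": str(self.ppi),
            "signature": None if self.signature is None else str(self.signature),
            "seed": self.seed,
            "gsea": {
                "weight": self.gsea_weight,
                "n_perm": self.gsea_n_perm,
                "scheme": self.gsea_scheme,
            },
            "pooling": {
                "min_datasets": self.pool_min_datasets,
                "direction": self.pool_direction,
                "fdr_max": self.pool_fdr_max,
            },
            "ssgsea": {"alpha": self.ssgsea_alpha, "normalize": self.ssgsea_normalize},
            "de": {"fdr_max": self.de_fdr_max, "lfc_min": self.de_lfc_min},
            "network": {
                "min_support": self.network_min_support,
                "sign_consistency": self.network_sign_consistency,
                "ppi_min_score": self.ppi_min_score,
            },
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path, output_dir=None, seed: Optional[int] = None) -> PipelineConfig:
    """Load a YAML pipeline config; relative paths resolve against the file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    datasets = [
        DatasetPaths(id=str(d["id"]), expression=resolve(d["expression"]),
                     metadata=resolve(d["metadata"]))
        for d in raw["datasets"]
    ]
    g = raw.get("gsea", {})
    pool = raw.get("pooling", {})
    ss = raw.get("ssgsea", {})
    de = raw.get("de", {})
    net = raw.get("network", {})
    cfg = PipelineConfig(
        datasets=datasets,
        gene_sets=resolve(raw["gene_sets"]),
        markers=resolve(raw["markers"]),
        ppi=resolve(raw["ppi"]),
        signature=resolve(raw["signature"]) if raw.get("signature") else None,
        output_dir=Path(output_dir) if output_dir else resolve(raw.get("output_dir", "results")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        gsea_weight=float(g.get("weight", 1.0)),
        gsea_n_perm=int(g.get("n_perm", 500)),
        gsea_scheme=str(g.get("scheme", "gene")),
        pool_min_datasets=int(pool.get("min_datasets", 2)),
        pool_direction=str(pool.get("direction", "down")),
        pool_fdr_max=(None if pool.get("fdr_max", 0.05) is None
                      else float(pool.get("fdr_max", 0.05))),
        ssgsea_alpha=float(ss.get("alpha", 0.25)),
        ssgsea_normalize=bool(ss.get("normalize", False)),
        de_fdr_max=float(de.get("fdr_max", 0.05)),
        de_lfc_min=float(de.get("lfc_min", 0.5)),
        network_min_support=int(net.get("min_support", 4)),
        network_sign_consistency=bool(net.get("sign_consistency", True)),
        ppi_min_score=float(net.get("ppi_min_score", 0.7)),
    )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _combine_datasets(datasets: List[ExpressionDataset]) -> ExpressionDataset:
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    genes = [g for g in datasets[0].genes if g in common]
    values = pd.concat([ds.values.loc[genes] for ds in datasets], axis=1)
    meta = pd.concat([ds.metadata for ds in datasets], axis=0)
    return ExpressionDataset(dataset_id="combined", values=values, metadata=meta)


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage, writing outputs + manifest to config.output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("glycoindex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest_stages = []
    results: Dict[str, object] = {}
    current_stage = "setup"

    def record(stage: str, outputs: Dict[str, Path]) -> None:
        manifest_stages.append(
            {"name": stage, "outputs": {p.name: _sha256(p) for p in outputs.values()}}
        )

    try:
        datasets = [
            read_expression_dataset(d.expression, d.metadata, d.id)
            for d in config.datasets
        ]
        glyco_sets = parse_gmt(config.gene_sets)
        marker_sets = parse_gmt(config.markers)
        ppi = read_ppi_table(config.ppi, min_score=config.ppi_min_score)

        # --- stage 1: GSEA per dataset -----------------------------------
        current_stage = "gsea"
        t0 = time.perf_counter()
        all_results: List[gsea.GseaResult] = []
        for ds in datasets:
            all_results.extend(
                gsea.run_gsea_collection(
                    ds, glyco_sets, weight=config.gsea_weight,
                    n_perm=config.gsea_n_perm, seed=config.seed,
                    scheme=config.gsea_scheme,
                )
            )
        gsea_path = out / "gsea_results.tsv"
        gsea.gsea_results_to_frame(all_results).to_csv(gsea_path, sep="\t", index=False)
        record("gsea", {"results": gsea_path})
        logger.info("stage gsea done in %.2fs", time.perf_counter() - t0)
        results["gsea"] = all_results

        # --- stage 2: pool core genes ------------------------------------
        current_stage = "pool"
        t0 = time.perf_counter()
        core = index_mod.pool_core_genes(
            all_results,
            min_datasets=config.pool_min_datasets,
            require_direction=config.pool_direction,
            fdr_max=config.pool_fdr_max,
        )
        if len(core) == 0:
            raise RuntimeError("no core genes pooled; check GSEA results/filters")
        core_gmt = out / "core_genes.gmt"
        write_gmt(GeneSetCollection(sets={"core_glycolysis": core.genes},
                                    source="pipeline"), core_gmt)
        support_path = out / "core_support.tsv"
        core.support_frame().to_csv(support_path, sep="\t", index=False)
        record("pool", {"gmt": core_gmt, "support": support_path})
        logger.info("stage pool done in %.2fs (%d core genes)",
                    time.perf_counter() - t0, len(core))
        results["core"] = core

        # --- stage 3: glycolysis index + median split --------------------
        current_stage = "index"
        t0 = time.perf_counter()
        frames = []
        for ds in datasets:
            sv = index_mod.glycolysis_index(ds, core, alpha=config.ssgsea_alpha,
                                            normalize=config.ssgsea_normalize)
            labels = index_mod.median_split_by_region(sv, ds.metadata)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sv.sample_ids,
                        "dataset_id": ds.dataset_id,
                        "region": ds.metadata["region"].values,
                        "group": ds.metadata["group"].values,
                        "index": sv.scores,
                        "split_label": labels.values,
                    }
                )
            )
        index_table = pd.concat(frames, ignore_index=True)
        index_path = out / "glycolysis_index.tsv"
        index_table.to_csv(index_path, sep="\t", index=False)
        record("index", {"index": index_path})
        logger.info("stage index done in %.2fs", time.perf_counter() - t0)
        results["index"] = index_table

        combined = _combine_datasets(datasets)

        # --- stage 4: DE case vs control ---------------------------------
        current_stage = "de_case_vs_control"
        t0 = time.perf_counter()
        design = diffexpr.build_design(combined.metadata, contrast="case_vs_control")
        table_cc = diffexpr.moderate_ebayes(diffexpr.fit_linear_models(combined, design))
        de_cc_path = out / "de_case_vs_control.tsv"
        table_cc.to_csv(de_cc_path, sep="\t")
        degs_cc = diffexpr.select_degs(table_cc, config.de_fdr_max, config.de_lfc_min)
        degs_cc_path = out / "degs_case_vs_control.txt"
        degs_cc_path.write_text("\n".join(degs_cc) + ("\n" if degs_cc else ""))
        record("de_case_vs_control", {"table": de_cc_path, "degs": degs_cc_path})
        logger.info("stage de_case_vs_control done in %.2fs (%d DEGs)",
                    time.perf_counter() - t0, len(degs_cc))

        # --- stage 5: DE high vs low index within cases ------------------
        current_stage = "de_high_vs_low_index"
        t0 = time.perf_counter()
        case_ids = list(combined.metadata.index[combined.metadata["group"] == "case"])
        cases = combined.subset_samples(case_ids)
        case_scores = index_table.set_index("sample_id").loc[case_ids, "index"]
        sv_cases = index_mod.SampleScoreVector(
            sample_ids=case_ids, scores=case_scores.values,
            score_name="glycolysis_index", alpha=config.ssgsea_alpha,
            normalized=config.ssgsea_normalize,
        )
        split = index_mod.median_split_by_region(sv_cases, cases.metadata)
        design_hl = diffexpr.build_design(cases.metadata, contrast="high_vs_low_index",
                                          split_labels=split)
        table_hl = diffexpr.moderate_ebayes(diffexpr.fit_linear_models(cases, design_hl))
        de_hl_path = out / "de_high_vs_low_index.tsv"
        table_hl.to_csv(de_hl_path, sep="\t")
        degs_hl = diffexpr.select_degs(table_hl, config.de_fdr_max, config.de_lfc_min)
        degs_hl_path = out / "degs_high_vs_low_index.txt"
        degs_hl_path.write_text("\n".join(degs_hl) + ("\n" if degs_hl else ""))
        record("de_high_vs_low_index", {"table": de_hl_path, "degs": degs_hl_path})
        logger.info("stage de_high_vs_low_index done in %.2fs (%d DEGs)",
                    time.perf_counter() - t0, len(degs_hl))

        # --- stage 6: DEG overlap + ORA ----------------------------------
        current_stage = "ora"
        t0 = time.perf_counter()
        overlap = diffexpr.overlap_genes(degs_cc, degs_hl)
        overlap_path = out / "degs_overlap.txt"
        overlap_path.write_text("\n".join(overlap) + ("\n" if overlap else ""))
        background = combined.genes  # genes measured in every dataset
        annotation = glyco_sets.merged_with(marker_sets)
        ora_path = out / "ora_results.tsv"
        if overlap:
            ora_table = ora.ora_enrich(overlap, annotation, background)
        else:
            logger.warning("no overlapping DEGs; writing empty ORA table")
            ora_table = pd.DataFrame(
                columns=["term", "k", "K", "n", "N", "p_value", "fdr", "hit_genes"]
            )
        ora_table.to_csv(ora_path, sep="\t", index=False)
        record("ora", {"overlap": overlap_path, "results": ora_path})
        logger.info("stage ora done in %.2fs", time.perf_counter() - t0)
        results["overlap"] = overlap

        # --- stage 7: microenvironment -----------------------------------
        current_stage = "microenv"
        t0 = time.perf_counter()
        score_frames, assoc_rows, abundance_frames = [], [], []
        idx_by_sample = index_table.set_index("sample_id")["index"]
        sig = (read_signature_matrix(config.signature)
               if config.signature is not None else None)
        for ds in datasets:
            scores = microenv.score_markers(ds, marker_sets, alpha=config.ssgsea_alpha)
            long = scores.reset_index(names="sample_id").melt(
                id_vars="sample_id", var_name="cell_type", value_name="marker_es"
            )
            long.insert(0, "dataset_id", ds.dataset_id)
            score_frames.append(long)
            labels = ds.metadata["group"].values
            ds_index = idx_by_sample.loc[list(ds.samples)].values
            for ct in scores.columns:
                grp = microenv.compare_groups(scores[ct].values, labels)
                sp = microenv.spearman_assoc(scores[ct].values, ds_index)
                assoc_rows.append(
                    (ds.dataset_id, ct, "marker_es", grp.statistic, grp.p_value,
                     grp.directed_log_p, sp.rho, sp.p_value)
                )
            if sig is not None:
                ab = microenv.nnls_deconvolve(ds, sig, mode="relative")
                ab_long = ab.reset_index(names="sample_id").melt(
                    id_vars="sample_id", var_name="cell_type", value_name="abundance"
                )
                ab_long.insert(0, "dataset_id", ds.dataset_id)
                abundance_frames.append(ab_long)
                for ct in ab.columns:
                    grp = microenv.compare_groups(ab[ct].values, labels)
                    try:
                        sp = microenv.spearman_assoc(ab[ct].values, ds_index)
                        rho, sp_p = sp.rho, sp.p_value
                    except ValueError:
                        rho, sp_p = np.nan, np.nan
                    assoc_rows.append(
                        (ds.dataset_id, ct, "deconvolution", grp.statistic,
                         grp.p_value, grp.directed_log_p, rho, sp_p)
                    )
        scores_path = out / "marker_scores.tsv"
        pd.concat(score_frames, ignore_index=True).to_csv(scores_path, sep="\t", index=False)
        assoc_path = out / "microenv_assoc.tsv"
        pd.DataFrame(
            assoc_rows,
            columns=["dataset_id", "cell_type", "estimate", "statistic", "p_value",
                     "directed_log_p", "rho_index", "rho_p_value"],
        ).to_csv(assoc_path, sep="\t", index=False)
        micro_outputs = {"scores": scores_path, "assoc": assoc_path}
        if abundance_frames:
            abundance_path = out / "abundance.tsv"
            pd.concat(abundance_frames, ignore_index=True).to_csv(
                abundance_path, sep="\t", index=False
            )
            micro_outputs["abundance"] = abundance_path
        record("microenv", micro_outputs)
        logger.info("stage microenv done in %.2fs", time.perf_counter() - t0)

        # --- stage 8: consensus network -----------------------------------
        current_stage = "network"
        t0 = time.perf_counter()
        glyco_genes = sorted({g for _, genes in glyco_sets for g in genes})
        marker_genes = sorted({g for _, genes in marker_sets for g in genes})
        tables = {
            ds.dataset_id: network_mod.coexpr_per_dataset(ds, glyco_genes, marker_genes)
            for ds in datasets
        }
        roles = {g: "glycolysis" for g in glyco_genes}
        for ct, genes in marker_sets:
            for g in genes:
                roles[g] = f"marker:{ct}"
        net = network_mod.consensus_network(
            tables, ppi,
            min_support=config.network_min_support,
            require_sign_consistency=config.network_sign_consistency,
            roles=roles,
        )
        net_tsv = out / "network.tsv"
        write_network(net, net_tsv, format="tsv")
        net_sif = out / "network.sif"
        write_network(net, net_sif, format="sif")
        record("network", {"tsv": net_tsv, "sif": net_sif})
        logger.info("stage network done in %.2fs (%d edges)",
                    time.perf_counter() - t0, len(net))
        results["network"] = net
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current_stage}\nerror: {exc}\n")
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage '{current_stage}': {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_stages": len(manifest_stages),
        "stages": manifest_stages,
    }
    manifest_path = out / "manifest.json"
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    root.removeHandler(handler)
    handler.close()
    return results
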