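"""Domain types and file formats.

All pipeline stages consume the containers defined here: log2-scale
expression matrices bound to sample metadata, named gene-set collections
(GMT), protein-protein interaction tables and deconvolution signature
matrices. Everything is plain TSV/GMT so datasets can be inspected and
diffed with standard tools.

Scale contract: expression values are assumed to be log2-scale. The
rank-based scorers (GSEA/ssGSEA/Spearman co-expression) are scale-agnostic;
the differential-expression module interprets coefficients as log2 fold
changes; deconvolution de-logs with ``2**x - 1``. The scale is documented,
not auto-detected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

VALID_GROUPS = ("control", "case")
VALID_SEXES = ("F", "M")

METADATA_COLUMNS = ("group", "region", "age", "sex")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample; ``metadata`` is indexed by sample id with columns
    group/region/age/sex and aligns 1:1 with the matrix columns.
    """

    dataset_id: str
    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene symbols: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids in expression matrix")
        if list(self.values.columns) != list(self.metadata.index):
            missing = set(self.values.columns).symmetric_difference(self.metadata.index)
            raise FormatError(
                f"expression samples and metadata rows do not align: {sorted(missing)}"
            )
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][:5]
            raise FormatError(f"missing expression values (e.g. genes {list(bad)}); "
                              "imputation is not performed")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise FormatError(f"metadata lacks required column '{col}'")
        bad_group = set(self.metadata["group"]) - set(VALID_GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels {sorted(bad_group)}; "
                              f"expected {VALID_GROUPS}")
        bad_sex = set(self.metadata["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex labels {sorted(bad_sex)}; expected {VALID_SEXES}")
        ages = pd.to_numeric(self.metadata["age"], errors="coerce")
        if ages.isna().any() or (ages < 0).any():
            raise FormatError("ages must be non-negative numbers")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            values=self.values.loc[:, ids].copy(),
            metadata=self.metadata.loc[ids].copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the seven glycolysis pathway sets, marker sets)."""

    sets: Dict[str, List[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set '{name}' is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set '{name}' contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def merged_with(self, other: "GeneSetCollection") -> "GeneSetCollection":
        overlap = set(self.sets) & set(other.sets)
        if overlap:
            raise FormatError(f"duplicate set names when merging: {sorted(overlap)}")
        merged = dict(self.sets)
        merged.update(other.sets)
        return GeneSetCollection(sets=merged, source=f"{self.source}+{other.source}")


@dataclass
class PpiTable:
    """Undirected protein-protein interactions with confidence scores in [0, 1].

    STRING-style integer scores (0-999) should be rescaled by the caller:
    a score of 700 corresponds to 0.7 here.
    """

    edges: List[Tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a, b, s in self.edges:
            if a == b:
                raise FormatError(f"self-loop edge {a}-{b}")
            if not (0.0 <= s <= 1.0):
                raise FormatError(f"PPI score {s} for {a}-{b} outside [0, 1]")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise FormatError(f"duplicate unordered pair {key}")
            seen.add(key)
        self._pairs = seen

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self._pairs

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SignatureMatrix:
    """Linear-scale reference expression (genes x cell types) for deconvolution."""

    values: pd.DataFrame  # genes x cell_types

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate genes in signature matrix")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate cell types in signature matrix")
        if (self.values.values < 0).any():
            raise FormatError("signature matrix must be non-negative (linear scale)")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# GMT


def parse_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (MSigDB dialect: name, description, genes...).

    Duplicate genes within a line are deduplicated preserving first
    occurrence; the description field is discarded. Lines with fewer than
    three fields or duplicate set names are errors.
    """
    path = Path(path)
    sets: Dict[str, List[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} "
                                  "fields, expected at least 3")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name '{name}'")
            genes: List[str] = []
            seen = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set '{name}' has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression


def read_expression_dataset(expr_path, meta_path, dataset_id: str) -> ExpressionDataset:
    """Load an expression TSV (genes x samples) plus its metadata TSV.

    Samples are aligned by id; duplicate gene symbols are collapsed by
    per-row median. Missing or non-numeric expression cells and
    matrix/metadata sample mismatches are errors.
    """
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"{expr_path}: non-numeric expression cell ({exc})") from exc
    if values.isna().any().any():
        raise FormatError(f"{expr_path}: missing expression values are not allowed")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = ("sample_id", *METADATA_COLUMNS)
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"{meta_path}: missing metadata columns {missing_cols}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise FormatError(f"{meta_path}: duplicate sample ids")

    matrix_samples = set(values.columns)
    meta_samples = set(meta.index)
    only_matrix = sorted(matrix_samples - meta_samples)
    only_meta = sorted(meta_samples - matrix_samples)
    if only_matrix or only_meta:
        raise FormatError(
            f"sample alignment error: in matrix only {only_matrix}, "
            f"in metadata only {only_meta}"
        )
    meta = meta.loc[list(values.columns)]

    if values.index.duplicated().any():
        # collapse duplicated gene symbols by per-row median, preserving
        # first-occurrence order of symbols
        order = values.index.drop_duplicates()
        values = values.groupby(level=0, sort=False).median().loc[order]

    return ExpressionDataset(dataset_id=dataset_id, values=values, metadata=meta)


def write_expression_dataset(ds: ExpressionDataset, expr_path, meta_path) -> None:
    ds.values.to_csv(expr_path, sep="\t", index_label="gene")
    ds.metadata.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# PPI


def read_ppi_table(path, min_score: float = 0.7) -> PpiTable:
    """Read a PPI edge TSV (gene_a, gene_b, score), keeping score > min_score.

    Unordered duplicate pairs are collapsed to their maximum score before
    filtering; the retention inequality is strict.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValueError("min_score must lie in [0, 1]")
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: PPI table lacks column '{col}'")
    best: Dict[Tuple[str, str], float] = {}
    for a, b, s in df[["gene_a", "gene_b", "score"]].itertuples(index=False):
        s = float(s)
        if not (0.0 <= s <= 1.0):
            raise FormatError(f"PPI score {s} for {a}-{b} outside [0, 1]")
        if a == b:
            raise FormatError(f"self-loop edge {a}-{b}")
        key = (a, b) if a <= b else (b, a)
        if key not in best or s > best[key]:
            best[key] = s
    edges = [(a, b, s) for (a, b), s in sorted(best.items()) if s > min_score]
    return PpiTable(edges=edges)


# ---------------------------------------------------------------------------
# Signature matrix


def read_signature_matrix(path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(values=df.astype(float))


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    sig.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Network export

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(net, path, format: str = "tsv") -> None:
    """Export a consensus network as SIF, GraphML or TSV.

    SIF uses the interaction label "pos"/"neg" by edge sign. The TSV
    includes roles, sign, support count and per-evidence flags, and
    round-trips exactly through :func:`read_network_tsv`.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format '{format}'; expected {NETWORK_FORMATS}")
    if format == "sif":
        with path.open("w") as fh:
            for e in net.edges:
                label = "pos" if e.sign == "+" else "neg"
                fh.write(f"{e.gene_a}\t{label}\t{e.gene_b}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for gene, role in sorted(net.nodes.items()):
            g.add_node(gene, role=role)
        for e in net.edges:
            g.add_edge(e.gene_a, e.gene_b, sign=e.sign, support_count=e.support_count)
        nx.write_graphml(g, path)
    else:
        evidence_keys = net.evidence_keys()
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["gene_a", "role_a", "gene_b", "role_b", "sign", "support_count"]
                + [f"ev_{k}" for k in evidence_keys]
            )
            for e in net.edges:
                writer.writerow(
                    [
                        e.gene_a,
                        net.nodes.get(e.gene_a, ""),
                        e.gene_b,
                        net.nodes.get(e.gene_b, ""),
                        e.sign,
                        e.support_count,
                    ]
                    + [int(e.evidence[k]) for k in evidence_keys]
                )


def read_network_tsv(path):
    """Read a consensus network written by :func:`write_network` (tsv format)."""
    from .network import ConsensusEdge, ConsensusNetwork

    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    ev_cols = [c for c in df.columns if c.startswith("ev_")]
    nodes: Dict[str, str] = {}
    edges = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for gene_col, role_col in (("gene_a", "role_a"), ("gene_b", "role_b")):
            role = d.get(role_col, "")
            nodes[d[gene_col]] = "" if pd.isna(role) else str(role)
        evidence = {c[3:]: bool(d[c]) for c in ev_cols}
        edges.append(
            ConsensusEdge(
                gene_a=d["gene_a"],
                gene_b=d["gene_b"],
                sign=d["sign"],
                support_count=int(d["support_count"]),
                evidence=evidence,
            )
        )
    return ConsensusNetwork(nodes=nodes, edges=edges)
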