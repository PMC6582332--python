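"""Readers, writers and load-time filters for all external formats.

Expression input is a delimited text table with genes in rows (first column)
and samples in columns (first row).  At load time, genes with zero expression
in every sample and samples containing any missing value are dropped, and a
load report is logged.  Bicluster collections are emitted as tab-separated
long-format tables plus one GraphML file per bicluster (shared samples
serialised as a semicolon-joined edge attribute, for Cytoscape-style
viewers) and a JSON run manifest embedding the configuration.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import BiclusterCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_locus_table",
    "read_cna_matrix",
    "read_sample_labels",
    "write_expression",
    "write_bicluster_collection",
    "read_bicluster_membership",
    "load_membership_biclusters",
]

_PVAL_FMT = "%.5e"  # 6 significant digits, scientific notation


def _infer_delimiter(path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_duplicates(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()].astype(str)))
        raise ValueError(f"duplicate {what} identifiers: {', '.join(dups[:10])}")


def read_expression(
    path,
    delimiter: str | None = None,
    transpose: bool = False,
    drop_all_zero_genes: bool = True,
    drop_na_samples: bool = True,
) -> pd.DataFrame:
    """Load a gene x sample expression matrix and apply the load-time filters.

    Genes that are zero across all samples are removed, as are samples with a
    missing value for any gene.  Duplicate identifiers and non-numeric cells
    are hard errors.
    """
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "NaN", ""])
    if transpose:
        raw = raw.T
    _check_duplicates(raw.index, "gene")
    _check_duplicates(raw.columns, "sample")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[raw[col].apply(lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number))))]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric cell at gene {gene!r}, sample {col!r}")
    mat = raw.astype(float)
    n_genes0, n_samples0 = mat.shape
    if drop_na_samples:
        keep = ~mat.isna().any(axis=0)
        mat = mat.loc[:, keep]
    if drop_all_zero_genes:
        mat = mat.loc[~(mat == 0).all(axis=1)]
    logger.info(
        "loaded %s: %d genes x %d samples (dropped %d all-zero genes, %d samples with NAs)",
        path, mat.shape[0], mat.shape[1], n_genes0 - mat.shape[0], n_samples0 - mat.shape[1],
    )
    return mat


def write_expression(matrix: pd.DataFrame, path, delimiter: str | None = None) -> None:
    matrix.to_csv(
        path,
        sep=_infer_delimiter(path, delimiter),
        index_label=matrix.index.name or "gene_id",
    )


def read_locus_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Gene locus table: gene_id, chromosome, start, end (1-based, inclusive)."""
    loci = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(loci.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    _check_duplicates(pd.Index(loci["gene_id"]), "gene")
    if (loci["start"] > loci["end"]).any():
        bad = loci.loc[loci["start"] > loci["end"], "gene_id"].tolist()
        raise ValueError(f"start > end for genes: {bad[:10]}")
    return loci


def read_cna_matrix(path, delimiter: str | None = None) -> pd.DataFrame:
    """GISTIC2-style gene x sample integer copy-number call matrix."""
    cna = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), index_col=0)
    _check_duplicates(cna.index, "gene")
    _check_duplicates(cna.columns, "sample")
    vals = cna.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("copy-number calls must be integer-valued")
    return cna.astype(int)


def read_sample_labels(path, delimiter: str | None = None, sample_id_column: str = "sample_id") -> pd.DataFrame:
    labels = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    if sample_id_column not in labels.columns:
        raise ValueError(f"label table missing column {sample_id_column!r}")
    _check_duplicates(pd.Index(labels[sample_id_column]), "sample")
    return labels


def _fmt_p(p) -> str:
    return _PVAL_FMT % p


def write_bicluster_collection(collection: BiclusterCollection, out_dir) -> dict:
    """Emit a collection: gene/sample tables, summary, GraphML, manifest.

    Files (tab-separated, headers, p-values in 6-significant-digit scientific
    notation): biclusters_genes.tsv, biclusters_samples.tsv,
    biclusters_summary.tsv, bicluster_<id>.graphml per bicluster, and
    manifest.json embedding the run configuration.  Output is byte-stable for
    a fixed collection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise PermissionError(f"output directory {out} is not writable")

    gene_rows, sample_rows, summary_rows = [], [], []
    for b in sorted(collection, key=lambda b: b.bicluster_id):
        degrees = b.degrees
        gfdr = (
            b.gene_scores.set_index("gene") if b.gene_scores is not None else None
        )
        for g in sorted(b.genes):
            gene_rows.append(
                {
                    "bicluster_id": b.bicluster_id,
                    "gene": g,
                    "degree": degrees.get(g, 0),
                    "is_seed": int(g in b.seed.genes),
                    "p_raw": _fmt_p(gfdr.loc[g, "p_raw"]) if gfdr is not None and g in gfdr.index else "",
                    "fdr": _fmt_p(gfdr.loc[g, "fdr"]) if gfdr is not None and g in gfdr.index else "",
                }
            )
        sfdr = (
            b.sample_scores.set_index("sample") if b.sample_scores is not None else None
        )
        for s in sorted(b.samples):
            sample_rows.append(
                {
                    "bicluster_id": b.bicluster_id,
                    "sample": s,
                    "p_raw": _fmt_p(sfdr.loc[s, "p_raw"]) if sfdr is not None and s in sfdr.index else "",
                    "fdr": _fmt_p(sfdr.loc[s, "fdr"]) if sfdr is not None and s in sfdr.index else "",
                }
            )
        summary_rows.append(
            {
                "bicluster_id": b.bicluster_id,
                "n_genes": b.n_genes,
                "n_samples": b.n_samples,
                "seed_size": len(b.seed.genes),
                "Q": "" if b.quality is None else f"{b.quality:.6f}",
            }
        )

    gene_cols = ["bicluster_id", "gene", "degree", "is_seed", "p_raw", "fdr"]
    sample_cols = ["bicluster_id", "sample", "p_raw", "fdr"]
    summary_cols = ["bicluster_id", "n_genes", "n_samples", "seed_size", "Q"]
    paths = {
        "genes": out / "biclusters_genes.tsv",
        "samples": out / "biclusters_samples.tsv",
        "summary": out / "biclusters_summary.tsv",
        "manifest": out / "manifest.json",
    }
    pd.DataFrame(gene_rows, columns=gene_cols).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame(sample_rows, columns=sample_cols).to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame(summary_rows, columns=summary_cols).to_csv(paths["summary"], sep="\t", index=False)

    graphml_paths = []
    for b in sorted(collection, key=lambda b: b.bicluster_id):
        g = nx.Graph()
        for node in sorted(b.graph.nodes):
            g.add_node(node, degree=int(b.graph.degree(node)), is_seed=int(node in b.seed.genes))
        for u, v, d in sorted(b.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            attrs = {"shared_samples": ";".join(sorted(d.get("shared_samples", ())))}
            if "m" in d:
                attrs["m"] = int(d["m"])
            if "p_raw" in d:
                attrs["p_raw"] = _fmt_p(d["p_raw"])
            if "p_adjusted" in d:
                attrs["p_adjusted"] = _fmt_p(d["p_adjusted"])
            g.add_edge(u, v, **attrs)
        p = out / f"bicluster_{b.bicluster_id:04d}.graphml"
        nx.write_graphml(g, p)
        graphml_paths.append(str(p))

    manifest = {
        "n_biclusters": len(collection),
        "config": collection.config.to_dict() if collection.config else None,
        "files": {k: str(v) for k, v in paths.items() if k != "manifest"},
        "graphml": graphml_paths,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {**{k: str(v) for k, v in paths.items()}, "graphml": graphml_paths}


class _MembershipBicluster:
    """Lightweight stand-in for a Bicluster reloaded from output tables."""

    def __init__(self, bicluster_id: int, genes: frozenset, samples: frozenset):
        self.bicluster_id = bicluster_id
        self.genes = genes
        self.samples = samples


def load_membership_biclusters(out_dir) -> list[_MembershipBicluster]:
    """Reload a written collection as membership-only bicluster records."""
    gene_sets, sample_sets = read_bicluster_membership(out_dir)
    return [
        _MembershipBicluster(bid, gene_sets[bid], sample_sets.get(bid, frozenset()))
        for bid in sorted(gene_sets)
    ]


def read_bicluster_membership(out_dir) -> tuple[dict[int, frozenset], dict[int, frozenset]]:
    """Reconstruct per-bicluster gene and sample sets from an output directory."""
    out = Path(out_dir)
    genes = pd.read_csv(out / "biclusters_genes.tsv", sep="\t")
    samples = pd.read_csv(out / "biclusters_samples.tsv", sep="\t")
    gene_sets = {
        int(bid): frozenset(sub["gene"]) for bid, sub in genes.groupby("bicluster_id")
    }
    sample_sets = {
        int(bid): frozenset(sub["sample"]) for bid, sub in samples.groupby("bicluster_id")
    }
    return gene_sets, sample_sets
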