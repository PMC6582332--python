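"""Downstream analyses on bicluster collections.

Covers: matching biclusters between two runs or cohorts by gene-set overlap;
categorical (subtype / grade / node status) enrichment of bicluster samples;
copy-number enrichment with Fisher's method to combine per-gene p-values;
classification of biclusters whose genes sit close together on one
chromosome; and hierarchical clustering of the binary bicluster x sample
membership matrix under the Hamming distance.

All overlap tests are one-sided Fisher's exact tests (hypergeometric upper
tails); every family is corrected by Benjamini-Hochberg and the family sizes
are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import Bicluster, BiclusterCollection
from .extremal import overlap_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "compare_collections",
    "categorical_enrichment",
    "cna_enrichment",
    "cna_enrichment_collection",
    "classify_proximal",
    "membership_matrix",
    "membership_and_hamming_clustering",
    "ComparisonResult",
    "HammingClustering",
]


@dataclass
class ComparisonResult:
    """Pairwise gene-set matching between two bicluster collections."""

    pairs: pd.DataFrame  # id_a, id_b, overlap, size_a, size_b, p_raw, fdr
    fraction_a_matched: float
    fraction_b_matched: float
    fdr_threshold: float
    family_size: int


def compare_collections(
    coll_a: BiclusterCollection,
    coll_b: BiclusterCollection,
    universe_size: int,
    fdr_threshold: float = 1e-3,
) -> ComparisonResult:
    """Match biclusters across two collections by gene-set overlap.

    Each (A, B) pair gets a hypergeometric upper-tail p for the overlap of
    their gene sets within a shared universe of ``universe_size`` genes; BH
    runs over all pairs.  The match fraction of a collection is the share of
    its biclusters enriched (FDR below threshold) in at least one bicluster
    of the other.
    """
    return _compare_membership(
        coll_a.gene_sets(), coll_b.gene_sets(), universe_size, fdr_threshold
    )


def _compare_membership(
    sets_a: dict, sets_b: dict, universe_size: int, fdr_threshold: float = 1e-3
) -> ComparisonResult:
    rows = []
    for ia, ga in sorted(sets_a.items()):
        for ib, gb in sorted(sets_b.items()):
            m = len(ga & gb)
            rows.append(
                {
                    "id_a": ia,
                    "id_b": ib,
                    "overlap": m,
                    "size_a": len(ga),
                    "size_b": len(gb),
                    "p_raw": overlap_pvalue(m, len(ga), len(gb), universe_size),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["id_a", "id_b", "overlap", "size_a", "size_b", "p_raw"]
    )
    if len(pairs):
        _, adj, _, _ = multipletests(pairs["p_raw"], method="fdr_bh")
        pairs["fdr"] = adj
    else:
        pairs["fdr"] = pd.Series(dtype=float)
    sig = pairs[pairs["fdr"] < fdr_threshold]
    frac_a = sig["id_a"].nunique() / len(sets_a) if sets_a else 0.0
    frac_b = sig["id_b"].nunique() / len(sets_b) if sets_b else 0.0
    logger.info(
        "compare_collections: BH family of %d pairs, FDR<%g", len(pairs), fdr_threshold
    )
    return ComparisonResult(
        pairs=pairs,
        fraction_a_matched=float(frac_a),
        fraction_b_matched=float(frac_b),
        fdr_threshold=fdr_threshold,
        family_size=len(pairs),
    )


def categorical_enrichment(
    collection: BiclusterCollection,
    labels: pd.DataFrame,
    column: str,
    sample_id_column: str = "sample_id",
) -> pd.DataFrame:
    """One-sided Fisher test of each bicluster against each category value.

    The 2x2 table crosses bicluster membership with the category, over the
    labelled cohort; unlabelled bicluster samples are excluded with a logged
    count.  BH runs across all biclusters x categories of the column.
    """
    lab = labels.set_index(sample_id_column)[column].dropna()
    n_labeled = len(lab)
    categories = sorted(lab.unique())
    rows = []
    for b in collection:
        in_b = [s for s in b.samples if s in lab.index]
        dropped = len(b.samples) - len(in_b)
        if dropped:
            logger.info(
                "bicluster %d: %d samples without a %r label excluded",
                b.bicluster_id, dropped, column,
            )
        for cat in categories:
            k_cat = int((lab == cat).sum())
            overlap = sum(1 for s in in_b if lab[s] == cat)
            p = overlap_pvalue(overlap, k_cat, len(in_b), n_labeled) if in_b else 1.0
            rows.append(
                {
                    "bicluster_id": b.bicluster_id,
                    "test_kind": "category",
                    "target": str(cat),
                    "n_bicluster_labeled": len(in_b),
                    "n_category": k_cat,
                    "overlap": overlap,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        _, adj, _, _ = multipletests(out["p_raw"], method="fdr_bh")
        out["fdr"] = adj
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def cna_enrichment(
    bicluster: Bicluster,
    cna: pd.DataFrame,
    direction: str = "gain",
    call_threshold: int = 1,
) -> tuple[pd.DataFrame, float, float]:
    """Copy-number enrichment of one bicluster, combined by Fisher's method.

    Per gene g present in the copy-number call matrix: a hypergeometric
    upper-tail p for the count of CNA-positive samples inside the bicluster,
    given the gene's cohort-wide positive count (positive means call >=
    ``call_threshold`` for gains, <= -``call_threshold`` for losses).  The
    per-gene p-values are combined as chi2 = -2 sum(ln p) on 2 * n_genes
    degrees of freedom.

    Returns (per-gene table, chi2 statistic, combined p).
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    n = cna.shape[1]
    in_b = [s for s in cna.columns if s in bicluster.samples]
    rows = []
    for g in sorted(bicluster.genes):
        if g not in cna.index:
            logger.warning("gene %s absent from the CNA matrix; skipped", g)
            continue
        calls = cna.loc[g]
        positive = calls >= call_threshold if direction == "gain" else calls <= -call_threshold
        k_pos = int(positive.sum())
        overlap = int(positive[in_b].sum())
        p = overlap_pvalue(overlap, k_pos, len(in_b), n)
        rows.append({"gene": g, "n_positive_cohort": k_pos, "n_positive_bicluster": overlap, "p_raw": p})
    table = pd.DataFrame(rows, columns=["gene", "n_positive_cohort", "n_positive_bicluster", "p_raw"])
    if not len(table):
        return table, float("nan"), float("nan")
    stat = float(-2.0 * np.sum(np.log(table["p_raw"].to_numpy())))
    combined = float(chi2.sf(stat, df=2 * len(table)))
    return table, stat, combined


def cna_enrichment_collection(
    collection: BiclusterCollection,
    cna: pd.DataFrame,
    direction: str = "gain",
    call_threshold: int = 1,
) -> pd.DataFrame:
    """Fisher's-method combined CNA p per bicluster, BH-adjusted across biclusters."""
    rows = []
    for b in collection:
        table, stat, combined = cna_enrichment(b, cna, direction, call_threshold)
        if not len(table):
            continue
        rows.append(
            {
                "bicluster_id": b.bicluster_id,
                "test_kind": f"cna_{direction}",
                "target": "combined",
                "n_genes_tested": len(table),
                "chi2": stat,
                "p_raw": combined,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, adj, _, _ = multipletests(out["p_raw"], method="fdr_bh")
        out["fdr"] = adj
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def classify_proximal(
    bicluster: Bicluster,
    loci: pd.DataFrame,
    min_fraction: float = 0.8,
    max_span_bp: int = 25_000_000,
) -> dict:
    """Classify a bicluster's genes as chromosomally proximal or distributed.

    ``loci`` needs columns gene_id, chromosome, start, end (1-based,
    inclusive).  The bicluster is *proximal* when at least ``min_fraction``
    of its annotated genes fit on one chromosome within a window of at most
    ``max_span_bp``; *unannotated* when no gene has a locus.  Both knobs are
    heuristics for what is otherwise a visual cytoband judgement and are
    echoed in the result.
    """
    ann = loci[loci["gene_id"].isin(bicluster.genes)]
    result = {
        "bicluster_id": bicluster.bicluster_id,
        "n_genes": len(bicluster.genes),
        "n_annotated": len(ann),
        "min_fraction": min_fraction,
        "max_span_bp": max_span_bp,
    }
    if not len(ann):
        result.update(classification="unannotated", best_chromosome=None, best_window_count=0)
        return result
    best_count, best_chrom = 0, None
    for chrom, sub in ann.groupby("chromosome"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # largest run (by start order) with max(end) - min(start) <= span
        for i in range(len(sub)):
            max_end = ends[i]
            for j in range(i, len(sub)):
                max_end = max(max_end, ends[j])
                if max_end - starts[i] > max_span_bp:
                    break
                if j - i + 1 > best_count:
                    best_count, best_chrom = j - i + 1, chrom
    proximal = best_count >= min_fraction * len(ann)
    result.update(
        classification="proximal" if proximal else "distributed",
        best_chromosome=best_chrom,
        best_window_count=int(best_count),
    )
    return result


@dataclass
class HammingClustering:
    matrix: pd.DataFrame
    distances: pd.DataFrame
    linkage: np.ndarray | None
    newick: str | None
    linkage_method: str
    axis: str


def membership_matrix(collection: BiclusterCollection, sample_ids: list) -> pd.DataFrame:
    """Binary biclusters x samples matrix: 1 iff the sample is in the bicluster."""
    ids = [b.bicluster_id for b in collection]
    mat = pd.DataFrame(0, index=pd.Index(ids, name="bicluster_id"), columns=list(sample_ids), dtype=int)
    for b in collection:
        cols = [s for s in b.samples if s in mat.columns]
        mat.loc[b.bicluster_id, cols] = 1
    return mat


def membership_and_hamming_clustering(
    collection: BiclusterCollection,
    sample_ids: list,
    axis: str = "biclusters",
    linkage_method: str = "average",
) -> HammingClustering:
    """Agglomerative clustering of the membership matrix under Hamming distance.

    Distances are Hamming *counts* (number of differing positions).  With a
    single row on the chosen axis, only the matrix and distances are
    returned (no tree).
    """
    if axis not in ("biclusters", "samples"):
        raise ValueError(f"axis must be 'biclusters' or 'samples', got {axis!r}")
    mat = membership_matrix(collection, sample_ids)
    data = mat if axis == "biclusters" else mat.T
    labels = [str(i) for i in data.index]
    n = len(data)
    if n == 0:
        raise ValueError("empty membership matrix")
    if n == 1:
        dist = pd.DataFrame([[0.0]], index=labels, columns=labels)
        return HammingClustering(mat, dist, None, None, linkage_method, axis)
    condensed = pdist(data.to_numpy(), metric="hamming") * data.shape[1]
    dist = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    lk = scipy_linkage(condensed, method=linkage_method)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(lk, labels)
    newick = str(tree).strip()
    return HammingClustering(mat, dist, lk, newick, linkage_method, axis)
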