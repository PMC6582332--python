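"""Enrichment scoring of bicluster genes and samples, and the quality Q.

A bicluster of |S_B| = m samples should be enriched in the top-m (bottom-m
for the low direction) samples of each of its genes, and each of its samples
should sit in the top-m sets of an improbably large share of its genes.  Both
checks are hypergeometric upper-tail tests; their BH-adjusted p-values act as
per-gene and per-sample scores, and the quality

    Q(B) = min( frac. genes with FDR < t, frac. samples with FDR < t )

summarises the bicluster at threshold t (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import Bicluster, BiclusterCollection
from .extremal import _extremal_order, overlap_pvalue

__all__ = [
    "score_genes",
    "score_samples",
    "score_collection",
    "quality",
    "rank_genes_by_degree",
]


def _top_m_membership(matrix: pd.DataFrame, m: int, direction: str) -> np.ndarray:
    """Boolean (genes x samples): is the sample in the gene's top-m set?"""
    values = matrix.to_numpy(dtype=float)
    member = np.zeros(matrix.shape, dtype=bool)
    for i in range(matrix.shape[0]):
        member[i, _extremal_order(values[i], direction)[:m]] = True
    return member


def score_genes(
    bicluster: Bicluster, matrix: pd.DataFrame, direction: str = "high"
) -> pd.Series:
    """Raw enrichment p-value of each bicluster gene.

    For gene g, with m = |S_B|: p = P(X >= |top_m(g) & S_B|) for a
    hypergeometric X with population N, m successes and m draws.
    """
    m = len(bicluster.samples)
    if m < 1:
        raise ValueError("bicluster has no samples")
    n = matrix.shape[1]
    genes = sorted(bicluster.genes)
    sub = matrix.loc[genes]
    member = _top_m_membership(sub, m, direction)
    in_b = np.asarray([s in bicluster.samples for s in matrix.columns])
    overlaps = (member & in_b).sum(axis=1)
    lut = overlap_pvalue(np.arange(m + 1), m, m, n)
    return pd.Series(lut[overlaps], index=genes, name="p_raw")


def score_samples(
    bicluster: Bicluster, matrix: pd.DataFrame, direction: str = "high"
) -> pd.Series:
    """Raw enrichment p-value of each bicluster sample.

    For sample s, G_s is the set of *all* dataset genes whose top-m set
    (m = |S_B|) contains s; p is the hypergeometric upper tail for the
    overlap |G_s & genes(B)| with the full gene list as population,
    |genes(B)| successes and |G_s| draws.
    """
    m = len(bicluster.samples)
    if m < 1:
        raise ValueError("bicluster has no samples")
    n_genes = matrix.shape[0]
    member = _top_m_membership(matrix, m, direction)
    gene_in_b = np.asarray([g in bicluster.genes for g in matrix.index])
    samples = sorted(bicluster.samples)
    col_of = {s: j for j, s in enumerate(matrix.columns)}
    out = {}
    for s in samples:
        col = member[:, col_of[s]]
        draws = int(col.sum())
        if draws == 0:
            out[s] = 1.0
            continue
        obs = int((col & gene_in_b).sum())
        out[s] = overlap_pvalue(obs, int(gene_in_b.sum()), draws, n_genes)
    return pd.Series(out, name="p_raw")


def quality(gene_fdr: pd.Series, sample_fdr: pd.Series, threshold: float = 0.05) -> float:
    """Q(B): minimum of the significant-gene and significant-sample fractions."""
    fg = float((gene_fdr < threshold).mean()) if len(gene_fdr) else 0.0
    fs = float((sample_fdr < threshold).mean()) if len(sample_fdr) else 0.0
    return min(fg, fs)


def rank_genes_by_degree(bicluster: Bicluster, n_flag: int = 5) -> pd.DataFrame:
    """Bicluster genes by descending degree; the top entries are candidate drivers."""
    rows = sorted(bicluster.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    df["candidate_driver"] = np.arange(len(df)) < n_flag
    return df


def score_collection(
    collection: BiclusterCollection,
    matrix: pd.DataFrame,
    direction: str = "high",
    fdr_threshold: float = 0.05,
) -> BiclusterCollection:
    """Attach gene/sample FDR scores and Q to every bicluster, in place.

    BH families pool the (gene, bicluster) pairs of the whole collection, and
    the (sample, bicluster) pairs likewise, so scores are comparable across
    biclusters of one run.
    """
    gene_raw: list[tuple[int, str, float]] = []
    sample_raw: list[tuple[int, str, float]] = []
    for b in collection:
        for g, p in score_genes(b, matrix, direction).items():
            gene_raw.append((b.bicluster_id, g, p))
        for s, p in score_samples(b, matrix, direction).items():
            sample_raw.append((b.bicluster_id, s, p))
    if gene_raw:
        _, g_adj, _, _ = multipletests([r[2] for r in gene_raw], method="fdr_bh")
    else:
        g_adj = []
    if sample_raw:
        _, s_adj, _, _ = multipletests([r[2] for r in sample_raw], method="fdr_bh")
    else:
        s_adj = []
    gtab = pd.DataFrame(gene_raw, columns=["bicluster_id", "gene", "p_raw"])
    gtab["fdr"] = list(g_adj)
    stab = pd.DataFrame(sample_raw, columns=["bicluster_id", "sample", "p_raw"])
    stab["fdr"] = list(s_adj)
    for b in collection:
        bg = gtab[gtab["bicluster_id"] == b.bicluster_id][["gene", "p_raw", "fdr"]]
        bs = stab[stab["bicluster_id"] == b.bicluster_id][["sample", "p_raw", "fdr"]]
        b.gene_scores = bg.reset_index(drop=True)
        b.sample_scores = bs.reset_index(drop=True)
        b.quality = quality(
            bg.set_index("gene")["fdr"], bs.set_index("sample")["fdr"], fdr_threshold
        )
    return collection
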