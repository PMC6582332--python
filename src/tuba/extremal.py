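"""Extremal sample sets, overlap significance, and the co-expression graph.

For every gene the *extremal set* is the top (or bottom) ``x`` percentile of
samples by expression.  Two genes are proximal when their extremal sets share
more samples than expected by chance; the significance of an overlap of ``m``
samples between sets of sizes ``k1`` and ``k2`` drawn from ``N`` samples is
the hypergeometric upper tail P(X >= m), i.e. the one-sided Fisher's exact
test on the 2x2 membership table.  Gene pairs whose overlap passes a
significance cut-off (raw or BH-adjusted) become edges of the co-expression
graph, with the shared samples attached to each edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremalSetCollection",
    "TuningCurve",
    "compute_extremal_sets",
    "overlap_pvalue",
    "build_graph",
    "tuning_curve",
    "suggest_cutoff",
    "permutation_null",
    "extremal_set_size",
]


def extremal_set_size(percentile: float, n_samples: int) -> int:
    """Size k of each extremal set: round-half-up of percentile * N.

    Raises ValueError when the resulting k would be < 2 (sets of one sample
    carry no overlap information).
    """
    if not 0.0 < percentile <= 0.5:
        raise ValueError(f"percentile must lie in (0, 0.5], got {percentile}")
    k = int(np.floor(percentile * n_samples + 0.5))
    if k < 2:
        raise ValueError(
            f"extremal set size k={k} < 2 for percentile={percentile}, "
            f"N={n_samples}; increase the percentile or the cohort size"
        )
    return k


def _extremal_order(values: np.ndarray, direction: str) -> np.ndarray:
    """Sample indices of one gene ordered from most to least extreme.

    Ties are broken by canonical (column) order with a stable sort, so
    membership of heavily tied genes is deterministic.
    """
    if direction == "high":
        key = -values
    elif direction == "low":
        key = values
    else:
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    return np.argsort(key, kind="stable")


@dataclass
class ExtremalSetCollection:
    """Per-gene extremal sample sets at a fixed percentile and direction."""

    direction: str
    percentile: float
    k: int
    gene_ids: list[str]
    sample_ids: list[str]
    membership: np.ndarray  # bool, shape (n_genes, n_samples)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def sets(self) -> dict[str, frozenset[str]]:
        samples = np.asarray(self.sample_ids, dtype=object)
        return {
            g: frozenset(samples[self.membership[i]])
            for i, g in enumerate(self.gene_ids)
        }


def compute_extremal_sets(
    matrix: pd.DataFrame, percentile: float, direction: str = "high"
) -> ExtremalSetCollection:
    """Top (or bottom) percentile sample set for every gene.

    Parameters
    ----------
    matrix
        Gene x sample expression values (genes in rows).
    percentile
        Fraction in (0, 0.5]; the set size is k = round(percentile * N).
    direction
        'high' for the top of each gene's profile, 'low' for the bottom.
    """
    n = matrix.shape[1]
    k = extremal_set_size(percentile, n)
    values = matrix.to_numpy(dtype=float)
    membership = np.zeros(matrix.shape, dtype=bool)
    for i in range(matrix.shape[0]):
        top = _extremal_order(values[i], direction)[:k]
        membership[i, top] = True
    return ExtremalSetCollection(
        direction=direction,
        percentile=percentile,
        k=k,
        gene_ids=list(matrix.index),
        sample_ids=list(matrix.columns),
        membership=membership,
    )


def overlap_pvalue(m, k1: int, k2: int, N: int):
    """Hypergeometric upper-tail probability P(X >= m).

    X counts the samples shared between a k1-set and a k2-set drawn from a
    population of N samples; this equals the one-sided Fisher's exact test on
    the 2x2 overlap table and is symmetric in (k1, k2).  ``m`` may be a
    scalar or an integer array (k1, k2, N fixed).

    Computed in log space (logsumexp over the tail of the log-pmf) so that
    extreme significances, far below double underflow of naive products,
    remain accurate.
    """
    if not (0 <= min(k1, k2) and max(k1, k2) <= N):
        raise ValueError(f"require 0 <= k1,k2 <= N, got k1={k1}, k2={k2}, N={N}")
    m_arr = np.atleast_1d(np.asarray(m, dtype=int))
    lo, hi = min(k1, k2), max(k1, k2)
    if np.any(m_arr < 0) or np.any(m_arr > lo):
        raise ValueError(f"require 0 <= m <= min(k1,k2)={lo}")
    # support of X: max(0, k1 + k2 - N) .. min(k1, k2)
    support = np.arange(max(0, k1 + k2 - N), lo + 1)
    logpmf = hypergeom.logpmf(support, N, hi, lo)
    # reverse log-cumsum: tail(m) = logsumexp(logpmf[j >= m])
    tail = np.empty(lo + 2)
    tail[lo + 1] = -np.inf
    acc = -np.inf
    offset = support[0]
    for j in range(lo, offset - 1, -1):
        acc = np.logaddexp(acc, logpmf[j - offset])
        tail[j] = acc
    tail[: offset + 1] = 0.0  # P(X >= m) = 1 exactly at/below the support floor
    out = np.exp(np.minimum(tail[m_arr], 0.0))
    return float(out[0]) if np.isscalar(m) or np.ndim(m) == 0 else out


def _pairwise_overlaps(membership: np.ndarray) -> np.ndarray:
    """Upper-triangle overlap counts for all gene pairs (condensed order)."""
    counts = membership.astype(np.int32) @ membership.T.astype(np.int32)
    iu = np.triu_indices(membership.shape[0], k=1)
    return counts[iu]


def _pair_pvalues(sets: ExtremalSetCollection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw and BH-adjusted p-values for every unordered gene pair.

    The BH family is the full set of G(G-1)/2 pairwise tests; zero-overlap
    pairs enter at p_raw = 1.
    """
    m = _pairwise_overlaps(sets.membership)
    lut = overlap_pvalue(np.arange(sets.k + 1), sets.k, sets.k, sets.n_samples)
    p_raw = lut[m]
    if p_raw.size:
        _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    else:
        p_adj = p_raw.copy()
    return m, p_raw, p_adj


def build_graph(
    sets: ExtremalSetCollection, cutoff: float, cutoff_mode: str = "fdr"
) -> nx.Graph:
    """Significance-filtered co-expression graph.

    Nodes are genes; an edge joins each unordered pair whose overlap p-value
    (BH-adjusted when cutoff_mode='fdr', raw when 'raw') is <= cutoff.  Each
    edge stores the shared-sample set, the overlap count m, p_raw and
    p_adjusted.  Genes without a significant partner are not added as nodes.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    if cutoff_mode not in ("fdr", "raw"):
        raise ValueError(f"cutoff_mode must be 'fdr' or 'raw', got {cutoff_mode!r}")
    m, p_raw, p_adj = _pair_pvalues(sets)
    crit = p_adj if cutoff_mode == "fdr" else p_raw
    keep = crit <= cutoff

    g = nx.Graph(
        percentile=sets.percentile,
        direction=sets.direction,
        cutoff=cutoff,
        cutoff_mode=cutoff_mode,
    )
    genes = np.asarray(sets.gene_ids, dtype=object)
    samples = np.asarray(sets.sample_ids, dtype=object)
    iu, ju = np.triu_indices(sets.n_genes, k=1)
    for idx in np.flatnonzero(keep):
        i, j = int(iu[idx]), int(ju[idx])
        shared = frozenset(samples[sets.membership[i] & sets.membership[j]])
        g.add_edge(
            genes[i],
            genes[j],
            shared_samples=shared,
            m=int(m[idx]),
            p_raw=float(p_raw[idx]),
            p_adjusted=float(p_adj[idx]),
        )
    if g.number_of_nodes() < 3:
        warnings.warn(
            "fewer than 3 genes pass the significance cut-off; "
            "no biclusters can be formed",
            stacklevel=2,
        )
    return g


@dataclass
class TuningCurve:
    """Edge / gene / sample counts across a grid of significance cut-offs."""

    cutoff_mode: str
    table: pd.DataFrame = field(repr=False)  # columns: cutoff, n_edges, n_genes_in_graph, n_samples_on_edges

    def __post_init__(self):
        t = self.table
        for col in ("n_edges", "n_genes_in_graph", "n_samples_on_edges"):
            if not np.all(np.diff(t[col].to_numpy()) >= 0):
                raise AssertionError(f"{col} must be non-decreasing with leniency")


def tuning_curve(
    sets: ExtremalSetCollection,
    cutoff_grid: list[float],
    cutoff_mode: str = "fdr",
) -> TuningCurve:
    """Graph size diagnostics over a grid of cut-offs (stringent to lenient).

    For each cut-off: the number of retained edges, the number of genes with
    at least one edge, and the number of distinct samples appearing on at
    least one edge's shared-sample set.
    """
    grid = sorted(float(c) for c in cutoff_grid)
    if not all(0.0 < c < 1.0 for c in grid):
        raise ValueError("all grid cut-offs must lie in (0, 1)")
    m, p_raw, p_adj = _pair_pvalues(sets)
    crit = p_adj if cutoff_mode == "fdr" else p_raw
    iu, ju = np.triu_indices(sets.n_genes, k=1)
    rows = []
    for c in grid:
        keep = np.flatnonzero(crit <= c)
        genes_in = np.unique(np.concatenate([iu[keep], ju[keep]])) if keep.size else []
        samples_on = np.zeros(sets.n_samples, dtype=bool)
        for start in range(0, keep.size, 4096):
            chunk = keep[start : start + 4096]
            both = sets.membership[iu[chunk]] & sets.membership[ju[chunk]]
            samples_on |= both.any(axis=0)
        rows.append(
            {
                "cutoff": c,
                "n_edges": int(keep.size),
                "n_genes_in_graph": int(len(genes_in)),
                "n_samples_on_edges": int(samples_on.sum()),
            }
        )
    return TuningCurve(cutoff_mode=cutoff_mode, table=pd.DataFrame(rows))


def suggest_cutoff(curve: TuningCurve) -> tuple[float, pd.DataFrame, bool]:
    """Pick the cut-off where the next-lenient decade grows edges by 40-60%.

    On a decade-spaced grid, the suggested value is the *least stringent*
    cut-off c whose edge count grows by a factor in [1.4, 1.6] when moving to
    the next decade of leniency.  If no cut-off qualifies, the one whose
    growth ratio is closest to 1.5 is returned and flagged approximate.

    Returns (cutoff, diagnostic table with growth ratios, approximate_flag).
    """
    t = curve.table
    if len(t) < 2:
        raise ValueError("tuning curve needs at least 2 rows")
    edges = t["n_edges"].to_numpy(dtype=float)
    if np.all(edges == 0):
        raise ValueError("all edge counts are zero; no cut-off can be suggested")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = edges[1:] / edges[:-1]
    diag = t.iloc[:-1].copy()
    diag["edge_growth_ratio"] = ratios
    ok = (ratios >= 1.4) & (ratios <= 1.6)
    if ok.any():
        idx = int(np.flatnonzero(ok)[-1])  # least stringent qualifying cut-off
        return float(t["cutoff"].iloc[idx]), diag, False
    finite = np.isfinite(ratios)
    if not finite.any():
        raise ValueError("no finite edge-growth ratio on the grid")
    dist = np.where(finite, np.abs(ratios - 1.5), np.inf)
    idx = int(np.argmin(dist))
    return float(t["cutoff"].iloc[idx]), diag, True


def permutation_null(
    matrix: pd.DataFrame,
    percentile: float,
    n_iter: int,
    rng_seed: int,
    direction: str = "high",
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation null for the pairwise overlap test.

    Each iteration independently permutes the sample labels of every gene,
    recomputes the extremal sets and every pairwise overlap p-value, and
    tallies the histogram of overlaps (raw p only takes k+1 attainable
    values, one per overlap count m).

    Returns (summary, histogram): summary has one row per iteration with the
    count of raw and BH-adjusted p-values below ``threshold``; histogram has
    one row per (iteration, m) with the attainable p-values and pair counts.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng_seed)
    values = matrix.to_numpy(dtype=float)
    n_genes, n = values.shape
    k = extremal_set_size(percentile, n)
    lut = overlap_pvalue(np.arange(k + 1), k, k, n)
    summaries, hists = [], []
    for it in range(n_iter):
        perm = rng.permuted(np.tile(np.arange(n), (n_genes, 1)), axis=1)
        shuffled = pd.DataFrame(
            np.take_along_axis(values, perm, axis=1),
            index=matrix.index,
            columns=matrix.columns,
        )
        sets = compute_extremal_sets(shuffled, percentile, direction)
        m, p_raw, p_adj = _pair_pvalues(sets)
        counts = np.bincount(m, minlength=k + 1)
        hists.append(
            pd.DataFrame(
                {
                    "iteration": it,
                    "overlap_m": np.arange(k + 1),
                    "p_raw": lut,
                    "n_pairs": counts,
                }
            )
        )
        summaries.append(
            {
                "iteration": it,
                "n_pairs": int(m.size),
                "min_p_raw": float(p_raw.min()) if p_raw.size else 1.0,
                "n_raw_below": int((p_raw < threshold).sum()),
                "n_adj_below": int((p_adj < threshold).sum()),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(summaries), pd.concat(hists, ignore_index=True)
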