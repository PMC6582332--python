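"""Graph-based bicluster discovery.

The significance-filtered co-expression graph is reduced to its triangle
backbone, mined iteratively for maximum-clique seeds, and each seed is then
expanded back in the pruned graph into a final bicluster:

1. prune every edge that belongs to no triangle (to a fixed point);
2. enumerate the maximum cliques (Bron-Kerbosch) and merge all equally large
   cliques that share at least one gene into a seed;
3. trim all edges incident to the seed and re-prune;
4. repeat 2-3 until no edges remain — seeds are pairwise gene-disjoint;
5. reintroduce each seed into the pruned graph of step 1 and add every gene
   adjacent to at least two seed genes; the induced subgraph is the
   bicluster, its samples the union of the shared-sample sets on its edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .config import RunConfig
from .extremal import ExtremalSetCollection, build_graph, compute_extremal_sets

logger = logging.getLogger(__name__)

__all__ = [
    "Seed",
    "Bicluster",
    "BiclusterCollection",
    "prune_to_triangles",
    "find_maximum_cliques",
    "form_seed",
    "trim",
    "extract_seeds",
    "expand_seed",
    "graph_from_edge_list",
    "run_tuba",
]


@dataclass(frozen=True)
class Seed:
    """Union of overlapping maximum cliques; the core of one bicluster."""

    genes: frozenset
    member_cliques: tuple[tuple, ...]
    discovery_index: int

    def __post_init__(self):
        if len(self.genes) < 3:
            raise ValueError("a seed must contain at least 3 genes")


@dataclass
class Bicluster:
    """A seed plus its expansion: genes, samples and the induced subgraph."""

    bicluster_id: int
    seed: Seed
    genes: frozenset
    samples: frozenset
    graph: nx.Graph = field(repr=False)
    # scoring, attached by tuba.scoring.score_collection
    gene_scores: "pd.DataFrame | None" = field(default=None, repr=False)
    sample_scores: "pd.DataFrame | None" = field(default=None, repr=False)
    quality: float | None = None

    @property
    def degrees(self) -> dict:
        return {g: d for g, d in self.graph.degree()}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class BiclusterCollection:
    biclusters: list[Bicluster]
    config: "RunConfig | None" = None
    gene_universe: list | None = None
    sample_universe: list | None = None

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def gene_sets(self) -> dict[int, frozenset]:
        return {b.bicluster_id: b.genes for b in self.biclusters}

    def sample_sets(self) -> dict[int, frozenset]:
        return {b.bicluster_id: b.samples for b in self.biclusters}


def prune_to_triangles(graph: nx.Graph) -> nx.Graph:
    """Maximal subgraph in which every edge lies in at least one triangle.

    Edges belonging to no 3-clique are removed iteratively until a fixed
    point; isolated nodes are dropped.
    """
    g = graph.copy()
    changed = True
    while changed:
        dead = [
            (u, v)
            for u, v in g.edges
            if not (set(g.adj[u]) & set(g.adj[v]))
        ]
        changed = bool(dead)
        g.remove_edges_from(dead)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return g


def find_maximum_cliques(graph: nx.Graph) -> list[tuple]:
    """All cliques of maximum size, canonically ordered.

    Maximal cliques are enumerated with the Bron-Kerbosch algorithm (with
    pivoting); only those of the maximum size are returned, each as a sorted
    tuple, the list sorted lexicographically.
    """
    if graph.number_of_edges() == 0:
        return []
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    size = max(len(c) for c in cliques)
    return sorted(c for c in cliques if len(c) == size)


def form_seed(max_cliques: list[tuple], discovery_index: int = 0) -> Seed:
    """Merge equally large cliques sharing genes into one seed.

    Cliques are nodes of an overlap graph (adjacent iff they share >= 1
    gene); the seed is the gene union of the connected component containing
    the canonically smallest gene identifier.  Other components stay in the
    main graph and surface as seeds in later iterations.
    """
    if not max_cliques:
        raise ValueError("form_seed requires a non-empty clique list")
    sizes = {len(c) for c in max_cliques}
    if len(sizes) != 1:
        raise ValueError("all cliques passed to form_seed must be of equal size")
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(max_cliques)))
    for i in range(len(max_cliques)):
        for j in range(i + 1, len(max_cliques)):
            if set(max_cliques[i]) & set(max_cliques[j]):
                overlap.add_edge(i, j)
    smallest_gene = min(g for c in max_cliques for g in c)
    anchor = next(i for i, c in enumerate(max_cliques) if smallest_gene in c)
    component = nx.node_connected_component(overlap, anchor)
    members = tuple(max_cliques[i] for i in sorted(component))
    genes = frozenset(g for c in members for g in c)
    return Seed(genes=genes, member_cliques=members, discovery_index=discovery_index)


def trim(graph: nx.Graph, seed: Seed) -> nx.Graph:
    """Remove all edges incident to seed genes, then re-prune to triangles."""
    g = graph.copy()
    g.remove_edges_from(
        [(u, v) for u, v in g.edges if u in seed.genes or v in seed.genes]
    )
    return prune_to_triangles(g)


def extract_seeds(graph: nx.Graph) -> list[Seed]:
    """Iterate max-clique seed discovery and trimming until no edges remain.

    The input must already be triangle-pruned.  Returned seeds carry their
    discovery order and are pairwise disjoint in genes.
    """
    seeds: list[Seed] = []
    g = graph
    while g.number_of_edges() > 0:
        cliques = find_maximum_cliques(g)
        seed = form_seed(cliques, discovery_index=len(seeds))
        seeds.append(seed)
        g = trim(g, seed)
    return seeds


def expand_seed(seed: Seed, pruned_graph: nx.Graph, bicluster_id: int | None = None) -> Bicluster:
    """Grow a seed into a bicluster in the (untrimmed) pruned graph.

    A single pass adds every gene adjacent to at least two seed genes.  The
    bicluster's edges are the pruned graph's induced edges on the final gene
    set; its samples are the union of the shared-sample sets on those edges.
    """
    added = {
        n
        for n in pruned_graph.nodes
        if n not in seed.genes
        and sum(1 for nb in pruned_graph.adj[n] if nb in seed.genes) >= 2
    }
    genes = frozenset(seed.genes | added)
    sub = pruned_graph.subgraph(genes).copy()
    samples = frozenset().union(
        *(d.get("shared_samples", frozenset()) for _, _, d in sub.edges(data=True))
    ) if sub.number_of_edges() else frozenset()
    return Bicluster(
        bicluster_id=seed.discovery_index + 1 if bicluster_id is None else bicluster_id,
        seed=seed,
        genes=genes,
        samples=samples,
        graph=sub,
    )


def graph_from_edge_list(edges, shared_samples: dict | None = None) -> nx.Graph:
    """Build a co-expression graph from a plain edge list.

    Lets the clique machinery consume externally constructed graphs (e.g.
    correlation-thresholded gene pairs).  ``edges`` is an iterable of gene
    pairs; ``shared_samples`` optionally maps a frozenset({g1, g2}) or tuple
    to the samples carried by that edge.
    """
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            continue
        attrs = {}
        if shared_samples is not None:
            key = frozenset((u, v))
            val = shared_samples.get(key, shared_samples.get((u, v), shared_samples.get((v, u))))
            attrs["shared_samples"] = frozenset(val) if val is not None else frozenset()
        g.add_edge(u, v, **attrs)
    return g


def biclusters_from_graph(graph: nx.Graph) -> list[Bicluster]:
    """Prune, mine seeds, and expand — the graph-side half of the pipeline."""
    pruned = prune_to_triangles(graph)
    seeds = extract_seeds(pruned)
    return [expand_seed(s, pruned, bicluster_id=i + 1) for i, s in enumerate(seeds)]


def run_tuba(matrix, config: RunConfig) -> BiclusterCollection:
    """Full pipeline: extremal sets -> graph -> seeds -> scored biclusters."""
    config.validate()
    sets = compute_extremal_sets(matrix, config.percentile, config.direction)
    graph = build_graph(sets, config.cutoff, config.cutoff_mode)
    if graph.number_of_nodes() < 3:
        warnings.warn("empty or near-empty graph: no biclusters", stacklevel=2)
        collection = BiclusterCollection(
            [], config=config,
            gene_universe=list(matrix.index), sample_universe=list(matrix.columns),
        )
        return collection
    biclusters = biclusters_from_graph(graph)
    collection = BiclusterCollection(
        biclusters,
        config=config,
        gene_universe=list(matrix.index),
        sample_universe=list(matrix.columns),
    )
    from .scoring import score_collection

    score_collection(collection, matrix, direction=config.direction)
    return collection
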