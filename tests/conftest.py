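import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import tuba


# ---------------------------------------------------------------- oracles
def hypergeom_tail_oracle(m: int, k1: int, k2: int, N: int) -> float:
    """Exact tail sum P(X >= m) via integer combinatorics (independent oracle)."""
    lo = min(k1, k2)
    num = sum(math.comb(k1, j) * math.comb(N - k1, k2 - j) for j in range(m, lo + 1)
              if k2 - j <= N - k1)
    return num / math.comb(N, k2)


def max_cliques_bruteforce(graph: nx.Graph) -> list[tuple]:
    """All maximum cliques by plain backtracking over ordered vertices."""
    nodes = sorted(graph.nodes)
    adj = {n: set(graph.adj[n]) for n in nodes}
    found = []

    def extend(clique, candidates):
        found.append(tuple(clique))
        for i, v in enumerate(candidates):
            extend(clique + [v], [w for w in candidates[i + 1:] if w in adj[v]])

    extend([], nodes)
    if not found:
        return []
    best = max(len(c) for c in found)
    return sorted(tuple(sorted(c)) for c in found if len(c) == best)


def prune_bruteforce(graph: nx.Graph) -> nx.Graph:
    """Fixed-point removal of triangle-free edges, written independently."""
    g = graph.copy()
    while True:
        dead = []
        for u, v in g.edges:
            if not any(w in g.adj[u] and w in g.adj[v] for w in g.nodes):
                dead.append((u, v))
        if not dead:
            break
        g.remove_edges_from(dead)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: matrix, ground truth."""
    return tuba.default_benchmark(seed=42)


@pytest.fixture(scope="session")
def benchmark_collection(benchmark):
    """Biclusters discovered on the default benchmark at standard settings."""
    matrix, _ = benchmark
    cfg = tuba.RunConfig(percentile=0.05, direction="high", cutoff=1e-8,
                         cutoff_mode="fdr", seed=42)
    return tuba.run_tuba(matrix, cfg)


@pytest.fixture
def tiny_matrix():
    """5 genes x 6 samples with a forced co-extremal pair on S4, S5."""
    rng = np.random.default_rng(0)
    values = rng.normal(0.0, 1.0, size=(5, 6))
    values[0, 4:] += 10
    values[1, 4:] += 10
    return pd.DataFrame(values,
                        index=[f"G{i}" for i in range(5)],
                        columns=[f"S{j}" for j in range(6)])


def make_shared_set_matrix(n_co: int, n_background: int, n_samples: int,
                           k_samples: int, seed: int = 1) -> pd.DataFrame:
    """Matrix where the first n_co genes share one extremal sample set."""
    rng = np.random.default_rng(seed)
    values = rng.normal(5.0, 1.0, size=(n_co + n_background, n_samples))
    values[:n_co, :k_samples] += 10.0
    genes = [f"G{i:04d}" for i in range(n_co + n_background)]
    samples = [f"S{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(values, index=genes, columns=samples)
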