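"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: betweenness
and Dpath oracles enumerate simple paths with a plain DFS, the hypergeometric
oracle counts draws exhaustively, and the eigenvector oracle is a power
iteration written here.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from heartomics.expression import ZScoreTable
from heartomics.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A fast study: 2 datasets, 4 cell types, few genes."""
    return SimulationConfig(
        n_datasets=2,
        cell_types=("cardiomyocytes", "fibroblasts", "mast cells", "pericytes"),
        n_genes=200,
        n_markers_per_cell_type=5,
    )


def make_profile_df(values: dict[str, dict[str, float]], pct: float = 80.0) -> pd.DataFrame:
    """gene -> {cell_type: expression} into a profile DataFrame."""
    rows = [
        {"gene": g, "cell_type": ct, "mean_lognorm_expr": v,
         "pct_expressing": pct, "n_nuclei": 1000}
        for g, cts in values.items()
        for ct, v in cts.items()
    ]
    return pd.DataFrame(rows)


def make_ztable(dataset_id: str, entries: list[tuple]) -> ZScoreTable:
    """entries: (gene, cell_type, z, p, class, pct) tuples."""
    df = pd.DataFrame(
        entries, columns=["gene", "cell_type", "z", "p", "class", "pct_expressing"]
    )
    df["mean_lognorm_expr"] = 1.0
    return ZScoreTable(dataset_id=dataset_id, data=df)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by counting every possible draw of n items from N."""
    hits = total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def all_simple_paths(adj: dict, s, t, path=None):
    """DFS enumeration of simple paths in an adjacency dict {u: {v: w}}."""
    path = path or [s]
    if s == t:
        yield list(path)
        return
    for v in adj.get(s, {}):
        if v not in path:
            path.append(v)
            yield from all_simple_paths(adj, v, t, path)
            path.pop()


def betweenness_by_enumeration(adj: dict) -> dict:
    """Fractional betweenness over unordered pairs, endpoints excluded,
    from exhaustive simple-path enumeration on an undirected graph."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_simple_paths(adj, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            bc[v] += through / len(sp)
    return bc


def min_dpath_by_enumeration(adj: dict, s, t):
    """(dpath, n_steps, path) of the optimal simple path in a weighted
    digraph {u: {v: dist}}, with the fewer-steps-then-lexicographic
    tie-break; None when unreachable."""
    best = None
    for path in all_simple_paths(adj, s, t):
        d = sum(adj[a][b] for a, b in zip(path[:-1], path[1:]))
        key = (round(d, 12), len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[0], best[1], list(best[2])


def principal_eigvec_power_iteration(a: np.ndarray, iters: int = 20_000) -> np.ndarray:
    """Unit-norm nonnegative principal eigenvector by plain power iteration."""
    v = np.ones(a.shape[0]) / math.sqrt(a.shape[0])
    for _ in range(iters):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return v
        w /= norm
        if np.linalg.norm(w - v) < 1e-13:
            v = w
            break
        v = w
    return np.abs(v)


def random_undirected_adj(rng: np.random.Generator, n_nodes: int, p: float = 0.4) -> dict:
    """Random undirected graph as a symmetric adjacency dict."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    adj = {v: {} for v in nodes}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p:
            adj[a][b] = 1.0
            adj[b][a] = 1.0
    return adj
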