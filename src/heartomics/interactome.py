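"""Confidence-filtered protein interaction network and node centralities.

The network keeps only edges whose confidence meets the cutoff (default
>= 0.9, the STRING "highest confidence" band, inclusive) with both endpoints
in the query whitelist; self-loops are dropped, duplicate pairs collapse to
the maximum confidence, and nodes left without edges are excluded.

Centralities follow the conventions that match the scale of values typically
reported for networks of this size: degree as a raw edge count, betweenness
as unnormalized fractional shortest-path counts over unordered pairs with
endpoints excluded (Brandes), and eigenvector centrality as the nonnegative
principal eigenvector of the largest connected component's adjacency matrix
scaled to unit Euclidean norm (nodes outside that component get 0).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import ConfidenceEdges

logger = logging.getLogger("heartomics.interactome")

CONFIDENCE_CUTOFF = 0.9


def build_network(
    edges: ConfidenceEdges,
    whitelist: set[str],
    cutoff: float = CONFIDENCE_CUTOFF,
    node_metadata: dict[str, dict] | None = None,
) -> nx.Graph:
    """Build the confidence-filtered undirected network over a gene whitelist.

    ``node_metadata`` (e.g. {gene: {"cell_type": ..., "direction": ...}}) is
    attached to surviving nodes.  Zero surviving edges yields an empty graph
    with a warning, not an error.
    """
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    df = edges.data
    keep = (
        (df["confidence"] >= cutoff)
        & (df["protein_a"] != df["protein_b"])
        & df["protein_a"].isin(whitelist)
        & df["protein_b"].isin(whitelist)
    )
    g = nx.Graph()
    for a, b, c in df.loc[keep, ["protein_a", "protein_b", "confidence"]].itertuples(index=False):
        # duplicate pairs (either orientation) collapse to max confidence
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=float(c))
    if g.number_of_edges() == 0:
        logger.warning("no edge passed cutoff %.3g within the whitelist", cutoff)
    if node_metadata:
        for node in g.nodes:
            g.nodes[node].update(node_metadata.get(node, {}))
    return g


def degree_centrality(net: nx.Graph) -> pd.Series:
    """Raw degree (edge count) per node."""
    return pd.Series(dict(net.degree()), dtype=float).sort_index()


def betweenness_centrality(net: nx.Graph) -> pd.Series:
    """Unnormalized betweenness: for each node v, the sum over unordered
    pairs {s, t} (s != v != t) of the fraction of shortest s-t paths through
    v.  Disconnected graphs are handled naturally (no paths across
    components)."""
    return pd.Series(nx.betweenness_centrality(net, normalized=False)).sort_index()


def eigenvector_centrality(
    net: nx.Graph, normalization: str = "unit", max_iter: int = 10_000
) -> pd.Series:
    """Eigenvector centrality of the largest connected component.

    Computed as the principal eigenvector of the component's dense adjacency
    matrix (symmetric eigendecomposition; nonnegative by Perron-Frobenius),
    scaled to unit Euclidean norm (``normalization="unit"``) or to maximum
    entry 1 (``"max"``).  Nodes outside the largest component receive 0.
    For components above 500 nodes a sparse Lanczos solver is used; failure
    to converge within ``max_iter`` iterations is a hard error.
    """
    if normalization not in {"unit", "max"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    if net.number_of_nodes() == 0:
        return pd.Series(dtype=float)
    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), sorted(c)))
    giant = sorted(components[0])
    sub = net.subgraph(giant)
    if len(giant) == 1:
        vec = np.array([1.0])
    elif len(giant) <= 500:
        a = nx.to_numpy_array(sub, nodelist=giant)
        _, vecs = np.linalg.eigh(a)
        vec = vecs[:, -1]
    else:
        from scipy.sparse.linalg import ArpackNoConvergence, eigsh

        a = nx.to_scipy_sparse_array(sub, nodelist=giant, format="csr", dtype=float)
        try:
            _, vecs = eigsh(a, k=1, which="LA", maxiter=max_iter)
        except ArpackNoConvergence as exc:  # pragma: no cover - large graphs only
            raise RuntimeError(
                f"eigenvector centrality failed to converge in {max_iter} iterations"
            ) from exc
        vec = vecs[:, 0]
    vec = np.abs(vec)
    if normalization == "unit":
        vec = vec / np.linalg.norm(vec)
    else:
        vec = vec / vec.max()
    out = pd.Series(0.0, index=sorted(net.nodes))
    out.loc[giant] = vec
    return out


def centrality_table(net: nx.Graph, normalization: str = "unit") -> pd.DataFrame:
    """All three centralities per node plus component membership flag."""
    if net.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["node", "degree", "betweenness", "eigenvector", "in_largest_component", "cell_type"]
        )
    deg = degree_centrality(net)
    bet = betweenness_centrality(net)
    eig = eigenvector_centrality(net, normalization=normalization)
    giant = max(nx.connected_components(net), key=lambda c: (len(c), sorted(c)))
    df = pd.DataFrame(
        {
            "node": deg.index,
            "degree": deg.values.astype(int),
            "betweenness": bet.values,
            "eigenvector": eig.values,
            "in_largest_component": [n in giant for n in deg.index],
            "cell_type": [net.nodes[n].get("cell_type", "") for n in deg.index],
        }
    )
    return df.reset_index(drop=True)


def gene_set_overlap(query: set[str], reference: set[str]) -> tuple[int, float]:
    """Overlap count and percentage (of the query, rounded to the nearest
    integer percent) between two symbol sets."""
    query = set(query)
    k = len(query & set(reference))
    pct = 0.0 if not query else round(100.0 * k / len(query))
    return k, pct


def network_summary(
    net: nx.Graph,
    centralities: pd.DataFrame,
    reference_proteome: set[str] | None = None,
    top_n: int = 3,
) -> dict:
    """Node/edge counts, centrality means, top nodes per centrality (ties
    lexicographic), node counts per primary cell type, and overlap with a
    reference proteome (count + integer percent)."""
    summary: dict = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
    }
    if centralities.empty:
        summary.update(
            mean_degree=np.nan, mean_betweenness=np.nan, mean_eigenvector=np.nan,
            top_degree=[], top_betweenness=[], top_eigenvector=[],
            nodes_per_cell_type={}, proteome_overlap=0, proteome_overlap_pct=0.0,
        )
        return summary
    for col in ["degree", "betweenness", "eigenvector"]:
        summary[f"mean_{col}"] = float(centralities[col].mean())
        ranked = centralities.sort_values([col, "node"], ascending=[False, True], kind="mergesort")
        summary[f"top_{col}"] = ranked["node"].head(top_n).tolist()
    by_ct = centralities[centralities["cell_type"] != ""].groupby("cell_type").size()
    summary["nodes_per_cell_type"] = {k: int(v) for k, v in by_ct.sort_values(ascending=False).items()}
    ref = set(reference_proteome or set())
    k, pct = gene_set_overlap(set(net.nodes), ref)
    summary["proteome_overlap"] = k
    summary["proteome_overlap_pct"] = pct
    return summary


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Canonical sorted edge list with confidences."""
    rows = [
        {"protein_a": min(a, b), "protein_b": max(a, b), "confidence": d["confidence"]}
        for a, b, d in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])
    return df.sort_values(["protein_a", "protein_b"], kind="mergesort").reset_index(drop=True)
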