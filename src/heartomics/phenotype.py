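"""Reliability-weighted causal shortest paths to physiological phenotypes.

Each directed causal edge carries a reliability score r in (0, 1], converted
to a step distance d = 1 - r; the score of a path is Dpath = sum of its step
distances, so Dpath = 0 exactly when every step has perfect reliability.
Every protein is scored by its minimum-Dpath directed path to each phenotype
node (cell proliferation, cell death, cell differentiation, glycolysis,
inflammation, angiogenesis and DNA repair by default).  The search follows
edge direction only (active-flow causality); edge signs annotate the net
effect of the optimal path but never constrain it, since both positive and
negative regulation count as regulation.

Ties on Dpath break by fewer steps, then by lexicographically smallest node
sequence, so results are deterministic and testable.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EFFECT_SIGNS, CausalEdges

logger = logging.getLogger("heartomics.phenotype")

#: default phenotype node set
PHENOTYPES = (
    "cell proliferation",
    "cell death",
    "cell differentiation",
    "glycolysis",
    "inflammation",
    "angiogenesis",
    "DNA repair",
)

ALPHA = 0.001
MIN_PHENOTYPES = 5

UNREACHABLE = math.inf


def step_distance(r: float) -> float:
    """d = 1 - r for a reliability score r in (0, 1]."""
    if not (0.0 < r <= 1.0):
        raise ValueError(f"reliability must lie in (0, 1]; got {r}")
    return 1.0 - r


@dataclass
class CausalNetwork:
    """Directed signed graph with per-edge reliability and phenotype nodes.

    ``adj`` maps node -> sorted list of (neighbor, distance, sign) with
    distance = 1 - r.  Parallel edges collapse to the smallest distance.
    """

    adj: dict[str, list[tuple[str, float, int]]]
    phenotype_nodes: frozenset[str]
    nodes: frozenset[str]

    @classmethod
    def from_edges(cls, edges: CausalEdges) -> "CausalNetwork":
        adj: dict[str, dict[str, tuple[float, int]]] = {}
        nodes: set[str] = set(edges.phenotype_nodes)
        for s, t, effect, r in edges.data[
            ["source", "target", "effect", "reliability"]
        ].itertuples(index=False):
            d = step_distance(float(r))
            sign = EFFECT_SIGNS[effect]
            nodes.update((s, t))
            best = adj.setdefault(s, {})
            if t not in best or d < best[t][0]:
                best[t] = (d, sign)
        pheno = frozenset(edges.phenotype_nodes)
        with_out = {p for p in pheno if adj.get(p)}
        if with_out:
            logger.warning("phenotype node(s) with outgoing edges: %s", sorted(with_out))
        return cls(
            adj={
                s: sorted((t, d, sg) for t, (d, sg) in targets.items())
                for s, targets in adj.items()
            },
            phenotype_nodes=pheno,
            nodes=frozenset(nodes),
        )


@dataclass
class PathResult:
    """Minimum-Dpath directed path from a protein to a phenotype node."""

    source: str
    phenotype: str
    dpath: float  # math.inf when unreachable
    n_steps: int
    path: tuple[str, ...] = field(default_factory=tuple)
    net_sign: int = 0  # product of step signs; 0 when unreachable

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.dpath)


def _single_source_dijkstra(
    net: CausalNetwork, source: str
) -> dict[str, tuple[float, tuple[str, ...], int]]:
    """Settled node -> (dpath, path, net_sign), with deterministic tie-breaks.

    Priority keys are (dpath, n_steps, path tuple): equal-distance ties
    resolve to the path with fewer steps, then to the lexicographically
    smallest node sequence.
    """
    best: dict[str, tuple[float, tuple[str, ...], int]] = {}
    heap: list[tuple[float, int, tuple[str, ...], int]] = [(0.0, 0, (source,), 1)]
    while heap:
        d, steps, path, sign = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (d, path, sign)
        for nbr, w, esign in net.adj.get(node, ()):
            if nbr not in best:
                heapq.heappush(heap, (d + w, steps + 1, path + (nbr,), sign * esign))
    return best


def shortest_path(net: CausalNetwork, source: str, phenotype: str) -> PathResult:
    """Minimum-Dpath path from ``source`` to ``phenotype``.

    ``source == phenotype`` returns Dpath 0 with an empty path and a logged
    warning; a missing directed route returns an unreachable result.
    """
    if source not in net.nodes or phenotype not in net.nodes:
        raise KeyError(f"{source!r} or {phenotype!r} not in the causal network")
    if source == phenotype:
        logger.warning("source equals phenotype node %r; Dpath is trivially 0", source)
        return PathResult(source, phenotype, 0.0, 0, (), 1)
    settled = _single_source_dijkstra(net, source)
    if phenotype not in settled:
        return PathResult(source, phenotype, UNREACHABLE, 0, (), 0)
    d, path, sign = settled[phenotype]
    return PathResult(source, phenotype, d, len(path) - 1, path, sign)


def distance_matrix(
    net: CausalNetwork,
    proteins: list[str],
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Protein x phenotype matrix of Dpath values (inf = unreachable).

    Proteins absent from the network get all-unreachable rows with a log
    message.  One Dijkstra run per protein covers all phenotypes.
    """
    phenotypes = list(phenotypes if phenotypes is not None else net.phenotype_nodes or PHENOTYPES)
    missing_ph = [p for p in phenotypes if p not in net.nodes]
    if missing_ph:
        raise KeyError(f"phenotype node(s) {missing_ph} not in the causal network")
    rows = {}
    for prot in proteins:
        if prot not in net.nodes:
            logger.info("protein %s absent from the causal network; row unreachable", prot)
            rows[prot] = {ph: UNREACHABLE for ph in phenotypes}
            continue
        settled = _single_source_dijkstra(net, prot)
        rows[prot] = {
            ph: settled[ph][0] if ph in settled else UNREACHABLE for ph in phenotypes
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=phenotypes)
    df = df.loc[sorted(df.index)]
    df.index.name = "protein"
    return df


def phenotype_means(matrix: pd.DataFrame) -> pd.Series:
    """Per-phenotype mean Dpath over reachable entries only, ascending."""
    masked = matrix.replace(UNREACHABLE, np.nan)
    return masked.mean(axis=0).sort_values(kind="mergesort")


def prioritize_targets(
    matrix: pd.DataFrame,
    min_phenotypes: int = MIN_PHENOTYPES,
    dmax: float = math.inf,
) -> pd.DataFrame:
    """Proteins with short causal routes to at least ``min_phenotypes``
    phenotypes.

    A protein qualifies for a phenotype when Dpath <= ``dmax`` (default: any
    finite Dpath, i.e. reachability).  Ranked by descending phenotype count,
    then ascending mean Dpath over qualifying phenotypes, then name.
    """
    qual = matrix.le(dmax) & np.isfinite(matrix)
    counts = qual.sum(axis=1)
    masked = matrix.where(qual)
    mean_d = masked.mean(axis=1)
    out = pd.DataFrame(
        {
            "protein": matrix.index,
            "n_phenotypes": counts.values.astype(int),
            "mean_dpath": mean_d.values,
            "phenotypes": [
                ",".join(c for c in matrix.columns if qual.loc[p, c]) for p in matrix.index
            ],
        }
    )
    out = out[out["n_phenotypes"] >= min_phenotypes]
    out = out.sort_values(
        ["n_phenotypes", "mean_dpath", "protein"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)


def compare_phenotypes(
    matrix: pd.DataFrame, alpha: float = ALPHA, method: str = "welch"
) -> pd.DataFrame:
    """All pairwise location tests between phenotype distance distributions.

    Reachable Dpath values only.  ``method`` is ``"welch"`` (unequal-variance
    two-sample t, with a 95% confidence interval of the mean difference) or
    ``"mannwhitney"`` (no CI).  Raw p-values are Bonferroni-adjusted over
    m = C(P, 2) pairs (multiplied by m, capped at 1); significance at
    ``alpha`` applies to the adjusted p.  Phenotypes with fewer than two
    reachable values have their pairs skipped with a warning.
    """
    if method not in {"welch", "mannwhitney"}:
        raise ValueError(f"unknown method {method!r}")
    masked = matrix.replace(UNREACHABLE, np.nan)
    phenos = list(masked.columns)
    m = len(phenos) * (len(phenos) - 1) // 2
    rows = []
    for a, b in itertools.combinations(phenos, 2):
        xa = masked[a].dropna().to_numpy()
        xb = masked[b].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("pair (%s, %s) skipped: <2 reachable values", a, b)
            continue
        if method == "welch":
            res = stats.ttest_ind(xa, xb, equal_var=False)
            ci = res.confidence_interval(confidence_level=0.95)
            ci_low, ci_high = float(ci.low), float(ci.high)
            statistic, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
            ci_low = ci_high = np.nan
        rows.append(
            {
                "phenotype_a": a,
                "phenotype_b": b,
                "mean_difference": float(xa.mean() - xb.mean()),
                "statistic": statistic,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * m),
                "m": m,
                "significant": min(1.0, p * m) < alpha,
                "ci95_low": ci_low,
                "ci95_high": ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype_a", "phenotype_b", "mean_difference", "statistic",
            "p_raw", "p_bonferroni", "m", "significant", "ci95_low", "ci95_high",
        ],
    )


def cell_type_distance(
    matrix: pd.DataFrame, cell_type_assignment: dict[str, str]
) -> pd.DataFrame:
    """Rank cell types by the mean of their proteins' per-protein mean
    reachable Dpath, ascending (shortest routes first).

    Unassigned proteins and proteins with no reachable phenotype are
    excluded with a log message.
    """
    masked = matrix.replace(UNREACHABLE, np.nan)
    per_protein = masked.mean(axis=1)
    rows = []
    for prot, mean_d in per_protein.items():
        ct = cell_type_assignment.get(prot)
        if ct is None:
            logger.info("protein %s has no cell-type assignment; excluded", prot)
            continue
        if np.isnan(mean_d):
            logger.info("protein %s reaches no phenotype; excluded", prot)
            continue
        rows.append({"cell_type": ct, "protein": prot, "mean_dpath": float(mean_d)})
    if not rows:
        return pd.DataFrame(columns=["cell_type", "mean_dpath", "n_proteins", "rank"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("cell_type")
        .agg(mean_dpath=("mean_dpath", "mean"), n_proteins=("protein", "size"))
        .sort_values(["mean_dpath", "cell_type"], kind="mergesort")
        .reset_index()
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg
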