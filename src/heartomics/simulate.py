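"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
multiple snRNA-seq datasets sharing a gene universe with planted cell-type
markers, annotation gene sets with planted enriched terms, a STRING-like
confidence edge list with planted hubs, and a SIGNOR-like layered causal
network with golden targets wired close to phenotype nodes.

Expression model.  Each gene g has a baseline log-normalized expression
level mu_g drawn once from Normal(baseline_mean, baseline_sd) (shared by all
datasets — genes keep their identity); each dataset/cell-type observation
adds independent jitter Normal(0, celltype_sd) and clips at 0.  An
over-expressed marker of cell type c is shifted by
``marker_effect_size * baseline_sd`` in c; an under-expressed marker is
modeled as a broadly expressed gene (baseline mu_g + shift everywhere)
depleted back to mu_g in c, which keeps the two directions symmetric without
running into the zero floor of log-normalized expression.
``marker_effect_size`` is therefore measured in population SDs of the
baseline expression distribution; at the default effect 4 and jitter 0.2 a
marker sits ~20 jitter-SDs away from its gene's other cell types, the
near-exclusive regime typical of canonical cell-type markers.

All generators are pure functions of (config, seed); each draws from its own
sub-stream (``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed
k per generator), so adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationDatabase, CausalEdges, ConfidenceEdges, ExpressionProfile
from .phenotype import PHENOTYPES
from .reference import HEART_CELL_TYPES

_SUBSTREAMS = {"expression": 0, "annotations": 1, "ppi": 2, "causal": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[stream],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Scale defaults (3 datasets, 13 heart cell types, 2000 genes, ~150-node
    interaction network, ~200-node causal network) mirror the order of
    magnitude of the real integrated analysis while keeping the full
    pipeline fast.
    """

    n_datasets: int = 3
    cell_types: tuple[str, ...] = HEART_CELL_TYPES
    n_genes: int = 2000
    n_markers_per_cell_type: int = 10
    marker_effect_size: float = 4.0  # in baseline-population SDs
    baseline_mean: float = 1.0  # log-normalized expression units
    baseline_sd: float = 1.0
    celltype_sd: float = 0.2  # across-cell-type jitter of a non-marker gene
    pct_background: tuple[float, float] = (5.0, 70.0)
    pct_marker: tuple[float, float] = (55.0, 98.0)
    # annotations
    n_annotation_terms: int = 50
    planted_term_size: int = 20
    background_term_size: tuple[int, int] = (10, 50)
    # protein-interaction network
    ppi_background_edge_p: float = 0.05
    ppi_hub_count: int = 1
    ppi_hub_attachment: float = 0.6  # fraction of markers wired to each hub
    ppi_background_confidence: tuple[float, float] = (0.2, 0.95)
    ppi_planted_confidence: tuple[float, float] = (0.9, 1.0)
    # causal network
    n_intermediate_layers: int = 2
    reliability_range: tuple[float, float] = (0.6, 0.99)
    golden_reliability_range: tuple[float, float] = (0.9, 0.99)
    n_golden_targets: int = 3
    golden_phenotype_count: int = 6
    max_background_phenotypes: int = 4
    phenotypes: tuple[str, ...] = PHENOTYPES

    def __post_init__(self):
        if self.n_datasets < 1 or self.n_genes < 1 or self.n_markers_per_cell_type < 1:
            raise ValueError("counts must be positive")
        if self.marker_effect_size < 0:
            raise ValueError("marker_effect_size must be >= 0")
        lo, hi = self.reliability_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("reliability_range must lie within (0, 1]")
        if len(self.cell_types) * self.n_markers_per_cell_type > self.n_genes:
            raise ValueError("more markers than genes")
        if self.n_golden_targets > self.n_markers_per_cell_type:
            raise ValueError("golden targets are drawn from one cell type's markers")


@dataclass
class GroundTruth:
    """What was planted, so recovery can be scored."""

    markers: dict[str, tuple[str, str]] = field(default_factory=dict)  # gene -> (cell_type, direction)
    planted_terms: dict[str, str] = field(default_factory=dict)  # term -> cell_type
    hubs: list[str] = field(default_factory=list)
    golden_targets: dict[str, int] = field(default_factory=dict)  # gene -> wired phenotype count
    golden_cell_type: str = ""

    @property
    def marker_genes(self) -> frozenset[str]:
        return frozenset(self.markers)

    def markers_of(self, cell_type: str) -> list[str]:
        return sorted(g for g, (ct, _) in self.markers.items() if ct == cell_type)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _plant_markers(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    genes = _gene_names(config.n_genes)
    chosen = rng.choice(config.n_genes, size=len(config.cell_types) * config.n_markers_per_cell_type, replace=False)
    truth = GroundTruth()
    i = 0
    for ct in config.cell_types:
        for _ in range(config.n_markers_per_cell_type):
            direction = "over" if rng.random() < 0.5 else "under"
            truth.markers[genes[chosen[i]]] = (ct, direction)
            i += 1
    return truth


def generate_expression(
    config: SimulationConfig, seed: int
) -> tuple[list[ExpressionProfile], GroundTruth]:
    """Per-dataset expression pseudo-profiles with planted markers.

    Marker placement and baselines are shared across datasets (same seed,
    same truth); jitter, percent-expressing and nucleus counts are drawn per
    dataset.
    """
    rng = _rng(seed, "expression")
    truth = _plant_markers(config, rng)
    genes = _gene_names(config.n_genes)
    cts = list(config.cell_types)
    n_ct = len(cts)
    shift = config.marker_effect_size * config.baseline_sd

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    # mean expression per gene x cell type, before jitter
    mu = np.tile(baseline[:, None], (1, n_ct))
    ct_index = {ct: j for j, ct in enumerate(cts)}
    for gene, (ct, direction) in truth.markers.items():
        gi, cj = genes.index(gene), ct_index[ct]
        if direction == "over":
            mu[gi, cj] += shift
        else:
            mu[gi, :] += shift  # broadly expressed ...
            mu[gi, cj] -= shift  # ... depleted in its cell type

    marker_mask = np.zeros((config.n_genes, n_ct), dtype=bool)
    for gene, (ct, _) in truth.markers.items():
        marker_mask[genes.index(gene), ct_index[ct]] = True

    profiles = []
    for d in range(config.n_datasets):
        jitter = rng.normal(0.0, config.celltype_sd, (config.n_genes, n_ct))
        expr = np.clip(mu + jitter, 0.0, None)
        pct = rng.uniform(*config.pct_background, (config.n_genes, n_ct))
        pct[marker_mask] = rng.uniform(*config.pct_marker, int(marker_mask.sum()))
        nuclei = np.round(10 ** rng.uniform(2.5, 5.2, n_ct)).astype(int)
        df = pd.DataFrame(
            {
                "gene": np.repeat(genes, n_ct),
                "cell_type": np.tile(cts, config.n_genes),
                "mean_lognorm_expr": expr.ravel(),
                "pct_expressing": pct.ravel(),
                "n_nuclei": np.tile(nuclei, config.n_genes),
            }
        )
        profiles.append(ExpressionProfile(dataset_id=f"SYN{d + 1}", data=df))
    return profiles, truth


def generate_annotations(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> tuple[AnnotationDatabase, GroundTruth]:
    """GMT-style annotation source with one planted term per cell type.

    Each planted term contains that cell type's markers padded with random
    genes up to ``planted_term_size``; background terms are uniform draws
    from the gene universe.
    """
    rng = _rng(seed, "annotations")
    genes = np.array(_gene_names(config.n_genes))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    truth = replace_truth(truth)
    for i, ct in enumerate(config.cell_types):
        markers = truth.markers_of(ct)
        pad = [
            str(x)
            for x in rng.choice(
                sorted(set(genes) - set(markers)),
                size=max(0, config.planted_term_size - len(markers)),
                replace=False,
            )
        ]
        term = f"PLANTED{i:02d}"
        terms[term] = (f"planted marker program: {ct}", frozenset(markers) | frozenset(pad))
        truth.planted_terms[term] = ct
    lo, hi = config.background_term_size
    for i in range(config.n_annotation_terms):
        size = int(rng.integers(lo, hi + 1))
        members = [str(x) for x in rng.choice(genes, size=size, replace=False)]
        terms[f"BG{i:03d}"] = (f"background term {i}", frozenset(members))
    return AnnotationDatabase(source="synthetic", terms=terms), truth


def replace_truth(truth: GroundTruth) -> GroundTruth:
    """Shallow-copied truth so generators never mutate their input."""
    return GroundTruth(
        markers=dict(truth.markers),
        planted_terms=dict(truth.planted_terms),
        hubs=list(truth.hubs),
        golden_targets=dict(truth.golden_targets),
        golden_cell_type=truth.golden_cell_type,
    )


def generate_ppi(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> tuple[ConfidenceEdges, GroundTruth]:
    """STRING-like edge list over the marker universe with planted hubs.

    Hubs are wired to a fixed fraction of the markers at confidences inside
    the high-confidence band; background edges are Bernoulli over marker
    pairs with confidences mostly below the 0.9 cutoff.
    """
    rng = _rng(seed, "ppi")
    truth = replace_truth(truth)
    markers = sorted(truth.marker_genes)
    hubs = sorted(str(x) for x in rng.choice(markers, size=config.ppi_hub_count, replace=False))
    truth.hubs = list(hubs)

    rows = []
    non_hubs = [m for m in markers if m not in hubs]
    for hub in hubs:
        n_attach = int(round(config.ppi_hub_attachment * len(non_hubs)))
        attached = rng.choice(non_hubs, size=n_attach, replace=False)
        conf = rng.uniform(*config.ppi_planted_confidence, n_attach)
        rows += [
            {"protein_a": hub, "protein_b": str(t), "confidence": float(c)}
            for t, c in zip(attached, conf)
        ]
    for i, a in enumerate(non_hubs):
        for b in non_hubs[i + 1 :]:
            if rng.random() < config.ppi_background_edge_p:
                rows.append(
                    {
                        "protein_a": a,
                        "protein_b": b,
                        "confidence": rng.uniform(*config.ppi_background_confidence),
                    }
                )
    return ConfidenceEdges(data=pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])), truth


def generate_causal_network(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> tuple[CausalEdges, GroundTruth]:
    """Layered SIGNOR-like causal network with golden targets.

    Every marker protein gets its own intermediate chain of length
    ``n_intermediate_layers`` ending at its assigned phenotype subset, so
    reachable phenotype sets are controlled exactly: golden targets (drawn
    from the first cell type's markers) are wired to
    ``golden_phenotype_count`` phenotypes through high-reliability steps;
    background proteins reach at most ``max_background_phenotypes``
    phenotypes through lower-reliability steps.
    """
    rng = _rng(seed, "causal")
    truth = replace_truth(truth)
    golden_ct = config.cell_types[0]
    truth.golden_cell_type = golden_ct
    golden = truth.markers_of(golden_ct)[: config.n_golden_targets]
    truth.golden_targets = {g: config.golden_phenotype_count for g in golden}

    phenotypes = list(config.phenotypes)
    rows = []
    for prot in sorted(truth.marker_genes):
        is_golden = prot in truth.golden_targets
        r_range = config.golden_reliability_range if is_golden else config.reliability_range
        if is_golden:
            k = config.golden_phenotype_count
        else:
            k = int(rng.integers(1, config.max_background_phenotypes + 1))
        targets = sorted(str(x) for x in rng.choice(phenotypes, size=k, replace=False))
        chain = [prot] + [f"I_{prot}_{j}" for j in range(config.n_intermediate_layers)]
        for a, b in zip(chain[:-1], chain[1:]):
            rows.append(_edge(a, b, rng, r_range))
        for ph in targets:
            rows.append(_edge(chain[-1], ph, rng, r_range))
    edges = CausalEdges(
        data=pd.DataFrame(rows, columns=["source", "target", "effect", "reliability"]),
        phenotype_nodes=phenotypes,
    )
    return edges, truth


def _edge(a: str, b: str, rng: np.random.Generator, r_range: tuple[float, float]) -> dict:
    return {
        "source": a,
        "target": b,
        "effect": "up-regulates" if rng.random() < 0.7 else "down-regulates",
        "reliability": float(rng.uniform(*r_range)),
    }


def generate_all(
    config: SimulationConfig, seed: int
) -> tuple[list[ExpressionProfile], AnnotationDatabase, ConfidenceEdges, CausalEdges, GroundTruth]:
    """Run all four generators with their documented sub-streams."""
    profiles, truth = generate_expression(config, seed)
    db, truth = generate_annotations(config, truth, seed)
    ppi, truth = generate_ppi(config, truth, seed)
    causal, truth = generate_causal_network(config, truth, seed)
    return profiles, db, ppi, causal, truth


def write_simulation(config: SimulationConfig, seed: int, outdir) -> "GroundTruth":
    """Write a complete synthetic input directory plus ground-truth TSVs."""
    from pathlib import Path

    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles, db, ppi, causal, truth = generate_all(config, seed)
    for p in profiles:
        hio.write_expression_profiles(p, outdir / f"expression_{p.dataset_id}.tsv")
    hio.write_gmt(db, outdir / "annotations.gmt")
    hio.write_confidence_edges(ppi, outdir / "ppi_edges.tsv")
    hio.write_causal_edges(causal, outdir / "causal_edges.tsv")
    markers = pd.DataFrame(
        [
            {"gene": g, "cell_type": ct, "direction": d}
            for g, (ct, d) in sorted(truth.markers.items())
        ]
    )
    markers.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene": sorted(truth.golden_targets), "n_phenotypes": [truth.golden_targets[g] for g in sorted(truth.golden_targets)]}
    ).to_csv(outdir / "truth_golden_targets.tsv", sep="\t", index=False)
    pd.DataFrame({"hub": truth.hubs}).to_csv(outdir / "truth_hubs.tsv", sep="\t", index=False)
    return truth
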