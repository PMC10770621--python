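# Methods

This note records the models, conventions and design choices behind
`heartomics`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Cell-type z-scores and cross-dataset integration

Each input dataset is a *pseudo-profile*: per (gene, cell type), the mean
log-normalized expression, the percent of nuclei expressing, and the nucleus
count. Within one dataset a gene's values across its cell types are
standardized, `z = (x − μ_g)/σ_g`, and a two-tailed p is read from the
standard normal.

**Population SD.** `σ_g` divides by `n`, not `n − 1` (configurable via
`ddof`). The cell types of a dataset are the complete population of
profiles being compared, not a sample from a larger one, and the population
convention makes the two-cell-type case analytically clean (`z = ±1`).
With ~13 cell types the choice is material.

**Significance is a conjunction.** A call requires both `|z| ≥ 2` and
`p ≤ 0.001`. These two rules are not equivalent: on the standard normal,
`p ≤ 0.001` corresponds to `|z| ≥ 3.2905`, so the p-rule binds. Both
thresholds are kept explicit and configurable rather than silently merged.
A consequence worth stating: a single outlying cell type among `n` profiles
can never score beyond `|z| = √(n−1)` (the one-outlier ceiling), so with
fewer than 12 cell types *no* gene can satisfy the conjunction at defaults.
Significance calls therefore presume a realistic panel — the 13 heart cell
types used throughout.

**Gene-level integration.** A gene is significant in a dataset if it is
significant in ≥ 1 cell type; the integrated signature is the intersection
across all datasets. By default genes whose direction (over/under) differs
between datasets, or is mixed within one, are excluded and logged
(`require_consistent_direction=False` retains them as "mixed"). Constant
genes (SD = 0) are classed `undefined` with a warning, never significant.

**Cell-type assignment.** The papers' per-cell-type tallies do not fix an
assignment rule, and genes may be significant in several cell types. The
primary assignment is the cell type with the highest mean |z| across
datasets (ties broken lexicographically); all significant cell types are
also reported, so both single- and multi-assignment readings of per-cell-type
counts are supported. The percent-expressing > 50 filter applies only to
the per-cell-type mean-z summary, never to significance calls.

## Over-representation analysis

The test is the exact cumulative hypergeometric upper tail (via
`scipy.stats.hypergeom.sf`), equal to the one-sided Fisher enrichment p.
The statistical universe of a source is the union of its term gene sets, so
query genes without any annotation are excluded from the effective query
size `n` — padding a query with unannotated genes changes nothing.

Terms with zero overlap are not tested: they cannot be enriched and would
only inflate the number of tests `m` (configurable with
`test_zero_overlap`). BH-FDR is applied within each annotation source,
mirroring how multi-source enrichment tools report per-source blocks;
`pooled=True` corrects across sources instead. Whether public web tools
count zero-overlap terms in `m` is generally undocumented, so this
convention is stated here as a potential source of divergence from them.

## Interactome centralities

Edges survive when confidence ≥ cutoff (default 0.9 — the inclusive reading
of the STRING "highest confidence" band; configurable) and both endpoints
sit in the significant-gene whitelist; self-loops are dropped, duplicate
pairs collapse to the maximum confidence, and nodes left isolated are
excluded from the network.

- **Degree** is the raw edge count; the network mean is `2E/N`.
- **Betweenness** is unnormalized fractional counting over unordered pairs
  with endpoints excluded (Brandes, via networkx) — the convention whose
  magnitudes (hundreds to thousands on a ~150-node graph) match values
  typically reported for networks of this size. Disconnected graphs are
  handled per component naturally.
- **Eigenvector centrality** is the nonnegative principal eigenvector of
  the largest connected component's adjacency matrix, computed by dense
  symmetric eigendecomposition (a sparse Lanczos solver above 500 nodes,
  with a hard error on non-convergence), scaled to unit Euclidean norm;
  nodes outside the component get 0 and are flagged. `normalization="max"`
  rescales to a maximum entry of 1. Within a connected component the
  Perron eigenvalue is simple, so the vector is well defined.

Summaries report top-3 nodes per centrality (ties lexicographic), node
counts per primary cell type, and the overlap with a reference proteome as
a count plus percentage of network nodes rounded to the nearest integer.

## Reliability-weighted phenotype distance

Each directed causal edge carries reliability `r ∈ (0, 1]`; its step
distance is `d = 1 − r`, and a path scores `Dpath = Σ d`. `Dpath = 0` holds
exactly when every step has `r = 1`. Search follows edge direction only
(active-flow causality); signs (+ activation, − inhibition) annotate the
net effect of the returned path (their product) but never constrain the
optimum, since positive and negative regulation both count as regulation.

Shortest paths use Dijkstra with a composite priority `(Dpath, steps,
node sequence)`: ties on distance resolve to fewer steps, then to the
lexicographically smallest sequence, making outputs deterministic and
testable. Parallel edges collapse to the smallest step distance.
Unreachability is represented explicitly (`inf`) and excluded from every
mean — summing infinities would destroy all summaries; per-phenotype and
per-cell-type means are over reachable entries only, and this is the
documented reading wherever published per-phenotype means leave the
treatment of unreachable proteins unstated.

**Prioritization.** A protein qualifies for a phenotype when
`Dpath ≤ dmax`; the default `dmax = ∞` makes qualification reachability,
the weakest defensible reading of "has a shortest path to" a phenotype
(a distance cap is available when a stricter one is wanted). Proteins
qualifying for ≥ `min_phenotypes` (default 5) are ranked by descending
phenotype count, ascending mean Dpath, then name.

**Comparison.** Pairwise location tests between phenotype distance
distributions default to Welch's unequal-variance t with a 95% CI of the
mean difference (Mann–Whitney available); raw p-values are Bonferroni
multiplied by `m = C(P, 2)` and capped at 1, with significance at
α = 0.001. Welch is the default because distance distributions are
continuous, roughly unimodal, and differ mainly in location, and because a
CI of the mean difference is wanted; phenotypes with fewer than two
reachable values have their pairs skipped with a warning.

## Drug annotation

A static join: targets × (drug, target, mechanism, max_phase, indications)
records with `max_phase ≥ 3`. Live drug-database queries are deliberately
out of scope — snapshots drift, a file join is reproducible. The packaged
fixture covers the three druggable prioritized heart proteins (ADRA1A,
PPARG, ROCK2; 15 drugs, 5 mechanisms, 13 cardiovascular indications);
drug–indication pairing in the fixture is reconstructed by clinical
plausibility and labelled as such in its header.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with known ground truth. Each
generator draws from its own sub-stream
(`SeedSequence(seed, spawn_key=(k,))`, k fixed per generator), so outputs
are pure functions of (config, seed) and adding a generator never perturbs
another's draws.

**Expression.** Gene baselines `μ_g ~ N(1.0, 1.0)` (log-normalized units)
are drawn once and shared across datasets; each dataset/cell-type value
adds jitter `N(0, 0.2)` and clips at 0. An over-marker of cell type c is
shifted by `marker_effect_size × 1.0` (baseline-population SDs) in c; an
under-marker is modeled as a broadly expressed gene depleted back to
baseline in c — symmetric to the over case and free of zero-floor
artefacts. The defaults (effect 4, jitter 0.2) place a marker ~20
jitter-SDs from its gene's other cell types: the near-exclusive regime of
canonical markers such as MYH7 or NPPA, and the regime in which the
conjunction threshold is satisfiable at all given the one-outlier ceiling
√12 ≈ 3.46 of a 13-cell-type panel. Percent-expressing is uniform (5, 70)
for background entries and (55, 98) for markers in their own cell type.

**Annotations.** One planted term per cell type (its markers padded to 20
genes) plus 50 uniform background terms of 10–50 genes.

**Interactome.** Planted hubs wired to 60% of the markers at confidence
U(0.9, 1.0); background marker pairs connected with probability 0.05 at
confidence U(0.2, 0.95), so most background edges fail the 0.9 cutoff and
the surviving-edge count is binomial with a known rate.

**Causal network.** Each marker protein gets its own intermediate chain
(2 layers) ending at its assigned phenotype subset, so reachable phenotype
sets are controlled exactly: golden targets (3, drawn from the first cell
type's markers) reach 6 phenotypes through r ~ U(0.9, 0.99) steps; the
rest reach at most 4 through r ~ U(0.6, 0.99) steps. Per-protein chains
deliberately prevent reachability leaking through shared intermediates.

**Not emulated:** raw UMI counts, dropout, doublets, batch effects between
datasets, correlated gene programs, scale-free interactome topology, or
cross-talk in the causal graph. Passing the planted-recovery tests
demonstrates that the statistical machinery recovers structure *of the kind
the model assumes*; it does not certify performance on real snRNA-seq data,
whose noise is richer.

**Scale.** Defaults are 3 datasets × 13 heart cell types × 2,000 genes,
130 markers (10 per cell type), a ~100-node interactome and a ~270-node
causal network — the order of magnitude of the real integrated analyses
while keeping a full pipeline run under ten seconds; unit tests use smaller
configurations (2 datasets, 200–400 genes) except where the 13-cell-type
panel is statistically required.

## Numerical and formatting conventions

- Two-tailed p from the standard normal: `2·Φ̄(|z|)`; hypergeometric tails
  exact via scipy; BH via statsmodels (step-up, capped at 1, input order).
- Confidence scales: "milli" (STRING 0–1000) divided by 1000; "auto" infers
  milli when any score exceeds 1; values outside both scales are hard
  errors; normalization is idempotent.
- All writers sort canonically and print floats with `%.10g`, so
  `write(read(write(x)))` is byte-stable and repeated pipeline runs are
  byte-identical.
- Degenerate inputs: constant genes → `undefined` (warning); zero surviving
  network edges → empty network (warning); source = phenotype → Dpath 0
  (warning); empty target set → empty drug map. Hard errors are reserved
  for structural violations (duplicate keys, closed-vocabulary breaches,
  out-of-domain scores) and name the offending value.

## Known limitations

- Published per-protein distances from live causal-network snapshots are
  not reproducible from a fixed edge list and are not attempted; the
  package reproduces the *method*, with file-based inputs.
- Gene identifiers are opaque case-sensitive symbols; no cross-namespace
  mapping.
- The enrichment universe is per source; results are sensitive to the GMT
  supplied, as in any ORA.
- The Welch test treats proteins as independent observations; proteins
  sharing causal intermediates violate this mildly, as they do in the
  underlying resources.
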