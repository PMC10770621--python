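"""Packaged reference tables for the three public heart snRNA-seq studies.

The per-cell-type nucleus counts and stated totals of the Broad Single Cell
Portal accessions SCP1303 (Chaffin et al.), SCP1852 (Hill et al.) and
SCP1849 (Simonson et al.) are shipped as a small TSV, used for consistency
checks and as a realistic scale reference for the synthetic-data generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Totals stated by the source studies; the consolidated count is their sum.
DATASET_TOTALS = {"SCP1303": 592_689, "SCP1852": 157_273, "SCP1849": 99_684}

#: The 13 heart cell types shared by the integrated analysis (default
#: cell-type panel of the synthetic generator).
HEART_CELL_TYPES = (
    "adipocytes",
    "cardiomyocytes",
    "endocardial cells",
    "endothelial cells",
    "epicardial cells",
    "fibroblasts",
    "lymphatic endothelial cells",
    "lymphocytes",
    "macrophages",
    "mast cells",
    "neuronal cells",
    "pericytes",
    "VSMCs",
)


def nucleus_count_table() -> pd.DataFrame:
    """Per-dataset, per-cell-type nucleus counts (dataset, cell_type, n_nuclei)."""
    path = resources.files("heartomics.data").joinpath("snrnaseq_nucleus_counts.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def nucleus_count_sums() -> dict[str, int]:
    """Sum of the per-cell-type counts for each dataset."""
    df = nucleus_count_table()
    return {k: int(v) for k, v in df.groupby("dataset")["n_nuclei"].sum().items()}


def consolidated_total() -> int:
    """Total nuclei across the three studies, from their stated totals."""
    return sum(DATASET_TOTALS.values())
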